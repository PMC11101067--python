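"""Chain construction, element force laws, statics, and integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from impactchain import (
    ChainConfigError,
    HardStopElement,
    InitializationError,
    TaperJunctionElement,
    build_default_chain,
    hardstop_force,
    mechanical_energy,
    normal_force,
    simulate,
    steady_state_preload,
    synth_half_sine,
    taper_friction_force,
)
from impactchain.chain_model import _element_forces


class TestBuildDefaultChain:
    def test_reference_values(self, default_chain):
        assert default_chain.head.mass == 0.062
        assert default_chain.taper.mu_static == 0.79
        assert default_chain.impactor_spring.stiffness == 85e6
        assert default_chain.loadcell_spring.stiffness == 2.3e9
        assert default_chain.tip_contact.full_damping == 240e3
        assert default_chain.tissue_spring.stiffness == 4000.0
        # tissue damping follows the 10 %-of-stiffness rule
        assert default_chain.tissue_spring.damping == pytest.approx(400.0)

    def test_additional_weight_override(self):
        chain = build_default_chain({"tissue_mass": 0.89})
        assert chain.tissue.mass == 0.89
        assert chain.tissue_spring.stiffness == 4000.0

    @pytest.mark.parametrize(
        "overrides",
        [{"head_mass": -1.0}, {"stem_stiffness": -5.0}, {"not_a_parameter": 1.0}],
    )
    def test_invalid_configurations_rejected(self, overrides):
        with pytest.raises(ChainConfigError):
            build_default_chain(overrides)


class TestElementLaws:
    def test_normal_force_values(self, default_chain):
        taper = default_chain.taper
        assert normal_force(taper, 0.0) == pytest.approx(5.0)
        assert normal_force(taper, 10e-6) == pytest.approx(19.0)
        free = TaperJunctionElement("head", "stem", normal_force_quadratic=0.0)
        assert normal_force(free, 3e-3) == pytest.approx(5.0)
        with pytest.raises(ValueError):
            normal_force(taper, -1e-6)

    def test_hardstop_force_values(self, default_chain):
        stop = default_chain.tip_contact
        assert hardstop_force(stop, -10e-6, 1.0) == 0.0
        assert hardstop_force(stop, 50e-6, 0.0) == pytest.approx(650.0)
        assert hardstop_force(stop, 25e-6, 0.0) == pytest.approx(162.5)
        # separating velocity can never make the contact pull
        assert hardstop_force(stop, 25e-6, -10.0) == 0.0

    @given(
        pen=st.floats(-1e-4, 5e-4),
        pen2=st.floats(-1e-4, 5e-4),
        vel=st.floats(-10.0, 10.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_hardstop_nonnegative_and_monotone(self, pen, pen2, vel):
        stop = HardStopElement("a", "b", full_stiffness=13e6, full_damping=240e3)
        assert hardstop_force(stop, pen, vel) >= 0.0
        lo, hi = sorted((pen, pen2))
        assert hardstop_force(stop, lo, 0.0) <= hardstop_force(stop, hi, 0.0)

    def test_taper_friction_stick_and_slip(self, default_chain):
        taper = default_chain.taper
        # stick: demand inside the static cone (limit 0.79 * 5 = 3.95 N)
        assert taper_friction_force(taper, 3.0, 0.0, 0.0) == pytest.approx(3.0)
        # slip at d = 10 um: 0.49 * 19.0 N opposing the motion
        assert taper_friction_force(taper, 0.0, 0.1, 10e-6) == pytest.approx(9.31)
        assert taper_friction_force(taper, 0.0, -0.1, 10e-6) == pytest.approx(-9.31)
        frictionless = TaperJunctionElement("head", "stem", mu_static=0.0, mu_kinetic=0.0)
        assert taper_friction_force(frictionless, 100.0, 1.0, 1e-3) == 0.0

    def test_mu_ordering_enforced(self):
        with pytest.raises(ChainConfigError):
            TaperJunctionElement("head", "stem", mu_static=0.4, mu_kinetic=0.6)


class TestStaticInitialization:
    def test_zero_gravity_means_zero_preload(self):
        chain = build_default_chain({"gravity": 0.0})
        init = steady_state_preload(chain)
        assert init.compression_tissue_spring == 0.0
        assert init.insertion_depth == 0.0
        assert init.preload_taper == 0.0

    def test_reference_statics(self, default_chain):
        init = steady_state_preload(default_chain)
        total = default_chain.total_mass
        # tissue spring carries the whole 1.354 kg assembly
        assert init.compression_tissue_spring == pytest.approx(
            total * 9.81 / 4000.0, rel=1e-9
        )
        assert init.compression_tissue_spring == pytest.approx(3.32e-3, rel=1e-2)
        # junction carries impactor + load cell + tip + head = 7.76 N
        assert init.preload_taper == pytest.approx(7.76, abs=0.01)
        # smallest d with mu_s * (N0 + beta d^2) >= 7.76 N
        assert init.insertion_depth == pytest.approx(5.87e-6, rel=1e-2)

    def test_unsupportable_weight_raises(self):
        chain = build_default_chain(
            {"mu_static": 0.0, "mu_kinetic": 0.0, "normal_force_quadratic": 0.0}
        )
        with pytest.raises(InitializationError):
            steady_state_preload(chain)


class TestSimulate:
    def test_grid_contract(self, reference_sim):
        assert len(reference_sim.time) == 641
        assert np.allclose(np.diff(reference_sim.time), 1.25e-6)
        assert reference_sim.impactor_force[0] == 0.0
        assert np.all(reference_sim.velocity[0] == 0.0)

    def test_static_persistence_with_zero_pulse(self, default_chain, zero_pulse):
        res = simulate(default_chain, zero_pulse)
        bound = 1e-6 * default_chain.total_mass * 9.81
        assert np.max(np.abs(res.impactor_force)) < bound
        assert np.max(np.abs(res.stem_force)) < bound

    def test_no_adhesion_along_trajectory(self, reference_sim):
        assert np.all(reference_sim.contact_force >= 0.0)

    def test_friction_bound_along_trajectory(self, reference_sim):
        taper = reference_sim.chain.taper
        limit = taper.mu_static * (
            taper.normal_force_constant
            + taper.normal_force_quadratic * reference_sim.insertion_depth**2
        )
        assert np.all(np.abs(reference_sim.junction_force) <= limit * (1 + 1e-6) + 1e-9)

    def test_single_oscillator_limit(self):
        """Near-rigid internal couplings reduce the chain to one mass on the
        tissue spring; the simulated period must match 2*pi*sqrt(M/k)."""
        k_tissue = 4e6
        chain = build_default_chain(
            {
                "impactor_stiffness": 1e10,
                "impactor_damping": 1e4,
                "loadcell_stiffness": 1e10,
                "loadcell_damping": 1e4,
                "tip_stiffness": 1e10,
                "tip_damping": 1e4,
                "stem_stiffness": 1e10,
                "stem_damping": 1e4,
                "mu_static": 1e3,
                "mu_kinetic": 1e3,
                "normal_force_quadratic": 1e18,
                "tissue_stiffness": k_tissue,
                "tissue_damping": 0.0,
            },
            bilateral_contact=True,
        )
        expected = 2 * math.pi * math.sqrt(chain.total_mass / k_tissue)
        pulse = synth_half_sine(peak=500.0, width=0.2e-3, duration=8e-3)
        res = simulate(chain, pulse, duration=8e-3, sample_rate=2e5, oversample=32)
        u = res.displacement[:, 5]
        from scipy.signal import find_peaks

        peaks, _ = find_peaks(u - u.mean())
        assert len(peaks) >= 2
        # quadratic interpolation of the peak locations
        refined = []
        for p in peaks[:2]:
            a, b, c = u[p - 1], u[p], u[p + 1]
            refined.append(p + 0.5 * (a - c) / (a - 2 * b + c))
        period = (refined[1] - refined[0]) / res.sample_rate
        assert period == pytest.approx(expected, rel=5e-3)

    def test_energy_conservation_without_dissipation(self):
        """No damping, no friction, bilateral contact, no gravity: total
        mechanical energy is constant once the pulse has ended."""
        chain = build_default_chain(
            {
                "tip_damping": 0.0,
                "tissue_damping": 0.0,
                "mu_static": 0.0,
                "mu_kinetic": 0.0,
                "gravity": 0.0,
            },
            bilateral_contact=True,
        )
        pulse = synth_half_sine()
        res = simulate(chain, pulse)
        energy = mechanical_energy(res)
        after = energy[res.time > pulse.width]
        assert np.max(np.abs(after - after.mean())) < 0.01 * after.mean()

    def test_element_force_reconstruction_matches_statics(self, reference_sim):
        forces = _element_forces(
            reference_sim.chain,
            reference_sim.initial_state,
            reference_sim.displacement,
            reference_sim.velocity,
        )
        init = reference_sim.initial_state
        assert forces["loadcell_spring"][0] == pytest.approx(init.preload_loadcell_spring)
        assert forces["taper"][0] == pytest.approx(init.preload_taper, rel=1e-6)
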