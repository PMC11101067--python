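"""Sensitivity screening, pseudo-measurements, and SSE fitting."""

import numpy as np
import pytest
from scipy import signal as sps

from impactchain import (
    build_default_chain,
    default_parameter_space,
    fit_parameters,
    make_pseudo_measurements,
    synth_half_sine,
)
from impactchain.estimation import (
    FREE_PARAMETERS,
    ParameterSpace,
    _rank_correlations,
    screen_outliers,
    sensitivity_mc,
)
from impactchain.signal_metrics import CUTOFF_IMPACTOR, zero_phase_lowpass


class TestParameterSpace:
    def test_defaults_free_and_fixed_split(self):
        space = default_parameter_space()
        assert len(space.ranges) == 10
        assert set(space.free_names) == set(FREE_PARAMETERS)
        assert space.fixed["transition_depth"] == 50e-6
        assert space.fixed["normal_force_constant"] == 5.0

    def test_zero_width_range_rejected(self):
        with pytest.raises(ValueError):
            ParameterSpace(ranges={"mu_static": (0.5, 0.5)})


class TestRankCorrelations:
    def test_affine_response_has_unit_rank_correlation(self):
        rng = np.random.default_rng(0)
        samples = rng.uniform(0, 1, size=(500, 3))
        responses = np.column_stack(
            [2.0 + 5.0 * samples[:, 0], rng.uniform(0, 1, 500)]
        )
        df = _rank_correlations(samples, responses, ["a", "b", "dummy"], ["affine", "noise"])
        assert df.loc["a", "affine"] > 0.95
        # parameters that do not enter the response show null correlation
        assert df.loc["dummy", "affine"] < 0.1
        assert df.loc["b", "affine"] < 0.1


class TestSensitivityMC:
    def test_ranking_deterministic_and_sensible(self):
        space = default_parameter_space()
        a = sensitivity_mc(space, n_samples=50, rng_seed=3)
        b = sensitivity_mc(space, n_samples=50, rng_seed=3)
        assert list(a.index) == list(b.index)
        assert np.allclose(a.to_numpy(), b.to_numpy())
        # every screened parameter is present, correlations lie in [0, 1]
        assert set(a.index) == set(space.ranges)
        assert ((a.to_numpy() >= 0) & (a.to_numpy() <= 1 + 1e-12)).all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_mc(default_parameter_space(), n_samples=10)


class TestPseudoMeasurements:
    def test_zero_noise_equals_filtered_simulation(self, default_chain, half_sine):
        from impactchain import simulate
        from impactchain.signal_metrics import CUTOFF_STEM, normalize_to_mallet

        (pulse, imp, stem), = make_pseudo_measurements(
            default_chain, {}, [half_sine], noise_sd=0.0
        )
        res = simulate(default_chain, half_sine)
        expected = zero_phase_lowpass(
            normalize_to_mallet(res.impactor_force, half_sine.peak_force),
            res.sample_rate,
            CUTOFF_IMPACTOR,
        )
        assert np.allclose(imp, expected)

    def test_deterministic_for_seed(self, default_chain, half_sine):
        a = make_pseudo_measurements(default_chain, {}, [half_sine], 0.02, rng_seed=5)
        b = make_pseudo_measurements(default_chain, {}, [half_sine], 0.02, rng_seed=5)
        assert np.array_equal(a[0][1], b[0][1])

    def test_noise_level_after_filtering(self, default_chain, half_sine):
        """The filtered residual SD must match the injected noise scaled by
        the filter's noise bandwidth (white noise loses variance in a
        low-pass; the expected factor follows from the squared magnitude
        response of the double-pass filter)."""
        noise_sd = 0.02
        # pool many blows: a single 0.8 ms window holds only ~8 independent
        # noise samples after 10 kHz low-pass filtering
        n_rep = 20
        clean, = make_pseudo_measurements(default_chain, {}, [half_sine], 0.0)
        noisy = make_pseudo_measurements(
            default_chain, {}, [half_sine] * n_rep, noise_sd, rng_seed=11
        )
        resid = np.concatenate([imp - clean[1] for _, imp, _ in noisy])
        # independent oracle: noise gain of forward-backward filtering is
        # the mean of |H|^4 over frequency
        sos = sps.butter(4, CUTOFF_IMPACTOR, btype="low", fs=800e3, output="sos")
        w, h = sps.sosfreqz(sos, worN=4096, fs=800e3)
        expected_sd = noise_sd * np.sqrt(np.mean(np.abs(h) ** 4))
        assert np.std(resid) == pytest.approx(expected_sd, rel=0.2)


class TestScreenOutliers:
    def test_distinct_frequency_dropped(self):
        rate = 800e3
        t = np.arange(641) / rate

        def two_peak(freq):
            return np.sin(2 * np.pi * freq * t)

        pulse = synth_half_sine()
        datasets = [(pulse, two_peak(4e3), two_peak(4e3)) for _ in range(4)]
        datasets.append((pulse, two_peak(8e3), two_peak(8e3)))
        kept = screen_outliers(datasets, threshold=0.25)
        assert len(kept) == 4


class TestFitParameters:
    def test_two_parameter_recovery(self, default_chain):
        """Bounded least squares recovers a two-parameter perturbation from
        noise-free pseudo-measurements."""
        truth = {"impactor_stiffness": 95e6, "stem_stiffness": 145e6}
        pulses = [synth_half_sine()]
        datasets = make_pseudo_measurements(default_chain, truth, pulses, 0.0)
        space = default_parameter_space()
        fixed = dict(space.fixed)
        for name in FREE_PARAMETERS:
            if name not in truth:
                fixed[name] = None  # placeholder, replaced below
        # fix every free parameter except the two of interest at its true
        # (nominal) value so the fit space is two-dimensional
        from impactchain.estimation import _chain_to_overrides

        nominal = _chain_to_overrides(default_chain)
        fixed = dict(space.fixed)
        for name in FREE_PARAMETERS:
            if name not in truth:
                fixed[name] = nominal[name]
        space2 = ParameterSpace(ranges=space.ranges, fixed=fixed)
        result = fit_parameters(
            datasets, space=space2, chain=default_chain, method="least-squares", max_nfev=60
        )
        assert result.params["impactor_stiffness"] == pytest.approx(95e6, rel=0.01)
        assert result.params["stem_stiffness"] == pytest.approx(145e6, rel=0.01)
        assert max(result.rmse_impactor + result.rmse_stem) < 0.1

    def test_empty_datasets_rejected(self):
        with pytest.raises(ValueError):
            fit_parameters([])
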