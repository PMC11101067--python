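"""Extrapolation sweeps and the experimental tissue-surrogate presets.

Two parameter sweeps extrapolate the identified model beyond the bench
setup: the impactor sweep varies impactor mass (5 steps, 0.1--2 kg) against
26 log-spaced impactor stiffnesses (100 N/mm to 1e6 N/mm; 130 simulations),
and the tissue sweep varies the responding-tissue surrogate (8 log-spaced
masses 0.1--20 kg x 8 log-spaced stiffnesses 0.1--50 N/mm; 64 simulations).
``run_experiment_presets`` reproduces the five bench configurations
(reference 4.0 N/mm / 0.52 kg, stiffness variants 1.9 / 5.0 / 0.6 N/mm, and
the added-weight assembly at 0.89 kg).

All outputs are tidy DataFrames with normalized peak forces (fractions of
the mallet peak).  Simulated PoM traces pass through the measurement-chain
zero-phase filters (impactor 10 kHz, stem 15 kHz) before feature
extraction, mirroring how the bench recordings were conditioned.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .chain_model import ChainConfig, build_default_chain, simulate
from .estimation import _chain_to_overrides
from .impulse_input import ForcePulse, synth_half_sine
from .signal_metrics import (
    CUTOFF_IMPACTOR,
    CUTOFF_STEM,
    FeatureError,
    extract_features,
    normalize_to_mallet,
    zero_phase_lowpass,
)

__all__ = [
    "run_impactor_sweep",
    "run_tissue_sweep",
    "run_experiment_presets",
    "EXPERIMENT_PRESETS",
]

#: Bench tissue-surrogate configurations: label -> (tissue mass kg, stiffness N/m).
EXPERIMENT_PRESETS = {
    "reference": (0.52, 4000.0),
    "stiffness_1.9": (0.52, 1900.0),
    "stiffness_5.0": (0.52, 5000.0),
    "stiffness_0.6": (0.52, 600.0),
    "additional_weight": (0.89, 4000.0),
}


def _sweep_cell(
    chain: ChainConfig, pulse: ForcePulse
) -> tuple[Optional[float], Optional[float], bool]:
    """Normalized impactor/stem first peaks for one sweep cell.

    Returns (impactor peak, stem peak, determinable).  A cell is flagged
    not determinable when the impactor force has no local maximum with
    prominence above 1 % of the mallet peak within the simulated window.
    """
    res = simulate(chain, pulse)
    imp = zero_phase_lowpass(
        normalize_to_mallet(res.impactor_force, pulse.peak_force),
        res.sample_rate,
        CUTOFF_IMPACTOR,
    )
    stem = zero_phase_lowpass(
        normalize_to_mallet(res.stem_force, pulse.peak_force),
        res.sample_rate,
        CUTOFF_STEM,
    )
    # prominence threshold relative to the mallet peak; the traces are
    # mallet-normalized, so the threshold is 0.01 in normalized units
    idx, _ = find_peaks(imp, height=0.0, prominence=0.01)
    determinable = bool(len(idx))
    imp_peak = float(imp[idx[0]]) if determinable else None
    stem_idx, _ = find_peaks(stem, height=0.0, prominence=0.01)
    stem_peak = float(stem[stem_idx[0]]) if len(stem_idx) else None
    return imp_peak, stem_peak, determinable


def run_impactor_sweep(
    chain: Optional[ChainConfig] = None,
    pulse: Optional[ForcePulse] = None,
    masses: Optional[Sequence[float]] = None,
    stiffnesses: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Sweep impactor mass and stiffness (default 5 x 26 = 130 simulations).

    Masses are linearly spaced over 0.1--2 kg, stiffnesses log-spaced over
    1e5--1e9 N/m (100 N/mm to 1e6 N/mm).  Rows where the impactor force has
    no determinable peak within the simulation window are flagged
    (``peak_determinable = False``), not dropped.
    """
    if chain is None:
        chain = build_default_chain()
    if pulse is None:
        pulse = synth_half_sine()
    if masses is None:
        masses = np.linspace(0.1, 2.0, 5)
    if stiffnesses is None:
        stiffnesses = np.geomspace(100e3, 1e9, 26)
    base = _chain_to_overrides(chain)
    rows = []
    for m in masses:
        for k in stiffnesses:
            overrides = dict(base, impactor_mass=float(m), impactor_stiffness=float(k))
            try:
                imp_peak, stem_peak, ok = _sweep_cell(build_default_chain(overrides), pulse)
            except (RuntimeError, FeatureError):
                imp_peak, stem_peak, ok = None, None, False
            rows.append(
                {
                    "impactor_mass_kg": float(m),
                    "impactor_stiffness_N_per_m": float(k),
                    "normalized_impactor_peak": imp_peak,
                    "normalized_stem_peak": stem_peak,
                    "peak_determinable": ok,
                }
            )
    return pd.DataFrame(rows)


def run_tissue_sweep(
    chain: Optional[ChainConfig] = None,
    pulse: Optional[ForcePulse] = None,
    masses: Optional[Sequence[float]] = None,
    stiffnesses: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Sweep the responding-tissue surrogate (default 8 x 8 = 64 simulations).

    Masses log-spaced over 0.1--20 kg, stiffnesses log-spaced over
    100--50e3 N/m (0.1--50 N/mm); tissue damping follows the 10 %-of-
    stiffness rule in each cell.
    """
    if chain is None:
        chain = build_default_chain()
    if pulse is None:
        pulse = synth_half_sine()
    if masses is None:
        masses = np.geomspace(0.1, 20.0, 8)
    if stiffnesses is None:
        stiffnesses = np.geomspace(100.0, 50e3, 8)
    base = _chain_to_overrides(chain)
    rows = []
    for m in masses:
        for k in stiffnesses:
            overrides = dict(
                base,
                tissue_mass=float(m),
                tissue_stiffness=float(k),
                tissue_damping=0.1 * float(k),
            )
            try:
                imp_peak, stem_peak, ok = _sweep_cell(build_default_chain(overrides), pulse)
            except (RuntimeError, FeatureError):
                imp_peak, stem_peak, ok = None, None, False
            rows.append(
                {
                    "tissue_mass_kg": float(m),
                    "tissue_stiffness_N_per_m": float(k),
                    "normalized_impactor_peak": imp_peak,
                    "normalized_stem_peak": stem_peak,
                    "peak_determinable": ok,
                }
            )
    return pd.DataFrame(rows)


def run_experiment_presets(
    pulse: Optional[ForcePulse] = None,
) -> pd.DataFrame:
    """Simulate the five bench tissue-surrogate configurations.

    Returns one row per configuration with the oscillation features of both
    PoM traces: normalized first/second peaks, periods, and delays from the
    mallet peak.
    """
    if pulse is None:
        pulse = synth_half_sine()
    rows = []
    for label, (mass, stiffness) in EXPERIMENT_PRESETS.items():
        ch = build_default_chain(
            {"tissue_mass": mass, "tissue_stiffness": stiffness, "tissue_damping": 0.1 * stiffness}
        )
        res = simulate(ch, pulse)
        imp = zero_phase_lowpass(
            normalize_to_mallet(res.impactor_force, pulse.peak_force),
            res.sample_rate,
            CUTOFF_IMPACTOR,
        )
        stem = zero_phase_lowpass(
            normalize_to_mallet(res.stem_force, pulse.peak_force),
            res.sample_rate,
            CUTOFF_STEM,
        )
        fi = extract_features(imp, res.sample_rate, pulse.peak_time)
        fs = extract_features(stem, res.sample_rate, pulse.peak_time)
        rows.append(
            {
                "configuration": label,
                "tissue_mass_kg": mass,
                "tissue_stiffness_N_per_m": stiffness,
                "impactor_first_peak": fi.first_peak,
                "impactor_second_peak": fi.second_peak,
                "impactor_period_s": fi.period,
                "impactor_delay_s": fi.delay_from_mallet_peak,
                "stem_first_peak": fs.first_peak,
                "stem_second_peak": fs.second_peak,
                "stem_period_s": fs.period,
                "stem_delay_s": fs.delay_from_mallet_peak,
            }
        )
    return pd.DataFrame(rows)
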