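"""Sensitivity screening and parameter estimation for the chain model.

Ten chain parameters cannot be measured directly: impactor stiffness, tip
contact stiffness and damping, the contact transition depth, the two
friction coefficients, the two normal-force-law coefficients, the stem
stiffness, and the tissue damping.  A Monte-Carlo sensitivity analysis
(uniform sampling over declared ranges, rank-correlation of scalar
responses) screens out the weakly influential ones; those keep broadly
estimated values (transition depth 50 um, normal-force constant 5 N,
tissue damping 10 % of the tissue spring stiffness).  The remaining seven
free parameters are identified by minimizing the summed squared error of
the normalized impactor and stem forces, over the windowed comparison
interval, against (pseudo-)measured recordings.

Because the raw in vitro recordings ship only as supplementary material,
:func:`make_pseudo_measurements` generates stand-in datasets by simulating
a chain with known parameters, adding sensor noise and applying the
measurement-chain filters -- which also provides the ground truth for
parameter-recovery checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .chain_model import (
    ChainConfig,
    ChainConfigError,
    SAMPLE_RATE,
    build_default_chain,
    simulate,
)
from .impulse_input import ForcePulse
from .signal_metrics import (
    CUTOFF_IMPACTOR,
    CUTOFF_STEM,
    FeatureError,
    _evaluation_window,
    dominant_frequency,
    extract_features,
    normalize_to_mallet,
    rmse_window,
    zero_phase_lowpass,
)

__all__ = [
    "ParameterSpace",
    "FitResult",
    "FitError",
    "default_parameter_space",
    "sensitivity_mc",
    "make_pseudo_measurements",
    "screen_outliers",
    "fit_parameters",
]

logger = logging.getLogger(__name__)

#: Names of the seven parameters left free in the optimization, in order.
FREE_PARAMETERS = (
    "impactor_stiffness",
    "tip_stiffness",
    "tip_damping",
    "mu_static",
    "mu_kinetic",
    "normal_force_quadratic",
    "stem_stiffness",
)

#: The three screened-out parameters and their broadly estimated values (SI).
FIXED_PARAMETERS = {
    "transition_depth": 50e-6,
    "normal_force_constant": 5.0,
    "tissue_damping": 400.0,  # 10 % of the 4.0 N/mm reference tissue spring
}


class FitError(RuntimeError):
    """Optimizer failed; the best-so-far result is attached as ``result``."""

    def __init__(self, message: str, result: "FitResult"):
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class ParameterSpace:
    """Uncertain-parameter ranges for screening and fitting (SI units).

    ``ranges`` maps each of the ten uncertain parameter names to a
    (low, high) interval; ``fixed`` pins the screened-out parameters to
    their broadly estimated values so only the remaining names are free.
    """

    ranges: dict[str, tuple[float, float]]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if not hi > lo:
                raise ValueError(f"range for {name!r} must have positive width")

    @property
    def free_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.ranges if n not in self.fixed)

    def free_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.ranges[n][0] for n in self.free_names])
        hi = np.array([self.ranges[n][1] for n in self.free_names])
        return lo, hi


def default_parameter_space() -> ParameterSpace:
    """The ten uncertain parameters with broad ranges around the identified values."""
    return ParameterSpace(
        ranges={
            "impactor_stiffness": (20e6, 300e6),
            "tip_stiffness": (3e6, 50e6),
            "tip_damping": (50e3, 1000e3),
            "transition_depth": (10e-6, 200e-6),
            "mu_static": (0.3, 1.2),
            "mu_kinetic": (0.1, 1.0),
            "normal_force_constant": (1.0, 20.0),
            "normal_force_quadratic": (20e9, 600e9),
            "stem_stiffness": (30e6, 500e6),
            "tissue_damping": (40.0, 4000.0),
        },
        fixed=dict(FIXED_PARAMETERS),
    )


def _chain_with(chain_overrides: dict[str, float], base: Optional[ChainConfig]) -> ChainConfig:
    """Default chain with overrides; mu_kinetic clamped to mu_static.

    The clamp regularizes sampled/optimized points that violate the
    ``mu_kinetic <= mu_static`` invariant instead of rejecting them.
    """
    p = dict(chain_overrides)
    if "mu_kinetic" in p:
        mu_s = p.get("mu_static", base.taper.mu_static if base else 0.79)
        p["mu_kinetic"] = min(p["mu_kinetic"], mu_s)
    if base is None:
        return build_default_chain(p)
    merged = _chain_to_overrides(base)
    merged.update(p)
    return build_default_chain(merged)


def _chain_to_overrides(chain: ChainConfig) -> dict[str, float]:
    contact = chain.tip_contact
    return {
        "impactor_mass": chain.impactor.mass,
        "loadcell_mass": chain.loadcell.mass,
        "tip_mass": chain.tip.mass,
        "head_mass": chain.head.mass,
        "stem_mass": chain.stem.mass,
        "tissue_mass": chain.tissue.mass,
        "impactor_stiffness": chain.impactor_spring.stiffness,
        "impactor_damping": chain.impactor_spring.damping,
        "loadcell_stiffness": chain.loadcell_spring.stiffness,
        "loadcell_damping": chain.loadcell_spring.damping,
        "tip_stiffness": getattr(contact, "full_stiffness", getattr(contact, "stiffness", 0.0)),
        "tip_damping": getattr(contact, "full_damping", getattr(contact, "damping", 0.0)),
        "transition_depth": getattr(contact, "transition_depth", 50e-6),
        "mu_static": chain.taper.mu_static,
        "mu_kinetic": chain.taper.mu_kinetic,
        "normal_force_constant": chain.taper.normal_force_constant,
        "normal_force_quadratic": chain.taper.normal_force_quadratic,
        "stem_stiffness": chain.stem_spring.stiffness,
        "stem_damping": chain.stem_spring.damping,
        "tissue_stiffness": chain.tissue_spring.stiffness,
        "tissue_damping": chain.tissue_spring.damping,
        "gravity": chain.gravity,
    }


def _simulate_pom_traces(
    chain: ChainConfig, pulse: ForcePulse, filtered: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (and by default filtered) impactor and stem PoM traces."""
    res = simulate(chain, pulse)
    imp = normalize_to_mallet(res.impactor_force, pulse.peak_force)
    stem = normalize_to_mallet(res.stem_force, pulse.peak_force)
    if filtered:
        imp = zero_phase_lowpass(imp, res.sample_rate, CUTOFF_IMPACTOR)
        stem = zero_phase_lowpass(stem, res.sample_rate, CUTOFF_STEM)
    return imp, stem


# ---------------------------------------------------------------------------
# Monte-Carlo sensitivity screening
# ---------------------------------------------------------------------------


def sensitivity_mc(
    space: ParameterSpace,
    chain: Optional[ChainConfig] = None,
    pulse: Optional[ForcePulse] = None,
    n_samples: int = 200,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Monte-Carlo sensitivity ranking of the uncertain parameters.

    Samples parameter vectors uniformly over the declared ranges, simulates
    each, and computes four scalar responses: normalized impactor and stem
    first peaks and the windowed RMSE of each trace against the nominal
    (unperturbed) run.  Returns the absolute Spearman rank correlation of
    every parameter with every response, plus a ``max_abs`` column, sorted
    descending -- rank correlation is invariant under monotone rescaling of
    the responses and robust to the nonlinear response surfaces.

    Failed simulations are dropped with a log entry; more than 20 %
    failures abort the analysis.
    """
    if n_samples < 50:
        raise ValueError("n_samples must be >= 50 for a stable ranking")
    if chain is None:
        chain = build_default_chain()
    if pulse is None:
        from .impulse_input import synth_half_sine

        pulse = synth_half_sine()
    rng = np.random.default_rng(rng_seed)
    names = list(space.ranges)
    lo = np.array([space.ranges[n][0] for n in names])
    hi = np.array([space.ranges[n][1] for n in names])
    samples = rng.uniform(lo, hi, size=(n_samples, len(names)))

    imp_nom, stem_nom = _simulate_pom_traces(chain, pulse)
    rows, kept = [], []
    for vec in samples:
        try:
            trial = _chain_with(dict(zip(names, vec)), chain)
            imp, stem = _simulate_pom_traces(trial, pulse)
            rows.append(
                (
                    extract_features(imp, SAMPLE_RATE).first_peak,
                    extract_features(stem, SAMPLE_RATE).first_peak,
                    rmse_window(imp, imp_nom, SAMPLE_RATE),
                    rmse_window(stem, stem_nom, SAMPLE_RATE),
                )
            )
            kept.append(vec)
        except (ChainConfigError, FeatureError, RuntimeError) as exc:
            logger.warning("sensitivity sample dropped: %s", exc)
    if len(kept) < 0.8 * n_samples:
        raise RuntimeError(
            f"sensitivity analysis failed: only {len(kept)}/{n_samples} samples usable"
        )
    resp_names = ("impactor_peak", "stem_peak", "impactor_rmse", "stem_rmse")
    return _rank_correlations(np.asarray(kept), np.asarray(rows), names, resp_names)


def _rank_correlations(
    samples: np.ndarray,
    responses: np.ndarray,
    param_names: Sequence[str],
    response_names: Sequence[str],
) -> pd.DataFrame:
    """Absolute Spearman correlation of each parameter with each response."""
    corr = np.empty((samples.shape[1], responses.shape[1]))
    for i in range(samples.shape[1]):
        for j in range(responses.shape[1]):
            rho = stats.spearmanr(samples[:, i], responses[:, j]).statistic
            corr[i, j] = abs(rho) if np.isfinite(rho) else 0.0
    df = pd.DataFrame(corr, index=list(param_names), columns=list(response_names))
    df["max_abs"] = df.max(axis=1)
    return df.sort_values("max_abs", ascending=False)


# ---------------------------------------------------------------------------
# pseudo-measurements (synthetic stand-in for the in vitro recordings)
# ---------------------------------------------------------------------------


def make_pseudo_measurements(
    chain: ChainConfig,
    true_params: dict[str, float],
    pulses: Sequence[ForcePulse],
    noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> list[tuple[ForcePulse, np.ndarray, np.ndarray]]:
    """Synthetic measurement datasets from a chain with known parameters.

    Simulates the chain (with ``true_params`` applied) under each pulse,
    adds i.i.d. Gaussian sensor noise of ``noise_sd`` times the mallet
    peak, applies the per-PoM zero-phase filters (10 kHz impactor, 15 kHz
    stem) and normalizes to the mallet peak.  Deterministic for a fixed
    seed.  Returns ``(pulse, impactor_trace, stem_trace)`` tuples.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    truth = _chain_with(dict(true_params), chain)
    datasets = []
    for pulse in pulses:
        res = simulate(truth, pulse)
        imp = res.impactor_force + noise_sd * pulse.peak_force * rng.standard_normal(len(res.time))
        stem = res.stem_force + noise_sd * pulse.peak_force * rng.standard_normal(len(res.time))
        imp = zero_phase_lowpass(normalize_to_mallet(imp, pulse.peak_force), res.sample_rate, CUTOFF_IMPACTOR)
        stem = zero_phase_lowpass(normalize_to_mallet(stem, pulse.peak_force), res.sample_rate, CUTOFF_STEM)
        datasets.append((pulse, imp, stem))
    return datasets


def screen_outliers(
    datasets: Sequence[tuple[ForcePulse, np.ndarray, np.ndarray]],
    threshold: float = 0.25,
) -> list[tuple[ForcePulse, np.ndarray, np.ndarray]]:
    """Drop datasets with distinctly different oscillatory behavior.

    A dataset is excluded when the dominant frequency of its impactor trace
    deviates more than ``threshold`` (relative) from the group median.
    """
    freqs = np.array(
        [dominant_frequency(imp, SAMPLE_RATE) for _, imp, _ in datasets]
    )
    median = np.median(freqs)
    keep = np.abs(freqs - median) <= threshold * median
    dropped = int((~keep).sum())
    if dropped:
        logger.info("outlier screen dropped %d of %d datasets", dropped, len(datasets))
    return [d for d, k in zip(datasets, keep) if k]


# ---------------------------------------------------------------------------
# SSE parameter fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of the SSE parameter optimization.

    ``params`` holds the fitted free parameters (SI); RMSEs are percent of
    the mallet peak per dataset; peak-time offsets are simulated-minus-
    measured first-peak times [s].
    """

    params: dict[str, float]
    rmse_impactor: list[float]
    rmse_stem: list[float]
    peak_offset_impactor: list[float]
    peak_offset_stem: list[float]
    sse_trajectory: list[float]
    success: bool
    message: str = ""

    def to_report(self) -> str:
        lines = ["fitted parameters (SI units):"]
        lines += [f"  {k} = {v:.6g}" for k, v in self.params.items()]
        lines.append(f"median RMSE impactor: {np.median(self.rmse_impactor):.3f} %")
        lines.append(f"median RMSE stem:     {np.median(self.rmse_stem):.3f} %")
        lines.append(f"converged: {self.success} ({self.message})")
        return "\n".join(lines)

    def rmse_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dataset": np.arange(len(self.rmse_impactor)),
                "rmse_impactor_pct": self.rmse_impactor,
                "rmse_stem_pct": self.rmse_stem,
                "peak_offset_impactor_s": self.peak_offset_impactor,
                "peak_offset_stem_s": self.peak_offset_stem,
            }
        )


def fit_parameters(
    datasets: Sequence[tuple[ForcePulse, np.ndarray, np.ndarray]],
    space: Optional[ParameterSpace] = None,
    chain: Optional[ChainConfig] = None,
    method: str = "auto",
    n_starts: int = 3,
    rng_seed: int = 0,
    max_nfev: Optional[int] = None,
    screen: bool = False,
) -> FitResult:
    """Identify the seven free chain parameters from measured force traces.

    Minimizes the summed squared error of the normalized impactor and stem
    forces over the windowed comparison interval of each dataset (the zero
    crossing before the first to the zero crossing after the second
    measured peak).  Simulated traces pass through the same per-PoM
    zero-phase filters as the measurements before comparison.  The
    optimization works on the logarithms of the (all-positive) parameters:
    the dominant ill-conditioning of the problem -- a common rescaling of
    the friction coefficients against the quadratic normal-force factor --
    is a straight valley in log space.

    ``method="auto"`` (default) warm-starts with a bounded trust-region
    least-squares pass from the supplied chain's nominal values and then
    descends the remaining ill-conditioned valley with an adaptive
    Nelder--Mead simplex (finite-difference gradients are too noisy there;
    the simplex elongates along the valley and is not).
    ``method="least-squares"`` stops after the trust-region pass;
    ``method="nelder-mead"`` is a pure bounded direct search with
    ``n_starts`` starts (nominal values plus random interior points).

    Raises
    ------
    FitError
        If the optimizer fails to converge; the best-so-far
        :class:`FitResult` is attached to the exception.
    """
    if len(datasets) == 0:
        raise ValueError("at least one dataset is required")
    if space is None:
        space = default_parameter_space()
    if chain is None:
        chain = build_default_chain()
    if screen:
        datasets = screen_outliers(datasets)
        if not datasets:
            raise ValueError("outlier screen removed all datasets")

    names = [n for n in FREE_PARAMETERS if n in space.free_names]
    if not names:
        raise ValueError("parameter space leaves no free parameters to fit")
    lo = np.log([space.ranges[n][0] for n in names])
    hi = np.log([space.ranges[n][1] for n in names])
    nominal = _chain_to_overrides(chain)
    z0 = np.clip(np.log([max(nominal[n], 1e-300) for n in names]), lo, hi)

    windows = []
    for _, imp, stem in datasets:
        windows.append((_evaluation_window(imp, False), _evaluation_window(stem, False)))

    sse_trajectory: list[float] = []

    def residuals(z: np.ndarray) -> np.ndarray:
        params = dict(zip(names, np.exp(np.clip(z, lo, hi))))
        for fixed_name, fixed_value in space.fixed.items():
            params.setdefault(fixed_name, fixed_value)
        trial = _chain_with(params, chain)
        out = []
        for (pulse, imp_meas, stem_meas), ((i0, i1), (s0, s1)) in zip(datasets, windows):
            imp, stem = _simulate_pom_traces(trial, pulse)
            out.append(imp[i0 : i1 + 1] - imp_meas[i0 : i1 + 1])
            out.append(stem[s0 : s1 + 1] - stem_meas[s0 : s1 + 1])
        r = np.concatenate(out)
        sse_trajectory.append(float(r @ r))
        return r

    def sse(z: np.ndarray) -> float:
        r = residuals(z)
        return float(r @ r)

    def simplex_descent(start: np.ndarray, maxfev: int):
        return optimize.minimize(
            sse,
            start,
            method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options={"maxfev": maxfev, "xatol": 1e-10, "fatol": 1e-16, "adaptive": True},
        )

    if method in ("auto", "least-squares"):
        sol = optimize.least_squares(
            residuals,
            z0,
            bounds=(lo, hi),
            diff_step=1e-2,
            xtol=1e-14,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=40 if method == "auto" else max_nfev,
        )
        z_best, success, message = sol.x, sol.success, sol.message
        if method == "auto":
            nm = simplex_descent(sol.x, max_nfev or 1200)
            z_best, message = nm.x, nm.message
            success = True  # warm start already feasible; simplex only improves
    elif method == "nelder-mead":
        rng = np.random.default_rng(rng_seed)
        starts = [z0] + [
            rng.uniform(lo + 0.1 * (hi - lo), hi - 0.1 * (hi - lo))
            for _ in range(max(0, n_starts - 1))
        ]
        best = None
        for start in starts:
            res = simplex_descent(start, max_nfev or 800)
            if best is None or res.fun < best.fun:
                best = res
        z_best, success, message = best.x, True, best.message
    else:
        raise ValueError(f"unknown fit method {method!r}")

    fitted = dict(zip(names, np.exp(np.clip(z_best, lo, hi))))
    full = dict(fitted)
    for fixed_name, fixed_value in space.fixed.items():
        full.setdefault(fixed_name, fixed_value)
    final_chain = _chain_with(full, chain)

    rmse_imp, rmse_stem, off_imp, off_stem = [], [], [], []
    for pulse, imp_meas, stem_meas in datasets:
        imp, stem = _simulate_pom_traces(final_chain, pulse)
        rmse_imp.append(rmse_window(imp, imp_meas, SAMPLE_RATE))
        rmse_stem.append(rmse_window(stem, stem_meas, SAMPLE_RATE))
        off_imp.append(
            extract_features(imp, SAMPLE_RATE).first_peak_time
            - extract_features(imp_meas, SAMPLE_RATE).first_peak_time
        )
        off_stem.append(
            extract_features(stem, SAMPLE_RATE).first_peak_time
            - extract_features(stem_meas, SAMPLE_RATE).first_peak_time
        )
    result = FitResult(
        params=fitted,
        rmse_impactor=rmse_imp,
        rmse_stem=rmse_stem,
        peak_offset_impactor=off_imp,
        peak_offset_stem=off_stem,
        sse_trajectory=sse_trajectory,
        success=bool(success),
        message=str(message),
    )
    if not result.success:
        raise FitError(f"optimizer did not converge: {message}", result)
    return result
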