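"""Signal conditioning and feature extraction for impaction force traces.

Mirrors the measurement-chain processing: zero-phase Butterworth low-pass
filtering (per-PoM cutoffs: mallet 20 kHz, impactor 10 kHz, stem 15 kHz),
normalization of every force to the peak of the corresponding mallet blow,
extraction of the first/second positive peaks with their period and the
delay from the mallet peak, and the windowed RMSE goodness-of-fit between a
simulated and a measured trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

__all__ = [
    "CUTOFF_MALLET",
    "CUTOFF_IMPACTOR",
    "CUTOFF_STEM",
    "FilterError",
    "FeatureError",
    "SignalFeatures",
    "zero_phase_lowpass",
    "normalize_to_mallet",
    "extract_features",
    "rmse_window",
    "find_positive_peaks",
    "dominant_frequency",
]

#: Low-pass cutoffs of the measurement chain, per position [Hz].
CUTOFF_MALLET = 20e3
CUTOFF_IMPACTOR = 10e3
CUTOFF_STEM = 15e3

#: Peak prominence threshold, as a fraction of the global maximum, used to
#: ignore numerical ripple when picking oscillation peaks.
PEAK_PROMINENCE_FRACTION = 0.01


class FilterError(ValueError):
    """Invalid filter specification."""


class FeatureError(ValueError):
    """Signal lacks the peaks needed for the requested feature or window."""


@dataclass(frozen=True)
class SignalFeatures:
    """Oscillation features of a normalized force trace.

    Peaks are fractions of the mallet peak (attenuation factors; values
    above 1 indicate amplification and are reported, not clamped).  The
    period is the time between the first and second positive peaks and is
    ``None`` for single-lobe signals; the delay is first-peak time minus
    mallet-peak time.
    """

    first_peak: float
    second_peak: Optional[float]
    period: Optional[float]  # s
    delay_from_mallet_peak: Optional[float]  # s
    first_peak_time: float  # s

    def __post_init__(self) -> None:
        if self.period is not None and not self.period > 0:
            raise FeatureError(f"period must be positive, got {self.period}")


def zero_phase_lowpass(
    x: np.ndarray, sample_rate: float, cutoff: float, order: int = 4
) -> np.ndarray:
    """Forward--backward Butterworth low-pass (zero net phase shift).

    A Butterworth filter of the given order is applied forward and backward
    (effective magnitude response squared), with reflective edge padding.
    Peak times of symmetric inputs are preserved exactly.
    """
    if not 0 < cutoff < sample_rate / 2:
        raise FilterError(
            f"cutoff must lie in (0, Nyquist) = (0, {sample_rate / 2:g}) Hz, got {cutoff:g}"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=sample_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def normalize_to_mallet(x: np.ndarray, mallet_peak: float) -> np.ndarray:
    """Express a force trace as a fraction of the mallet peak force."""
    if mallet_peak <= 0:
        raise ValueError(f"mallet peak must be positive, got {mallet_peak}")
    return np.asarray(x, dtype=float) / mallet_peak


def find_positive_peaks(
    x: np.ndarray, prominence_fraction: float = PEAK_PROMINENCE_FRACTION
) -> np.ndarray:
    """Indices of positive local maxima with prominence above the threshold."""
    x = np.asarray(x, dtype=float)
    top = float(np.max(x, initial=0.0))
    if top <= 0:
        return np.array([], dtype=int)
    idx, _ = sps.find_peaks(x, height=0.0, prominence=prominence_fraction * top)
    return idx


def extract_features(
    x: np.ndarray,
    sample_rate: float,
    mallet_peak_time: Optional[float] = None,
    prominence_fraction: float = PEAK_PROMINENCE_FRACTION,
) -> SignalFeatures:
    """First/second positive peaks, their period, and the delay from the mallet.

    Peaks are taken in time order (not by height): the oscillation features
    describe the leading cycles of the response.  With fewer than two peaks
    the period is reported missing; with none a :class:`FeatureError` is
    raised.
    """
    peaks = find_positive_peaks(x, prominence_fraction)
    if len(peaks) == 0:
        raise FeatureError("no positive peak above the prominence threshold")
    x = np.asarray(x, dtype=float)
    t1 = peaks[0] / sample_rate
    first = float(x[peaks[0]])
    if len(peaks) >= 2:
        second = float(x[peaks[1]])
        period = (peaks[1] - peaks[0]) / sample_rate
    else:
        second = None
        period = None
    delay = None if mallet_peak_time is None else t1 - mallet_peak_time
    return SignalFeatures(
        first_peak=first,
        second_peak=second,
        period=period,
        delay_from_mallet_peak=delay,
        first_peak_time=t1,
    )


def _evaluation_window(measured: np.ndarray, strict: bool) -> tuple[int, int]:
    """RMSE window on the measured trace.

    From the zero crossing before the first positive peak to the zero
    crossing after the second -- two positive half-waves and the negative
    one in between.  If the trace rides on an offset and never returns to
    zero after the second peak, the nearest local minimum substitutes for
    the missing crossing (strict=False) or a :class:`FeatureError` is
    raised (strict=True).
    """
    peaks = find_positive_peaks(measured)
    if len(peaks) < 2:
        raise FeatureError("measured trace needs two positive peaks to define the window")
    p1, p2 = int(peaks[0]), int(peaks[1])
    nonpos = measured <= 0.0
    before = np.flatnonzero(nonpos[: p1 + 1])
    start = int(before[-1]) if len(before) else 0
    after = np.flatnonzero(nonpos[p2:])
    if len(after):
        end = p2 + int(after[0])
    elif strict:
        raise FeatureError("no zero crossing after the second peak")
    else:
        tail = measured[p2:]
        end = p2 + (int(np.argmin(tail)) if len(tail) > 1 else 0)
    return start, end


def rmse_window(
    simulated: np.ndarray,
    measured: np.ndarray,
    sample_rate: float,
    strict: bool = False,
) -> float:
    """Windowed RMSE between two normalized traces, in percent of mallet peak.

    The window is located on the measured trace (zero crossing before its
    first positive peak to the zero crossing after its second) and applied
    to both signals.  Identical signals give 0; a constant offset c gives
    100*c.
    """
    simulated = np.asarray(simulated, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if simulated.shape != measured.shape:
        raise ValueError("simulated and measured traces must have equal length")
    start, end = _evaluation_window(measured, strict)
    diff = simulated[start : end + 1] - measured[start : end + 1]
    return 100.0 * float(np.sqrt(np.mean(diff**2)))


def dominant_frequency(
    x: np.ndarray, sample_rate: float, method: str = "peaks"
) -> float:
    """Dominant oscillation frequency of a force trace [Hz].

    ``method="peaks"`` (default): reciprocal of the first-to-second-peak
    period -- the natural reading for the few-cycle impact transients here.
    ``method="spectrum"``: location of the magnitude-spectrum maximum of
    the mean-removed signal, zero-padded for interpolation.
    """
    x = np.asarray(x, dtype=float)
    if method == "peaks":
        feats = extract_features(x, sample_rate)
        if feats.period is None:
            raise FeatureError("fewer than two peaks; period-based frequency undefined")
        return 1.0 / feats.period
    if method == "spectrum":
        y = x - x.mean()
        n = max(8 * len(y), 1 << 14)
        mag = np.abs(np.fft.rfft(y, n))
        freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
        return float(freqs[np.argmax(mag)])
    raise ValueError(f"unknown method {method!r}")
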