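"""Mallet force inputs.

A surgical mallet blow is a short, high force pulse (measured blows:
9247 N +/- 1513 N peak, 0.140 ms +/- 0.008 ms first-peak width).  Only the
first peak of the mallet force drives the chain; everything after it is
ringing of the instrumented mallet.  This module provides

* a synthetic half-sine pulse with the measured peak/width statistics (the
  canonical stand-in for a recorded blow),
* first-peak extraction from an arbitrary recorded waveform, and
* a random-blow generator emulating surgeon-to-surgeon variability
  (truncated-normal peak and width).

Waveforms read/write a two-column CSV (``time`` [s], ``force`` [N]) with a
header line; a single ``force`` column implies 800 kHz sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .chain_model import SAMPLE_RATE, SIM_DURATION

__all__ = [
    "PulseError",
    "ForcePulse",
    "synth_half_sine",
    "extract_first_peak",
    "random_blow",
    "DEFAULT_PEAK_FORCE",
    "DEFAULT_PEAK_SD",
    "DEFAULT_WIDTH",
    "DEFAULT_WIDTH_SD",
]

#: Mean measured mallet peak force [N].
DEFAULT_PEAK_FORCE = 9247.0
#: Standard deviation of the measured mallet peak force [N].
DEFAULT_PEAK_SD = 1513.0
#: Mean measured first-peak base width [s].
DEFAULT_WIDTH = 0.140e-3
#: Standard deviation of the first-peak width [s].
DEFAULT_WIDTH_SD = 0.008e-3

#: Threshold (fraction of the global maximum) treated as "zero" when
#: locating the crossings bounding the first peak; robust to sensor noise.
ZERO_CROSSING_FRACTION = 0.005


class PulseError(ValueError):
    """Invalid pulse parameters or unextractable first peak."""


@dataclass(frozen=True)
class ForcePulse:
    """A sampled axial force-versus-time signal on a uniform grid.

    ``peak_force``/``peak_time`` locate the global maximum; ``width`` is the
    base width of the lobe containing it (between threshold crossings).
    """

    samples: np.ndarray  # N
    sample_rate: float  # Hz
    peak_force: float = field(default=np.nan)
    peak_time: float = field(default=np.nan)
    width: float = field(default=np.nan)

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise PulseError("sample_rate must be positive")
        if np.isnan(self.peak_force):
            peak, t_peak, width = _characterize(self.samples, self.sample_rate)
            object.__setattr__(self, "peak_force", peak)
            object.__setattr__(self, "peak_time", t_peak)
            object.__setattr__(self, "width", width)

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    @property
    def duration(self) -> float:
        return (len(self.samples) - 1) / self.sample_rate

    def force_at(self, t: float) -> float:
        """Linearly interpolated force at time t [s]; zero outside the record."""
        x = t * self.sample_rate
        i = int(x)
        if x < 0.0 or i >= len(self.samples) - 1:
            return 0.0
        s = self.samples
        frac = x - i
        return s[i] * (1.0 - frac) + s[i + 1] * frac

    # -- CSV waveform I/O ---------------------------------------------------

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame({"time": self.times, "force": self.samples}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ForcePulse":
        """Read a waveform CSV (``time,force`` header; 800 kHz if no time column)."""
        df = pd.read_csv(path)
        cols = [c.strip().lower().split("[")[0].strip() for c in df.columns]
        df.columns = cols
        if "force" not in cols:
            raise PulseError(f"waveform CSV {path} lacks a 'force' column")
        force = df["force"].to_numpy(dtype=float)
        if "time" in cols:
            t = df["time"].to_numpy(dtype=float)
            dt = np.diff(t)
            if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
                raise PulseError(f"waveform CSV {path} must have a uniform time grid")
            rate = 1.0 / dt[0]
        else:
            rate = SAMPLE_RATE
        return cls(samples=force, sample_rate=rate)


def _characterize(samples: np.ndarray, sample_rate: float):
    """Peak force, peak time, and base width of the lobe holding the maximum."""
    if len(samples) == 0 or not np.any(samples > 0):
        return 0.0, 0.0, 0.0
    i_max = int(np.argmax(samples))
    peak = float(samples[i_max])
    thresh = ZERO_CROSSING_FRACTION * peak
    below = samples <= thresh
    left = i_max
    while left > 0 and not below[left]:
        left -= 1
    right = i_max
    while right < len(samples) - 1 and not below[right]:
        right += 1
    return peak, i_max / sample_rate, (right - left) / sample_rate


def synth_half_sine(
    peak: float = DEFAULT_PEAK_FORCE,
    width: float = DEFAULT_WIDTH,
    sample_rate: float = SAMPLE_RATE,
    start: float = 0.0,
    duration: Optional[float] = None,
) -> ForcePulse:
    """Synthetic half-sine mallet pulse.

    ``F(t) = peak * sin(pi * (t - start) / width)`` on
    ``[start, start + width]`` and zero elsewhere, sampled at
    ``sample_rate`` over ``duration`` (default: at least the 0.8 ms
    simulation window).  The impulse integral is ``2 * peak * width / pi``.
    """
    if peak <= 0:
        raise PulseError(f"pulse peak must be positive, got {peak}")
    if width <= 0:
        raise PulseError(f"pulse width must be positive, got {width}")
    if start < 0:
        raise PulseError("pulse start must be >= 0")
    if duration is None:
        duration = max(SIM_DURATION, start + width)
    n = int(round(duration * sample_rate)) + 1
    t = np.arange(n) / sample_rate
    phase = (t - start) / width
    samples = np.where(
        (phase >= 0.0) & (phase <= 1.0), peak * np.sin(np.pi * phase), 0.0
    )
    return ForcePulse(
        samples=samples,
        sample_rate=sample_rate,
        peak_force=peak,
        peak_time=start + width / 2.0,
        width=width,
    )


def extract_first_peak(waveform: ForcePulse) -> ForcePulse:
    """Isolate the first peak of a recorded mallet waveform.

    Returns the segment between the threshold crossings (0.5 % of the
    global maximum) bracketing the global maximum, zeroed elsewhere and
    padded to at least the simulation duration.  Idempotent on single-lobe
    inputs such as the synthetic half-sine.
    """
    s = waveform.samples
    if len(s) == 0 or not np.any(s > 0):
        raise PulseError("waveform has no positive peak to extract")
    i_max = int(np.argmax(s))
    thresh = ZERO_CROSSING_FRACTION * s[i_max]
    left = i_max
    while left > 0 and s[left - 1] > thresh:
        left -= 1
    right = i_max
    while right < len(s) - 1 and s[right + 1] > thresh:
        right += 1
    if left == 0 and s[0] > thresh and right == len(s) - 1 and s[-1] > thresh:
        raise PulseError("waveform does not cross zero around its maximum")
    n_out = max(len(s), int(round(SIM_DURATION * waveform.sample_rate)) + 1)
    out = np.zeros(n_out)
    out[left : right + 1] = s[left : right + 1]
    return ForcePulse(samples=out, sample_rate=waveform.sample_rate)


def random_blow(
    rng_seed: Union[int, np.random.Generator],
    peak_mean: float = DEFAULT_PEAK_FORCE,
    peak_sd: float = DEFAULT_PEAK_SD,
    width_mean: float = DEFAULT_WIDTH,
    width_sd: float = DEFAULT_WIDTH_SD,
    sample_rate: float = SAMPLE_RATE,
) -> ForcePulse:
    """A random half-sine blow with truncated-normal peak and width.

    Peak and width are drawn independently from normal distributions with
    the measured moments, truncated at zero (a blow cannot have negative
    force or duration).  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed

    def draw(mean: float, sd: float) -> float:
        if sd == 0:
            return mean
        a = (0.0 - mean) / sd
        return float(stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))

    return synth_half_sine(
        peak=draw(peak_mean, peak_sd),
        width=draw(width_mean, width_sd),
        sample_rate=sample_rate,
    )
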