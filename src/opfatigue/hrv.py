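"""Heart-rate-variability feature extraction from RR-interval series.

The ten features used throughout the package, in canonical order, are

    rri_mean, hr, sdnn, rmssd, lf, hf, lf_hf, sd1, sd2, sd2_sd1

i.e. the mean RR interval (ms), heart rate (bpm), the overall and
short-term time-domain variability measures, spectral band powers of the
RR tachogram in the standard low-frequency (0.04-0.15 Hz) and
high-frequency (0.15-0.40 Hz) bands (ms^2), and the Poincare-plot
descriptors SD1/SD2.

Conventions
-----------
* SDNN is reported with the sample (n-1) standard deviation.
* Inside the Poincare identities the population (n) convention is used,
  so that ``sd1**2 + sd2**2 == 2 * sdnn_pop**2`` holds exactly and
  ``sd1 == rmssd / sqrt(2)`` whenever successive differences have zero
  mean.
* Spectral powers are computed on the tachogram resampled at 4 Hz with
  cubic-spline interpolation and a Welch periodogram whose segment
  length is at most half the record.
* Undefined ratios (division by a zero denominator) are reported as NaN,
  never as infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

__all__ = [
    "RRISeries",
    "HRVFeatures",
    "FEATURE_NAMES",
    "time_domain",
    "poincare",
    "frequency_domain",
    "feature_vector",
]

#: canonical feature order; fixed, relied upon by the predictor.
FEATURE_NAMES: tuple[str, ...] = (
    "rri_mean",
    "hr",
    "sdnn",
    "rmssd",
    "lf",
    "hf",
    "lf_hf",
    "sd1",
    "sd2",
    "sd2_sd1",
)

MIN_BEATS = 30
MIN_SPECTRAL_DURATION_S = 120.0
#: physiological plausibility guard on single intervals (ms).
RR_MIN_MS, RR_MAX_MS = 300.0, 2000.0

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
RESAMPLE_HZ = 4.0


@dataclass(frozen=True)
class RRISeries:
    """One recording's RR intervals in milliseconds, with provenance labels."""

    intervals: np.ndarray
    subject_id: str = ""
    stage: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "intervals", arr)
        if arr.ndim != 1:
            raise ValueError("intervals must be a 1-D sequence")
        if arr.size and not np.all(arr > 0):
            raise ValueError("all RR intervals must be positive")

    @property
    def duration_s(self) -> float:
        return float(self.intervals.sum() / 1000.0)

    def __len__(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class HRVFeatures:
    """The 10-element HR/HRV feature vector for one subject-stage."""

    rri_mean: float
    hr: float
    sdnn: float
    rmssd: float
    lf: float
    hf: float
    lf_hf: float
    sd1: float
    sd2: float
    sd2_sd1: float
    subject_id: str = field(default="", compare=False)
    stage: int = field(default=0, compare=False)

    def as_array(self) -> np.ndarray:
        """Values in canonical order (see :data:`FEATURE_NAMES`)."""
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}


def _check_series(rri: RRISeries, min_beats: int = MIN_BEATS) -> np.ndarray:
    x = rri.intervals
    if len(x) < min_beats:
        raise ValueError(
            f"series has {len(x)} intervals; at least {min_beats} are "
            "required for feature extraction"
        )
    bad = (x < RR_MIN_MS) | (x > RR_MAX_MS)
    if bad.any():
        i = int(np.argmax(bad))
        raise ValueError(
            f"interval {x[i]:.1f} ms at position {i} lies outside the "
            f"physiological guard [{RR_MIN_MS:.0f}, {RR_MAX_MS:.0f}] ms"
        )
    return x


def time_domain(rri: RRISeries) -> tuple[float, float, float, float]:
    """Return ``(rri_mean, hr, sdnn, rmssd)`` in (ms, bpm, ms, ms)."""
    x = _check_series(rri)
    rri_mean = float(x.mean())
    hr = 60000.0 / rri_mean
    sdnn = float(x.std(ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
    return rri_mean, hr, sdnn, rmssd


def poincare(rri: RRISeries) -> tuple[float, float, float]:
    """Poincare-plot descriptors ``(sd1, sd2, sd2_sd1)``.

    sd1 is the dispersion perpendicular to the identity line of the
    lag-1 scatter plot, sd2 along it; both in ms.  ``sd2_sd1`` is NaN
    when sd1 is zero (a constant or perfectly linear ramp series).
    """
    x = _check_series(rri)
    d = np.diff(x)
    sd1 = float(np.sqrt(d.var(ddof=0) / 2.0))
    sdnn_pop = float(x.std(ddof=0))
    sd2 = float(np.sqrt(max(2.0 * sdnn_pop**2 - sd1**2, 0.0)))
    ratio = sd2 / sd1 if sd1 > 0 else math.nan
    return sd1, sd2, ratio


def frequency_domain(rri: RRISeries) -> tuple[float, float, float]:
    """Band powers ``(lf, hf, lf_hf)`` of the RR tachogram, in ms^2.

    The irregularly sampled tachogram (interval value at each beat time)
    is cubic-spline resampled at 4 Hz, mean-removed, and its power
    spectral density estimated by Welch's method; band powers are the
    PSD integrated over 0.04-0.15 Hz (LF) and 0.15-0.40 Hz (HF).
    """
    x = _check_series(rri)
    duration = rri.duration_s
    if duration < MIN_SPECTRAL_DURATION_S:
        raise ValueError(
            f"series spans {duration:.1f} s; spectral analysis requires at "
            f"least {MIN_SPECTRAL_DURATION_S:.0f} s"
        )
    t = np.cumsum(x) / 1000.0  # beat times, s
    spline = CubicSpline(t, x)
    tt = np.arange(t[0], t[-1], 1.0 / RESAMPLE_HZ)
    xx = spline(tt)
    xx = xx - xx.mean()
    nperseg = min(len(xx) // 2, 512)
    freqs, psd = welch(xx, fs=RESAMPLE_HZ, nperseg=nperseg, detrend="constant")
    lf = _band_power(freqs, psd, *LF_BAND)
    hf = _band_power(freqs, psd, *HF_BAND)
    ratio = lf / hf if hf > 0 else math.nan
    return lf, hf, ratio


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    mask = (freqs >= lo) & (freqs < hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], freqs[mask]))


def feature_vector(rri: RRISeries) -> HRVFeatures:
    """All ten canonical HR/HRV features for one series."""
    rri_mean, hr, sdnn, rmssd = time_domain(rri)
    sd1, sd2, sd2_sd1 = poincare(rri)
    lf, hf, lf_hf = frequency_domain(rri)
    return HRVFeatures(
        rri_mean=rri_mean,
        hr=hr,
        sdnn=sdnn,
        rmssd=rmssd,
        lf=lf,
        hf=hf,
        lf_hf=lf_hf,
        sd1=sd1,
        sd2=sd2,
        sd2_sd1=sd2_sd1,
        subject_id=rri.subject_id,
        stage=rri.stage,
    )
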