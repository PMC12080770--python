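"""Synthetic graded-treadmill cohort generator.

Emulates a graded exercise study: each subject walks/runs consecutive
treadmill stages of fixed length, starting at 4 km/h and speeding up by
1 km/h per stage.  After every stage the subject reports a Borg 6-20
rating of perceived exertion (RPE) and performs a simple reaction-time
test, while the stage's ECG-derived RR intervals are recorded.  The
default protocol (6 subjects x 7 stages) yields 42 observations.

Ground truth
------------
The latent fatigue of subject *s* at stage *k* is the heart-rate reserve
fraction used at that stage,

    f = (HR - HR_rest) / (HR_max - HR_rest),   clipped to [0, 1],

which is monotone in stage by construction.  All observable channels are
driven by f:

* heart rate rises linearly with treadmill speed;
* SDNN falls with the shortening beat and with f (vagal withdrawal);
* the LF/HF ratio rises in f (sympathetic predominance);
* Borg rises linearly in f (integer, clipped to [6, 20]);
* reaction time lengthens as ``baseline_rt * (1 + 0.5 f)``.

RR series are synthesised as a mean interval plus two sinusoidal
modulations at the centres of the standard LF (0.10 Hz) and HF (0.25 Hz)
bands -- making the band powers analytically attributable -- plus white
jitter, with total standard deviation matching the requested SDNN.

Noise channels (``noise_sd``): ``borg`` (RPE units), ``rt`` (ms) and
``rr`` (fraction of RR variance carried by white jitter instead of the
sinusoids).  Setting all three to zero gives noise-free observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hrv import RRISeries

__all__ = [
    "ProtocolConfig",
    "SubjectProfile",
    "LatentFatigue",
    "DEFAULT_NOISE_SD",
    "simulate_rr",
    "simulate_cohort",
]

# Default observation noise; calibrated so that on the default protocol
# roughly 7% of the variance of the composite fatigue index cannot be
# explained from the HRV features (see docs/methods.md).
DEFAULT_NOISE_SD: dict[str, float] = {"borg": 0.5, "rt": 8.0, "rr": 0.1}

LF_CARRIER_HZ = 0.10
HF_CARRIER_HZ = 0.25


@dataclass(frozen=True)
class ProtocolConfig:
    """Graded-treadmill protocol: stage count, length and speed ramp."""

    n_subjects: int = 6
    n_stages: int = 7
    stage_minutes: float = 4.0
    start_speed: float = 4.0  # km/h
    speed_increment: float = 1.0  # km/h per stage
    seed: int = 0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_SD)
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects: must be >= 1")
        if self.n_stages < 2:
            raise ValueError("n_stages: must be >= 2")
        if self.stage_minutes <= 0:
            raise ValueError("stage_minutes: must be > 0")
        if self.start_speed <= 0:
            raise ValueError("start_speed: must be > 0")
        if self.speed_increment < 0:
            raise ValueError("speed_increment: must be >= 0")
        bad = {k: v for k, v in self.noise_sd.items() if v < 0}
        if bad:
            raise ValueError(f"noise_sd: negative entries {bad}")

    def speed_at(self, stage: int) -> float:
        """Treadmill speed (km/h) at 1-based stage number."""
        return self.start_speed + (stage - 1) * self.speed_increment


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject physiology driving the observable channels."""

    subject_id: str
    resting_hr: float  # bpm
    max_hr: float  # bpm
    hr_slope: float  # bpm per km/h above start speed
    baseline_sdnn: float  # ms, at rest-like stage 1
    baseline_rt: float  # ms, unfatigued simple reaction time
    borg_slope: float  # RPE units per stage
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))

    def __post_init__(self) -> None:
        if not (50.0 <= self.resting_hr <= 90.0):
            raise ValueError("resting_hr: must lie in [50, 90] bpm")
        if self.max_hr <= self.resting_hr:
            raise ValueError("max_hr: must exceed resting_hr")
        if any(v < 0 for v in self.noise_sd.values()):
            raise ValueError("noise_sd: all entries must be >= 0")

    def hr_at(self, speed: float, start_speed: float) -> float:
        hr = self.resting_hr + self.hr_slope * (speed - start_speed)
        return min(hr, self.max_hr)

    def fatigue_at(self, speed: float, start_speed: float) -> float:
        """Heart-rate-reserve fraction in use at this speed, in [0, 1]."""
        hr = self.hr_at(speed, start_speed)
        f = (hr - self.resting_hr) / (self.max_hr - self.resting_hr)
        return float(np.clip(f, 0.0, 1.0))


@dataclass(frozen=True)
class LatentFatigue:
    """Ground-truth fatigue per subject-stage (long format, one row each)."""

    table: pd.DataFrame  # columns: subject, stage, true_fatigue

    def for_subject(self, subject_id: str) -> np.ndarray:
        sub = self.table[self.table["subject"] == subject_id]
        return sub.sort_values("stage")["true_fatigue"].to_numpy()


def simulate_rr(
    hr_target: float,
    sdnn_target: float,
    lf_hf_target: float,
    duration: float,
    rng: np.random.Generator | int,
    jitter_fraction: float = 0.2,
    subject_id: str = "",
    stage: int = 0,
) -> RRISeries:
    """Synthesise an RR series with prescribed HR, SDNN and LF/HF.

    The series is ``RR(t) = 60000/hr + a_lf sin(2 pi 0.10 t + p1)
    + a_hf sin(2 pi 0.25 t + p2) + e``, with the sinusoid amplitudes in
    the ratio ``sqrt(lf_hf_target)`` so the LF:HF band-power ratio of
    the noise-free part equals ``lf_hf_target``, and white jitter *e*
    carrying ``jitter_fraction`` of the total variance ``sdnn_target**2``.

    Parameters
    ----------
    hr_target : target mean heart rate, bpm (> 0).
    sdnn_target : target standard deviation of the intervals, ms.
        Zero yields a perfectly constant series.
    lf_hf_target : target LF/HF band-power ratio of the modulation (> 0).
    duration : recording length, seconds (>= 60, and long enough for
        at least 30 beats).
    rng : seeded generator or integer seed.
    jitter_fraction : share of the RR variance given to white jitter
        rather than the two sinusoids, in [0, 1].
    """
    if hr_target <= 0:
        raise ValueError("hr_target must be > 0")
    if sdnn_target < 0:
        raise ValueError("sdnn_target must be >= 0")
    if lf_hf_target <= 0:
        raise ValueError("lf_hf_target must be > 0")
    if duration < 60:
        raise ValueError("duration must be >= 60 s")
    if not 0.0 <= jitter_fraction <= 1.0:
        raise ValueError("jitter_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    mean_rr = 60000.0 / hr_target
    if duration * 1000.0 / mean_rr < 30:
        raise ValueError(
            f"duration {duration:.0f} s holds fewer than 30 beats at "
            f"{hr_target:.0f} bpm"
        )

    sine_var = (1.0 - jitter_fraction) * sdnn_target**2
    jitter_var = jitter_fraction * sdnn_target**2
    jitter_sd = np.sqrt(jitter_var)
    # The white jitter spreads its variance over [0, f_beat/2] and so
    # contributes to both bands; choose the tone variances s_lf, s_hf
    # (power a^2/2 each) so the total expected band-power ratio,
    # (s_lf + J_lf) / (s_hf + J_hf), equals lf_hf_target.
    half_beat_rate = hr_target / 60.0 / 2.0
    j_lf = jitter_var * (0.15 - 0.04) / half_beat_rate
    j_hf = jitter_var * (0.40 - 0.15) / half_beat_rate
    s_hf = (sine_var - lf_hf_target * j_hf + j_lf) / (1.0 + lf_hf_target)
    s_hf = float(np.clip(s_hf, 0.0, sine_var))
    s_lf = sine_var - s_hf
    a_lf = np.sqrt(2.0 * s_lf)
    a_hf = np.sqrt(2.0 * s_hf)
    phase_lf, phase_hf = rng.uniform(0.0, 2.0 * np.pi, size=2)

    intervals: list[float] = []
    t = 0.0
    while t < duration:
        rr = (
            mean_rr
            + a_lf * np.sin(2.0 * np.pi * LF_CARRIER_HZ * t + phase_lf)
            + a_hf * np.sin(2.0 * np.pi * HF_CARRIER_HZ * t + phase_hf)
        )
        if jitter_sd > 0:
            rr += rng.normal(0.0, jitter_sd)
        # keep every beat physiologically possible
        rr = float(np.clip(rr, 305.0, 1995.0))
        intervals.append(rr)
        t += rr / 1000.0
    return RRISeries(np.array(intervals), subject_id=subject_id, stage=stage)


def _draw_profile(
    subject_id: str, rng: np.random.Generator, noise_sd: dict[str, float]
) -> SubjectProfile:
    resting = rng.uniform(55.0, 75.0)
    max_hr = rng.uniform(185.0, 195.0)
    # peak heart-rate-reserve use at the final stage of the default ramp;
    # slope expressed per km/h so HR never reaches max_hr within protocol.
    peak_fraction = rng.uniform(0.78, 0.92)
    slope = peak_fraction * (max_hr - resting) / 6.0
    return SubjectProfile(
        subject_id=subject_id,
        resting_hr=resting,
        max_hr=max_hr,
        hr_slope=slope,
        baseline_sdnn=rng.uniform(45.0, 70.0),
        baseline_rt=rng.uniform(220.0, 300.0),
        borg_slope=rng.uniform(1.9, 2.3),
        noise_sd=dict(noise_sd),
    )


def simulate_cohort(
    config: ProtocolConfig,
) -> tuple[list[RRISeries], pd.DataFrame, LatentFatigue]:
    """Simulate a full graded-treadmill cohort.

    Returns one :class:`~opfatigue.hrv.RRISeries` per subject-stage, the
    observation table (columns ``subject, stage, speed_kmh, borg, rt_ms,
    true_fatigue``), and the latent fatigue ground truth.  Identical
    configs (including seed) reproduce identical output.
    """
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)

    series: list[RRISeries] = []
    rows: list[dict] = []
    for i, sub_ss in enumerate(subject_seeds):
        subject_id = f"S{i + 1}"
        profile_ss, stages_ss = sub_ss.spawn(2)
        profile = _draw_profile(
            subject_id, np.random.default_rng(profile_ss), config.noise_sd
        )
        stage_seeds = stages_ss.spawn(config.n_stages)
        for k, stage_ss in enumerate(stage_seeds, start=1):
            rng = np.random.default_rng(stage_ss)
            speed = config.speed_at(k)
            f = profile.fatigue_at(speed, config.start_speed)
            hr = profile.hr_at(speed, config.start_speed)
            # variability shrinks both with the shorter beat and with
            # vagal withdrawal as fatigue accumulates
            sdnn = (
                profile.baseline_sdnn
                * (profile.resting_hr / hr)
                * (1.0 - 0.5 * f)
            )
            lf_hf = 1.5 + 3.5 * f
            rr = simulate_rr(
                hr_target=hr,
                sdnn_target=sdnn,
                lf_hf_target=lf_hf,
                duration=config.stage_minutes * 60.0,
                rng=rng,
                jitter_fraction=profile.noise_sd.get("rr", 0.0),
                subject_id=subject_id,
                stage=k,
            )
            series.append(rr)

            borg_raw = 6.0 + profile.borg_slope * (k - 1)
            if profile.noise_sd.get("borg", 0.0) > 0:
                borg_raw += rng.normal(0.0, profile.noise_sd["borg"])
            borg = int(np.clip(np.rint(borg_raw), 6, 20))

            rt = profile.baseline_rt * (1.0 + 0.5 * f)
            if profile.noise_sd.get("rt", 0.0) > 0:
                rt += rng.normal(0.0, profile.noise_sd["rt"])
            rt = max(rt, 1.0)

            rows.append(
                {
                    "subject": subject_id,
                    "stage": k,
                    "speed_kmh": speed,
                    "borg": borg,
                    "rt_ms": rt,
                    "true_fatigue": f,
                }
            )

    obs = pd.DataFrame(rows)
    latent = LatentFatigue(obs[["subject", "stage", "true_fatigue"]].copy())
    return series, obs, latent


def zero_noise(config: ProtocolConfig) -> ProtocolConfig:
    """A copy of *config* with every observation-noise channel at zero."""
    return replace(config, noise_sd={k: 0.0 for k in config.noise_sd})
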