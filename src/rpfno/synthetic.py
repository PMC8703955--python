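"""Synthetic quasi-periodic motion streams and fall transients.

The study population this package targets (a handful of volunteers walking
and running with a thigh-mounted smartphone) is emulated here by a harmonic
gait model: each axis of the gyroscope is a sum of 2-3 harmonics of a
subject-specific stride frequency with axis-specific amplitudes and phases,
plus white measurement noise.  Walking subjects draw their fundamental from
1.4-2.0 Hz, running subjects from 2.4-3.0 Hz, which brackets typical human
stride rates.  Distinct subjects get distinct frequencies and amplitude
patterns so that personalized models are distinguishable downstream.

Falls are modelled as the simplest signal that is out-of-distribution for
periodic gait: a short high-amplitude broadband burst (the impact) followed
by near-zero signal (lying still).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .streams import SensorStream

MOTION_KINDS = ("walking", "running")

#: Stride-frequency ranges per motion, Hz.
FREQ_RANGES = {"walking": (1.4, 2.0), "running": (2.4, 3.0)}

#: Per-axis harmonic amplitude range, rad/s — plausible thigh-gyro magnitudes;
#: only the relative scale matters downstream.
AMPLITUDE_RANGE = (0.5, 3.0)

#: Measurement-noise standard deviation range, rad/s.
NOISE_SD_RANGE = (0.03, 0.08)

#: Minimum pairwise stride-frequency gap enforced across a cohort, Hz.
MIN_FREQ_GAP = 0.05

#: Gravity magnitude used for the accelerometer offset, m/s^2.
GRAVITY = 9.81


@dataclass(frozen=True)
class SubjectProfile:
    """Harmonic gait parameters for one synthetic subject."""

    subject_id: str
    motion_kind: str
    fundamental_freq: float
    harmonic_amplitudes: tuple  # per axis: tuple of amplitudes, rad/s
    harmonic_phases: tuple  # per axis: tuple of radians, same lengths
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.motion_kind not in MOTION_KINDS:
            raise ValueError(
                f"unknown motion_kind {self.motion_kind!r}; expected one of {MOTION_KINDS}"
            )
        if not self.fundamental_freq > 0:
            raise ValueError("fundamental_freq must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if len(self.harmonic_amplitudes) != 3 or len(self.harmonic_phases) != 3:
            raise ValueError("amplitudes/phases must be given for all three axes")
        for amps, phases in zip(self.harmonic_amplitudes, self.harmonic_phases):
            if len(amps) != len(phases):
                raise ValueError("each axis needs matching amplitude/phase counts")
            if not any(a != 0 for a in amps):
                raise ValueError("each axis needs at least one nonzero amplitude")


@dataclass
class FallAnnotation:
    """Ground-truth labelling of an injected fall."""

    onset_index: int
    burst_duration: int
    label_track: np.ndarray  # per-sample: "normal" or "fall"

    def __post_init__(self) -> None:
        self.label_track = np.asarray(self.label_track)
        if not 0 <= self.onset_index < self.label_track.shape[0]:
            raise ValueError("onset_index must lie within the stream")


def _draw_profile(subject_id: str, motion_kind: str, seed: int) -> SubjectProfile:
    rng = np.random.default_rng(seed)
    lo, hi = FREQ_RANGES[motion_kind]
    freq = float(rng.uniform(lo, hi))
    amps, phases = [], []
    for _axis in range(3):
        n_h = int(rng.integers(2, 4))  # 2 or 3 harmonics
        a = rng.uniform(*AMPLITUDE_RANGE, size=n_h)
        # taper higher harmonics so the fundamental dominates, as in real gait
        a = a / (1.0 + np.arange(n_h))
        amps.append(tuple(float(v) for v in a))
        phases.append(tuple(float(v) for v in rng.uniform(0, 2 * np.pi, size=n_h)))
    noise_sd = float(rng.uniform(*NOISE_SD_RANGE))
    return SubjectProfile(
        subject_id=subject_id,
        motion_kind=motion_kind,
        fundamental_freq=freq,
        harmonic_amplitudes=tuple(amps),
        harmonic_phases=tuple(phases),
        noise_sd=noise_sd,
        seed=seed,
    )


def make_subject_profile(subject_id: str, motion_kind: str, seed: int) -> SubjectProfile:
    """Deterministically draw one subject's gait parameters from ``seed``."""
    if motion_kind not in MOTION_KINDS:
        raise ValueError(
            f"unknown motion_kind {motion_kind!r}; expected one of {MOTION_KINDS}"
        )
    return _draw_profile(subject_id, motion_kind, seed)


def make_cohort(
    n_subjects: int,
    motion_kind: str,
    seed: int,
    min_freq_gap: float = MIN_FREQ_GAP,
) -> list:
    """Draw ``n_subjects`` profiles with pairwise stride-frequency gaps.

    Profiles whose fundamental lands within ``min_freq_gap`` Hz of an already
    drawn subject are redrawn (with a fresh derived seed) until the cohort is
    separated, so that cross-subject evaluation is well posed.
    """
    if motion_kind not in MOTION_KINDS:
        raise ValueError(
            f"unknown motion_kind {motion_kind!r}; expected one of {MOTION_KINDS}"
        )
    profiles: list = []
    freqs: list = []
    next_seed = seed
    for i in range(n_subjects):
        while True:
            prof = _draw_profile(f"s{i + 1}", motion_kind, next_seed)
            next_seed += 1
            if all(abs(prof.fundamental_freq - f) >= min_freq_gap for f in freqs):
                break
        profiles.append(prof)
        freqs.append(prof.fundamental_freq)
    return profiles


def generate_motion_stream(
    profile: SubjectProfile,
    duration_s: float = 60.0,
    rate_hz: float = 30.0,
    sensor_kind: str = "gyroscope",
) -> SensorStream:
    """Synthesize one quasi-periodic stream for a subject.

    Each axis is ``sum_h A_h sin(2 pi h f t + phi_h)`` plus Gaussian noise of
    standard deviation ``profile.noise_sd``; the harmonic index ``h`` runs
    from 1.  60 s at 30 Hz yields exactly 1800 samples.  Accelerometer
    streams use the same harmonic model with a gravity offset on the z axis.
    """
    if not duration_s > 0 or not rate_hz > 0:
        raise ValueError("duration_s and rate_hz must be positive")
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    rng = np.random.default_rng(profile.seed + 1_000_003)
    axes = np.zeros((3, n))
    for ax in range(3):
        amps = profile.harmonic_amplitudes[ax]
        phases = profile.harmonic_phases[ax]
        for h, (a, ph) in enumerate(zip(amps, phases), start=1):
            axes[ax] += a * np.sin(2 * np.pi * h * profile.fundamental_freq * t + ph)
        if profile.noise_sd > 0:
            axes[ax] += rng.normal(0.0, profile.noise_sd, size=n)
    if sensor_kind == "accelerometer":
        axes[2] += GRAVITY
    return SensorStream(
        timestamps=t,
        axes=axes,
        rate_hz=float(rate_hz),
        sensor_kind=sensor_kind,
        meta={"subject_id": profile.subject_id, "motion": profile.motion_kind},
    )


def companion_accelerometer_stream(
    profile: SubjectProfile, duration_s: float = 60.0, rate_hz: float = 30.0
) -> SensorStream:
    """An accelerometer stream time-locked to the subject's gyro stream.

    Re-uses the subject's stride frequency but draws fresh amplitudes and
    phases (derived seed), then adds the gravity offset; used for the
    cross-recurrence-plot sensor-fusion experiments.
    """
    accel_profile = _draw_profile(
        profile.subject_id, profile.motion_kind, profile.seed + 7_777
    )
    accel_profile = SubjectProfile(
        subject_id=profile.subject_id,
        motion_kind=profile.motion_kind,
        fundamental_freq=profile.fundamental_freq,  # same gait cycle
        harmonic_amplitudes=accel_profile.harmonic_amplitudes,
        harmonic_phases=accel_profile.harmonic_phases,
        noise_sd=accel_profile.noise_sd,
        seed=profile.seed + 7_777,
    )
    return generate_motion_stream(
        accel_profile, duration_s, rate_hz, sensor_kind="accelerometer"
    )


def inject_fall(
    stream: SensorStream,
    onset_s: float,
    burst_duration_s: float = 0.5,
    seed: int = 0,
):
    """Overwrite a stream with a fall transient starting at ``onset_s``.

    From the onset, each axis carries a broadband burst whose amplitude is
    3.5x that axis' pre-onset maximum for ``burst_duration_s`` seconds (the
    impact), followed by near-zero signal until the end of the stream (post
    impact rest).  Returns the modified stream and a :class:`FallAnnotation`
    labelling burst and rest samples as ``"fall"``.
    """
    rate = stream.rate_hz
    onset = int(round(onset_s * rate))
    burst = int(round(burst_duration_s * rate))
    n = stream.n_samples
    if onset < 1 or onset + burst > n:
        raise ValueError(
            f"fall onset {onset_s} s (sample {onset}) does not leave room for a "
            f"{burst}-sample burst in a {n}-sample stream"
        )
    rng = np.random.default_rng(seed + 424_243)
    axes = stream.axes.copy()
    pre_max = np.abs(axes[:, :onset]).max(axis=1)
    pre_max = np.maximum(pre_max, 1e-6)
    for ax in range(3):
        # every burst sample is at least 3x the pre-onset peak, with random
        # sign flips making the burst broadband
        magnitudes = rng.uniform(3.0, 4.0, size=burst) * pre_max[ax]
        signs = rng.choice([-1.0, 1.0], size=burst)
        axes[ax, onset : onset + burst] = magnitudes * signs
        axes[ax, onset + burst :] = rng.normal(0.0, 0.02 * pre_max[ax], size=n - onset - burst)
    labels = np.array(["normal"] * n, dtype=object)
    labels[onset:] = "fall"
    out = SensorStream(
        timestamps=stream.timestamps.copy(),
        axes=axes,
        rate_hz=rate,
        sensor_kind=stream.sensor_kind,
        meta=dict(stream.meta, fall_onset=onset),
    )
    return out, FallAnnotation(onset_index=onset, burst_duration=burst, label_track=labels)


def write_annotation(annotation: FallAnnotation, path) -> None:
    """Write a fall annotation as a two-column ``index,label`` CSV."""
    import pandas as pd

    pd.DataFrame(
        {"index": np.arange(annotation.label_track.shape[0]), "label": annotation.label_track}
    ).to_csv(path, index=False)
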