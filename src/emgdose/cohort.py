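"""Synthetic surface-EMG cohort generation.

Emulates a shoulder-rehabilitation acquisition protocol: a cohort of
subjects, each recorded in two sessions, performing four standardized
movements (scaption, internal rotation at the side, external rotation at
the side, external rotation at 90° abduction) while six muscles are
recorded at 2000 Hz — three superficial (medial deltoid, posterior
deltoid, trapezius) and three deep (supraspinatus, infraspinatus, teres
minor).

The signal model for channel *m* during movement *v* is

    x_m(t) = g[m, v] · c_subj · env(t) · (ρ·z(t) + √(1−ρ²)·n_m(t))
             + σ₀ · w_m(t)

where ``g`` is a per-(muscle, movement) amplitude gain in μV, ``c_subj`` a
per-subject log-normal scale factor shared across that subject's sessions
and movements, ``env`` a repeated raised-cosine burst envelope emulating
exercise repetitions, ``z`` a latent drive shared by all channels (its
weight ρ plants learnable inter-muscle correlation), ``n_m``/``w_m``
independent noises, and ``σ₀`` an additive instrument-noise floor. All
stochastic terms are band-limited to 20–450 Hz, so no 50/60 Hz line
component exists to notch out.

Everything is deterministic given the configuration seed: the same
(seed, subject, session, movement) always reproduces the identical
signal bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sps

__all__ = [
    "SUPERFICIAL_MUSCLES",
    "DEEP_MUSCLES",
    "MUSCLES",
    "MOVEMENTS",
    "LAYER_MAP",
    "PRIMARY_ACTIVATION",
    "CohortConfig",
    "EMGRecording",
    "make_default_gain_table",
    "generate_recording",
    "generate_cohort",
    "subject_scale_factor",
    "repetition_envelope",
]

# Canonical muscle set, superficial first, matching the instrumented layout.
SUPERFICIAL_MUSCLES: tuple[str, ...] = (
    "medial deltoid",
    "posterior deltoid",
    "trapezius",
)
DEEP_MUSCLES: tuple[str, ...] = (
    "supraspinatus",
    "infraspinatus",
    "teres minor",
)
MUSCLES: tuple[str, ...] = SUPERFICIAL_MUSCLES + DEEP_MUSCLES

LAYER_MAP: dict[str, str] = {
    **{m: "superficial" for m in SUPERFICIAL_MUSCLES},
    **{m: "deep" for m in DEEP_MUSCLES},
}

# Canonical movement order; downstream label encoding follows this order.
MOVEMENTS: tuple[str, ...] = (
    "scaption",
    "internal rotation at side",
    "external rotation at side",
    "external rotation at 90° abduction",
)

# Which muscles each movement primarily activates, by anatomical consensus
# for these four exercises.
PRIMARY_ACTIVATION: dict[str, tuple[str, ...]] = {
    "scaption": (
        "medial deltoid",
        "trapezius",
        "supraspinatus",
        "infraspinatus",
        "teres minor",
    ),
    "internal rotation at side": ("medial deltoid",),
    "external rotation at side": (
        "posterior deltoid",
        "infraspinatus",
        "teres minor",
    ),
    "external rotation at 90° abduction": (
        "posterior deltoid",
        "supraspinatus",
        "teres minor",
    ),
}


def make_default_gain_table(
    high: float = 1.0,
    low: float = 0.2,
    movements: Sequence[str] = MOVEMENTS,
    muscles: Sequence[str] = MUSCLES,
    activation: Mapping[str, Sequence[str]] = PRIMARY_ACTIVATION,
) -> dict[tuple[str, str], float]:
    """Amplitude gain (μV) per (muscle, movement) cell.

    Primarily activated muscles receive ``high``, the rest ``low``, so the
    activation pattern is recoverable by a learner yet overlapping enough
    to be non-trivial. The table is complete over all muscle × movement
    cells.
    """
    if high < 0 or low < 0:
        raise ValueError("gains must be nonnegative")
    table: dict[tuple[str, str], float] = {}
    for movement in movements:
        active = set(activation.get(movement, ()))
        for muscle in muscles:
            table[(muscle, movement)] = high if muscle in active else low
    return table


@dataclass(frozen=True)
class EMGRecording:
    """One subject/session/movement block of multi-channel sEMG.

    ``channels`` maps muscle name → 1-D signal in μV, all the same length.
    ``segments`` holds the lengths of contiguous recording segments (a
    single segment for a raw trial; one per session after merging) so that
    later windowing never straddles a session boundary.
    """

    subject_id: str
    session_id: str
    movement: str
    sampling_rate: float
    channels: dict[str, np.ndarray]
    layer_map: dict[str, str] = field(default_factory=lambda: dict(LAYER_MAP))
    segments: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channels:
            raise ValueError("recording has no channels")
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) != 1:
            raise ValueError("all channels must have equal length")
        (n,) = lengths
        if n == 0:
            raise ValueError("zero-length signals are not allowed")
        if not self.segments:
            object.__setattr__(self, "segments", (n,))
        if sum(self.segments) != n:
            raise ValueError("segment lengths must sum to the signal length")

    @property
    def muscles(self) -> tuple[str, ...]:
        return tuple(self.channels)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def as_array(self) -> np.ndarray:
        """Channels stacked as a (n_muscles, n_samples) array."""
        return np.stack([self.channels[m] for m in self.channels])


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the acquisition protocol being emulated: 8 subjects,
    2 sessions each, the four shoulder movements, six muscles at 2000 Hz
    with 20–450 Hz band-limited content. ``shared_drive_correlation`` (ρ)
    controls how strongly co-active channels share a latent drive and
    hence how learnable cross-muscle prediction is. Trial duration
    defaults to 30 s per movement per session.
    """

    n_subjects: int = 8
    n_sessions: int = 2
    movements: tuple[str, ...] = MOVEMENTS
    muscles: tuple[str, ...] = MUSCLES
    layer_map: dict[str, str] = field(default_factory=lambda: dict(LAYER_MAP))
    sampling_rate: float = 2000.0
    duration_per_trial: float = 30.0
    gain_table: dict[tuple[str, str], float] = field(
        default_factory=make_default_gain_table
    )
    shared_drive_correlation: float = 0.6
    subject_scale_sd: float = 0.2
    noise_floor: float = 0.05
    band: tuple[float, float] = (20.0, 450.0)
    repetition_period: float = 3.0
    envelope_tonic: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_sessions < 1:
            raise ValueError("n_subjects and n_sessions must be >= 1")
        if self.sampling_rate <= 0 or self.duration_per_trial <= 0:
            raise ValueError("sampling_rate and duration_per_trial must be > 0")
        rho = self.shared_drive_correlation
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"shared_drive_correlation must be in [0, 1], got {rho}")
        lo, hi = self.band
        if not (0.0 < lo < hi < self.sampling_rate / 2):
            raise ValueError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist "
                f"({self.sampling_rate / 2} Hz)"
            )
        for muscle in self.muscles:
            for movement in self.movements:
                gain = self.gain_table.get((muscle, movement))
                if gain is None:
                    raise ValueError(
                        f"gain_table missing cell ({muscle!r}, {movement!r})"
                    )
                if gain < 0:
                    raise ValueError(
                        f"gain_table[{muscle!r}, {movement!r}] is negative"
                    )
        if self.noise_floor < 0:
            raise ValueError("noise_floor must be nonnegative")
        if self.subject_scale_sd < 0:
            raise ValueError("subject_scale_sd must be nonnegative")
        if not 0.0 <= self.envelope_tonic <= 1.0:
            raise ValueError("envelope_tonic must be in [0, 1]")

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.duration_per_trial * self.sampling_rate))

    def subject_ids(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1:02d}" for i in range(self.n_subjects))

    def session_ids(self) -> tuple[str, ...]:
        return tuple(f"sess{i + 1}" for i in range(self.n_sessions))


def repetition_envelope(
    n_samples: int,
    sampling_rate: float,
    period: float = 3.0,
    tonic: float = 0.1,
) -> np.ndarray:
    """Repeated raised-cosine burst amplitude envelope in [tonic, 1].

    Emulates cyclic exercise repetitions with one burst per ``period``
    seconds plus a small tonic baseline for stabilizing co-contraction.
    """
    t = np.arange(n_samples) / sampling_rate
    return tonic + (1.0 - tonic) * np.sin(np.pi * t / period) ** 2


def _bandlimited_noise(
    rng: np.random.Generator,
    n_samples: int,
    band: tuple[float, float],
    sampling_rate: float,
) -> np.ndarray:
    """Zero-phase band-passed white noise, normalized to unit RMS."""
    white = rng.standard_normal(n_samples)
    sos = _sps.butter(4, band, btype="bandpass", fs=sampling_rate, output="sos")
    x = _sps.sosfiltfilt(sos, white)
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:  # pragma: no cover - cannot occur for nondegenerate noise
        return x
    return x / rms


def _indices(config: CohortConfig, subject_id: str, session_id: str, movement: str):
    try:
        si = config.subject_ids().index(subject_id)
    except ValueError:
        raise ValueError(
            f"unknown subject {subject_id!r}; valid: {config.subject_ids()}"
        ) from None
    try:
        ei = config.session_ids().index(session_id)
    except ValueError:
        raise ValueError(
            f"unknown session {session_id!r}; valid: {config.session_ids()}"
        ) from None
    try:
        mi = config.movements.index(movement)
    except ValueError:
        raise ValueError(
            f"unknown movement {movement!r}; valid movements: {list(config.movements)}"
        ) from None
    return si, ei, mi


def subject_scale_factor(config: CohortConfig, subject_id: str) -> float:
    """Per-subject log-normal amplitude multiplier, exp(N(0, sd)).

    Drawn from a stream keyed by (seed, subject) only, so it is identical
    across that subject's sessions and movements — a stand-in for
    electrode-placement and anthropometric variability.
    """
    si = config.subject_ids().index(subject_id)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1, si]))
    return float(np.exp(rng.normal(0.0, config.subject_scale_sd)))


def generate_recording(
    config: CohortConfig,
    subject_id: str,
    session_id: str,
    movement: str,
) -> EMGRecording:
    """Simulate one trial: all six channels for one subject/session/movement.

    Raises ``ValueError`` for a movement outside ``config.movements``,
    naming the valid set.
    """
    si, ei, mi = _indices(config, subject_id, session_id, movement)
    n = config.samples_per_trial
    fs = config.sampling_rate
    rho = config.shared_drive_correlation
    scale = subject_scale_factor(config, subject_id)
    env = repetition_envelope(
        n, fs, period=config.repetition_period, tonic=config.envelope_tonic
    )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, si, ei, mi]))
    shared = _bandlimited_noise(rng, n, config.band, fs)
    mix_coef = np.sqrt(1.0 - rho**2)

    channels: dict[str, np.ndarray] = {}
    for muscle in config.muscles:
        own = _bandlimited_noise(rng, n, config.band, fs)
        floor = _bandlimited_noise(rng, n, config.band, fs)
        gain = config.gain_table[(muscle, movement)]
        drive = rho * shared + mix_coef * own
        channels[muscle] = gain * scale * env * drive + config.noise_floor * floor
    return EMGRecording(
        subject_id=subject_id,
        session_id=session_id,
        movement=movement,
        sampling_rate=fs,
        channels=channels,
        layer_map=dict(config.layer_map),
    )


def generate_cohort(config: CohortConfig) -> list[EMGRecording]:
    """Simulate the full cohort: n_subjects × n_sessions × movements trials."""
    return [
        generate_recording(config, subject, session, movement)
        for subject in config.subject_ids()
        for session in config.session_ids()
        for movement in config.movements
    ]
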