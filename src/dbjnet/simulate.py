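"""Synthetic multi-subject fNIRS cohort generator.

Emulates a block-design video emotion paradigm recorded as continuous HbO:
each subject contributes 2 task blocks of 12 trials (3 negative, 6 neutral,
3 positive per block, labels 1/2/3), sampled at 4 Hz over 40 channels.
Each trial is a boxcar the length of the video convolved with a
double-gamma hemodynamic response function, projected onto a class-specific
spatial pattern over channels, on top of physiological oscillations
(Mayer waves, respiration, cardiac), linear drift and white noise.

All randomness derives from ``SimConfig.seed``: identical configs produce
bit-identical datasets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

LABEL_NEGATIVE, LABEL_NEUTRAL, LABEL_POSITIVE = 1, 2, 3
LABEL_NAMES = {1: "negative", 2: "neutral", 3: "positive"}

#: seconds of trial-number screen then instruction screen before each video
PRE_VIDEO_S = 3.0


class SimConfigError(ValueError):
    """Raised for an inconsistent simulation configuration."""


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma hemodynamic response: a positive gamma peaking at
    ``peak_delay_s`` minus a later, smaller gamma (the undershoot)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 32.0


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise amplitudes (same arbitrary concentration units as the
    evoked response) and the oscillation frequencies in Hz."""

    white: float = 0.3
    mayer: float = 0.3
    respiration: float = 0.15
    cardiac: float = 0.1
    drift: float = 0.5
    mayer_hz: float = 0.1
    respiration_hz: float = 0.3
    cardiac_hz: float = 1.1


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 18
    n_blocks: int = 2
    trials_per_block: int = 12
    #: trials per block for labels (negative, neutral, positive)
    class_mix_per_block: tuple[int, int, int] = (3, 6, 3)
    n_channels: int = 40
    fs: float = 4.0
    video_duration_s: float = 60.0
    rest_s: float = 15.0
    effect_amplitude: float = 1.0
    pattern_overlap: float = 0.3
    subject_gain_sd: float = 0.2
    pattern_jitter_sd: float = 0.4
    noise: NoiseParams = field(default_factory=NoiseParams)
    hrf: HRFParams = field(default_factory=HRFParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.class_mix_per_block) != self.trials_per_block:
            raise SimConfigError(
                "class_mix_per_block must sum to trials_per_block "
                f"({self.class_mix_per_block} vs {self.trials_per_block})"
            )
        if any(c < 0 for c in self.class_mix_per_block) or min(
            self.n_blocks, self.trials_per_block, self.n_channels
        ) <= 0:
            raise SimConfigError("counts must be positive")
        if self.effect_amplitude < 0:
            raise SimConfigError("effect_amplitude must be >= 0")
        n = self.noise
        if min(n.white, n.mayer, n.respiration, n.cardiac, n.drift) < 0:
            raise SimConfigError("noise amplitudes must be >= 0")
        nyquist = self.fs / 2.0
        for f in (n.mayer_hz, n.respiration_hz, n.cardiac_hz):
            if f >= nyquist:
                raise SimConfigError(
                    f"oscillation at {f} Hz is not below the Nyquist "
                    f"frequency {nyquist} Hz"
                )
        if not 0.0 <= self.pattern_overlap <= 1.0:
            raise SimConfigError("pattern_overlap must lie in [0, 1]")


@dataclass(frozen=True)
class EventMarker:
    onset_sample: int
    duration_samples: int
    label: int

    def __post_init__(self) -> None:
        if self.label not in (1, 2, 3):
            raise ValueError(f"label must be in {{1,2,3}}, got {self.label}")


@dataclass
class ContinuousRecording:
    """A continuous HbO recording: channels x samples plus event markers."""

    hbo: np.ndarray
    fs: float
    subject_id: str
    channel_ids: list[str]
    events: list[EventMarker]

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=np.float64)
        if self.hbo.ndim != 2:
            raise ValueError("hbo must be channels x samples")
        if not np.isfinite(self.hbo).all():
            raise ValueError("hbo contains non-finite values")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be unique")
        if len(self.channel_ids) != self.hbo.shape[0]:
            raise ValueError("channel_ids length must match hbo rows")
        n = self.hbo.shape[1]
        for ev in self.events:
            if ev.onset_sample < 0 or ev.onset_sample + ev.duration_samples > n:
                raise ValueError(
                    f"event at sample {ev.onset_sample} extends outside "
                    f"the {n}-sample recording"
                )

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]


def canonical_hrf(t_grid: np.ndarray, hrf: HRFParams = HRFParams()) -> np.ndarray:
    """Double-gamma HRF sampled on ``t_grid`` (seconds), unit peak.

    The kernel is gamma(peak_delay/dispersion, dispersion) minus
    ``undershoot_ratio`` times gamma(undershoot_delay/dispersion,
    dispersion); with the defaults it rises to peak near 5-6 s and returns
    to baseline with a late undershoot.
    """
    t = np.asarray(t_grid, dtype=np.float64)
    if np.any(t < 0):
        raise ValueError("t_grid must be non-negative")
    if hrf.dispersion <= 0 or hrf.peak_delay_s <= 0 or hrf.undershoot_delay_s <= 0:
        raise ValueError("HRF delays and dispersion must be positive")
    def kernel(tt: np.ndarray) -> np.ndarray:
        peak = gamma_dist.pdf(tt, hrf.peak_delay_s / hrf.dispersion,
                              scale=hrf.dispersion)
        under = gamma_dist.pdf(tt, hrf.undershoot_delay_s / hrf.dispersion,
                               scale=hrf.dispersion)
        return peak - hrf.undershoot_ratio * under

    # Normalize by the kernel's true peak (dense grid over its support) so
    # "unit peak" does not depend on the caller's sampling grid.
    dense = np.arange(0.0, hrf.duration_s, 1e-3)
    peak_val = kernel(dense).max()
    if peak_val <= 0:
        raise ValueError("degenerate HRF: non-positive peak")
    return kernel(t) / peak_val


def class_patterns(config: SimConfig) -> np.ndarray:
    """Three unit-norm spatial patterns over channels (rows: negative,
    neutral, positive) with pairwise correlation ``pattern_overlap``.

    Built as sqrt(rho)*u0 + sqrt(1-rho)*u_k from four orthonormal random
    vectors, so every pairwise inner product equals rho exactly. Derived
    only from ``config.seed``: the population patterns are shared by all
    subjects.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(0xBA5E,)))
    g = rng.standard_normal((config.n_channels, 4))
    q, _ = np.linalg.qr(g)
    u0, rest = q[:, 0], q[:, 1:]
    rho = config.pattern_overlap
    pats = np.sqrt(rho) * u0[None, :] + np.sqrt(1 - rho) * rest.T
    return pats  # rows already unit norm


def _trial_labels(config: SimConfig, rng: np.random.Generator) -> list[int]:
    """Per-block trial order with neutral trials interleaved as buffers
    between the emotional (negative/positive) trials."""
    n_neg, n_neu, n_pos = config.class_mix_per_block
    emotional = [LABEL_NEGATIVE] * n_neg + [LABEL_POSITIVE] * n_pos
    rng.shuffle(emotional)
    neutrals = [LABEL_NEUTRAL] * n_neu
    order: list[int] = []
    # alternate neutral / emotional while both remain, then append leftovers
    while neutrals or emotional:
        if neutrals:
            order.append(neutrals.pop())
        if emotional:
            order.append(emotional.pop())
    return order


def simulate_subject(config: SimConfig, subject_index: int,
                     seed: int) -> ContinuousRecording:
    """Simulate one subject's continuous HbO recording.

    The evoked signal per trial is boxcar(video) convolved with the HRF,
    scaled by effect_amplitude, a subject gain, and the class pattern
    (jittered per subject); noise adds per-channel random-phase sinusoids,
    linear drift and white noise.
    """
    if config.video_duration_s < 40.0:
        raise SimConfigError(
            "video_duration_s must cover the 40-s analysis window"
        )
    rng = np.random.default_rng(seed)
    fs = config.fs
    trial_s = PRE_VIDEO_S + config.video_duration_s + config.rest_s
    lead_s = max(config.rest_s, 6.0)
    total_s = lead_s + config.n_blocks * config.trials_per_block * trial_s + 1.0
    n_samples = int(round(total_s * fs))
    t = np.arange(n_samples) / fs

    # trial schedule
    events: list[EventMarker] = []
    dur_samp = int(round(config.video_duration_s * fs))
    cursor = lead_s
    for _ in range(config.n_blocks):
        for label in _trial_labels(config, rng):
            onset = int(round((cursor + PRE_VIDEO_S) * fs))
            events.append(EventMarker(onset, dur_samp, label))
            cursor += trial_s

    # evoked response: one boxcar per class, convolved with the HRF
    hrf_t = np.arange(0.0, config.hrf.duration_s + 1.0 / fs, 1.0 / fs)
    kernel = canonical_hrf(hrf_t, config.hrf)
    responses = np.zeros((3, n_samples))
    for ev in events:
        box = np.zeros(n_samples)
        box[ev.onset_sample: ev.onset_sample + ev.duration_samples] = 1.0
        responses[ev.label - 1] += np.convolve(box, kernel)[:n_samples]

    pats = class_patterns(config)
    jitter = config.pattern_jitter_sd * rng.standard_normal(pats.shape)
    subj_pats = pats + jitter
    subj_pats /= np.linalg.norm(subj_pats, axis=1, keepdims=True)
    gain = abs(1.0 + config.subject_gain_sd * rng.standard_normal())

    hbo = (config.effect_amplitude * gain) * (subj_pats.T @ responses)

    # physiological oscillations with random phase per channel
    nz = config.noise
    for amp, freq in ((nz.mayer, nz.mayer_hz),
                      (nz.respiration, nz.respiration_hz),
                      (nz.cardiac, nz.cardiac_hz)):
        phases = rng.uniform(0, 2 * np.pi, size=config.n_channels)
        hbo += amp * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    slopes = rng.uniform(-1, 1, size=config.n_channels)
    hbo += nz.drift * slopes[:, None] * (2 * t[None, :] / t[-1] - 1.0)
    hbo += nz.white * rng.standard_normal(hbo.shape)

    return ContinuousRecording(
        hbo=hbo,
        fs=fs,
        subject_id=f"S{subject_index + 1:02d}",
        channel_ids=[f"CH{i + 1:02d}" for i in range(config.n_channels)],
        events=events,
    )


def simulate_dataset(config: SimConfig) -> list[ContinuousRecording]:
    """One recording per subject, with per-subject seeds derived
    deterministically from ``config.seed``."""
    if config.n_subjects < 2:
        raise SimConfigError("need at least 2 subjects")
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_subjects)
    return [
        simulate_subject(config, i, int(seeds[i]))
        for i in range(config.n_subjects)
    ]


def config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["class_mix_per_block"] = list(d["class_mix_per_block"])
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - known
    if unknown:
        raise SimConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
    if "noise" in d and isinstance(d["noise"], dict):
        d["noise"] = NoiseParams(**d["noise"])
    if "hrf" in d and isinstance(d["hrf"], dict):
        d["hrf"] = HRFParams(**d["hrf"])
    if "class_mix_per_block" in d:
        d["class_mix_per_block"] = tuple(d["class_mix_per_block"])
    return SimConfig(**d)
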