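"""Continuous-recording to trial-tensor preprocessing.

The pipeline follows the fixed order: Butterworth band-pass filter ->
trial epoching (5-s pre-stimulus baseline + stimulus) -> baseline
correction -> per-trial per-channel Z-score -> extraction of the last 40 s
of the stimulus -> optional channel reordering. With the defaults (4 Hz,
40 channels) every trial becomes a 40 x 160 matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulate import ContinuousRecording, EventMarker

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    band_low_hz: float = 0.01
    band_high_hz: float = 0.5
    filter_order: int = 3
    baseline_s: float = 5.0
    window_s: float = 40.0
    zero_phase: bool = True
    #: "identity" or an explicit permutation of channel indices
    channel_order: str | tuple[int, ...] = "identity"

    def validate(self, fs: float) -> None:
        if not 0 < self.band_low_hz < self.band_high_hz < fs / 2:
            raise ValueError(
                f"band edges ({self.band_low_hz}, {self.band_high_hz}) Hz "
                f"must satisfy 0 < low < high < fs/2 = {fs / 2} Hz"
            )
        if (self.window_s * fs) % 1 != 0:
            raise ValueError("window_s * fs must be an integer sample count")


@dataclass
class Epoch:
    """One trial: baseline segment followed by the stimulus segment."""

    data: np.ndarray  # channels x (n_baseline + n_stimulus)
    n_baseline: int
    label: int
    subject_id: str
    fs: float

    @property
    def stimulus(self) -> np.ndarray:
        return self.data[:, self.n_baseline:]


@dataclass
class EpochSet:
    """Stack of preprocessed trials: n_trials x n_channels x n_samples."""

    data: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    fs: float
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        if not (len(self.data) == len(self.labels) == len(self.subject_ids)):
            raise ValueError("data, labels and subject_ids must align")

    def __len__(self) -> int:
        return len(self.data)

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.subject_ids:
            seen.setdefault(s, None)
        return list(seen)

    def select(self, mask: np.ndarray) -> "EpochSet":
        return EpochSet(self.data[mask], self.labels[mask],
                        self.subject_ids[mask], self.fs)


def _design_sos(config: PreprocessConfig, fs: float) -> np.ndarray:
    config.validate(fs)
    return signal.butter(config.filter_order,
                         [config.band_low_hz, config.band_high_hz],
                         btype="bandpass", fs=fs, output="sos")


def bandpass_filter(recording: ContinuousRecording,
                    config: PreprocessConfig) -> ContinuousRecording:
    """Band-pass each channel independently (zero-phase by default)."""
    sos = _design_sos(config, recording.fs)
    pad = 3 * (config.filter_order + 1) * 2
    if recording.n_samples <= pad:
        raise ValueError(
            f"recording too short ({recording.n_samples} samples) to filter"
        )
    if config.zero_phase:
        filtered = signal.sosfiltfilt(sos, recording.hbo, axis=1)
    else:
        filtered = signal.sosfilt(sos, recording.hbo, axis=1)
    return ContinuousRecording(
        hbo=filtered, fs=recording.fs, subject_id=recording.subject_id,
        channel_ids=list(recording.channel_ids), events=list(recording.events),
    )


@dataclass
class EpochingResult:
    epochs: list[Epoch]
    n_excluded: int = 0


def epoch_trials(recording: ContinuousRecording,
                 events: list[EventMarker] | None = None,
                 config: PreprocessConfig = PreprocessConfig()) -> EpochingResult:
    """Cut one epoch per event: baseline_s before onset through the end of
    the stimulus. Events too close to a recording edge are skipped (with a
    warning) and counted, not padded."""
    if events is None:
        events = recording.events
    n_base = int(round(config.baseline_s * recording.fs))
    epochs: list[Epoch] = []
    excluded = 0
    for ev in events:
        start = ev.onset_sample - n_base
        stop = ev.onset_sample + ev.duration_samples
        if start < 0 or stop > recording.n_samples:
            logger.warning(
                "subject %s: event at sample %d too close to a recording "
                "edge; trial excluded", recording.subject_id, ev.onset_sample,
            )
            excluded += 1
            continue
        epochs.append(Epoch(
            data=recording.hbo[:, start:stop].copy(),
            n_baseline=n_base,
            label=ev.label,
            subject_id=recording.subject_id,
            fs=recording.fs,
        ))
    return EpochingResult(epochs, excluded)


def baseline_correct(epoch: Epoch,
                     config: PreprocessConfig = PreprocessConfig()) -> Epoch:
    """Subtract each channel's mean over the pre-stimulus baseline from the
    whole epoch."""
    if epoch.n_baseline < 1:
        raise ValueError("epoch carries no baseline segment")
    base_mean = epoch.data[:, :epoch.n_baseline].mean(axis=1, keepdims=True)
    return Epoch(epoch.data - base_mean, epoch.n_baseline, epoch.label,
                 epoch.subject_id, epoch.fs)


def zscore_channels(epoch: Epoch) -> Epoch:
    """Per channel: subtract the mean and divide by the standard deviation
    computed over all of the epoch's samples."""
    mean = epoch.data.mean(axis=1, keepdims=True)
    sd = epoch.data.std(axis=1, keepdims=True)
    flat = np.nonzero(sd.ravel() == 0)[0]
    if flat.size:
        raise ValueError(
            f"zero-variance channel(s) {flat.tolist()} cannot be Z-scored"
        )
    return Epoch((epoch.data - mean) / sd, epoch.n_baseline, epoch.label,
                 epoch.subject_id, epoch.fs)


def extract_final_window(epoch: Epoch,
                         config: PreprocessConfig = PreprocessConfig()) -> np.ndarray:
    """The trailing window_s seconds of the stimulus segment
    (channels x window_s*fs)."""
    n_win = int(round(config.window_s * epoch.fs))
    stim = epoch.stimulus
    if stim.shape[1] < n_win:
        raise ValueError(
            f"stimulus segment ({stim.shape[1]} samples) shorter than the "
            f"{n_win}-sample analysis window"
        )
    return stim[:, stim.shape[1] - n_win:]


def reorder_channels(epoch_set: EpochSet,
                     order: tuple[int, ...] | list[int]) -> EpochSet:
    """Permute the channel axis so spatially adjacent channels are
    contiguous; labels and trial order are untouched."""
    order = list(order)
    n_ch = epoch_set.data.shape[1]
    if sorted(order) != list(range(n_ch)):
        raise ValueError(
            f"channel order must be a permutation of 0..{n_ch - 1}"
        )
    return EpochSet(epoch_set.data[:, order, :], epoch_set.labels.copy(),
                    epoch_set.subject_ids.copy(), epoch_set.fs,
                    epoch_set.n_excluded)


def preprocess_pipeline(recordings, config: PreprocessConfig = PreprocessConfig()
                        ) -> EpochSet:
    """Filter -> epoch -> baseline-correct -> Z-score -> final window
    (-> reorder), over one or many recordings, into a single EpochSet."""
    if isinstance(recordings, ContinuousRecording):
        recordings = [recordings]
    trials, labels, subjects = [], [], []
    excluded = 0
    for rec in recordings:
        filtered = bandpass_filter(rec, config)
        result = epoch_trials(filtered, filtered.events, config)
        excluded += result.n_excluded
        for ep in result.epochs:
            try:
                ep = baseline_correct(ep, config)
                ep = zscore_channels(ep)
                win = extract_final_window(ep, config)
            except ValueError as exc:
                raise ValueError(
                    f"subject {rec.subject_id}: {exc}"
                ) from exc
            trials.append(win)
            labels.append(ep.label)
            subjects.append(ep.subject_id)
    if not trials:
        n_ch = recordings[0].n_channels if recordings else 0
        fs = recordings[0].fs if recordings else 0.0
        n_w = int(round(config.window_s * fs)) if fs else 0
        data = np.empty((0, n_ch, n_w))
        eset = EpochSet(data, np.empty(0, dtype=int), np.empty(0, dtype=object),
                        fs, excluded)
    else:
        eset = EpochSet(np.stack(trials), np.array(labels),
                        np.array(subjects, dtype=object),
                        recordings[0].fs, excluded)
    if config.channel_order != "identity":
        eset = reorder_channels(eset, config.channel_order)
    return eset


def snake_channel_order(n_channels: int = 40, n_cols: int = 8) -> list[int]:
    """An example adjacency-preserving permutation: walk a channel grid in
    boustrophedon (snake) order, reversing direction on alternate rows."""
    if n_channels % n_cols:
        raise ValueError("n_channels must be a multiple of n_cols")
    order: list[int] = []
    for r in range(n_channels // n_cols):
        row = list(range(r * n_cols, (r + 1) * n_cols))
        order.extend(row if r % 2 == 0 else row[::-1])
    return order
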