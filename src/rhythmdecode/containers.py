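"""In-memory containers for continuous recordings and stimulus-locked epochs.

Amplitudes are in microvolts throughout. A :class:`Recording` is a
channels-by-samples matrix with event markers (stimulus onsets plus a class
label); an :class:`EpochSet` is a stack of fixed-length stimulus-locked
segments with per-epoch labels and an optional rejection mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The two stimulus classes, in label-integer order (drum -> 0, syllable -> 1).
CLASSES = ("drum", "syllable")

LABEL_TO_INT = {name: i for i, name in enumerate(CLASSES)}


def labels_to_int(labels: np.ndarray) -> np.ndarray:
    """Map string class labels to {0, 1} integers (drum=0, syllable=1)."""
    labels = np.asarray(labels)
    if labels.dtype.kind in "iub":
        return labels.astype(np.int64)
    try:
        return np.array([LABEL_TO_INT[str(l)] for l in labels], dtype=np.int64)
    except KeyError as e:  # pragma: no cover - defensive
        raise ValueError(f"unknown class label {e}") from None


@dataclass
class Recording:
    """Continuous multi-channel EEG with stimulus events.

    Attributes
    ----------
    data : (n_channels, n_samples) float array, microvolts.
    rate : sampling rate in Hz.
    channel_labels : per-channel names.
    channel_positions : (n_channels, 3) unit-sphere sensor coordinates.
    event_onsets : 0-based sample indices of stimulus onsets, strictly
        increasing.
    event_labels : per-event class label, ``"drum"`` or ``"syllable"``.
    site : recording-site identifier (the cohort may span two sites).
    """

    data: np.ndarray
    rate: float
    channel_labels: list = field(default_factory=list)
    channel_positions: np.ndarray | None = None
    event_onsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    event_labels: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=object))
    site: str = "A"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.event_onsets = np.asarray(self.event_onsets, dtype=np.int64)
        self.event_labels = np.asarray(self.event_labels, dtype=object)
        if self.event_onsets.size:
            if self.event_onsets.min() < 0 or self.event_onsets.max() >= self.n_samples:
                raise ValueError("event onsets out of range")
            if np.any(np.diff(self.event_onsets) <= 0):
                raise ValueError("event onsets must be strictly increasing")
        if len(self.event_labels) != len(self.event_onsets):
            raise ValueError("event_labels and event_onsets length mismatch")
        if not self.channel_labels:
            self.channel_labels = [f"E{i + 1:02d}" for i in range(self.n_channels)]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy(self, **changes) -> "Recording":
        out = replace(self, **changes)
        if "data" not in changes:
            out.data = self.data.copy()
        return out


@dataclass
class EpochSet:
    """Fixed-length stimulus-locked epochs with labels and a rejection mask.

    ``reject_mask[i]`` is True when epoch ``i`` was judged improbable (noisy).
    Data are retained for all epochs so that both the clean view and the
    all-epochs view stay derivable from one object.
    """

    data: np.ndarray  # (n_epochs, n_channels, n_samples)
    labels: np.ndarray  # per-epoch class label strings
    rate: float
    epoch_length: float
    reject_mask: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (epochs x channels x samples)")
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != self.n_epochs:
            raise ValueError("labels length mismatch")
        n_expected = int(round(self.epoch_length * self.rate))
        if self.data.shape[2] != n_expected:
            raise ValueError(
                f"epoch sample count {self.data.shape[2]} != epoch_length*rate = {n_expected}"
            )
        if self.reject_mask is not None:
            self.reject_mask = np.asarray(self.reject_mask, dtype=bool)
            if self.reject_mask.shape != (self.n_epochs,):
                raise ValueError("reject_mask shape mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def labels_int(self) -> np.ndarray:
        return labels_to_int(self.labels)

    def select(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            data=self.data[idx],
            labels=self.labels[idx],
            rate=self.rate,
            epoch_length=self.epoch_length,
            reject_mask=None if self.reject_mask is None else self.reject_mask[idx],
        )

    def clean(self) -> "EpochSet":
        """Epochs that survived improbability masking."""
        if self.reject_mask is None:
            return self
        return self.select(~self.reject_mask)

    def rejected(self) -> "EpochSet":
        if self.reject_mask is None:
            return self.select(np.zeros(self.n_epochs, dtype=bool))
        return self.select(self.reject_mask)

    @classmethod
    def concatenate(cls, sets: list["EpochSet"]) -> "EpochSet":
        if not sets:
            raise ValueError("nothing to concatenate")
        rate = sets[0].rate
        length = sets[0].epoch_length
        for s in sets:
            if s.rate != rate or s.epoch_length != length:
                raise ValueError("incompatible epoch sets")
        masks = [
            s.reject_mask if s.reject_mask is not None else np.zeros(s.n_epochs, bool)
            for s in sets
        ]
        return cls(
            data=np.concatenate([s.data for s in sets], axis=0),
            labels=np.concatenate([s.labels for s in sets]),
            rate=rate,
            epoch_length=length,
            reject_mask=np.concatenate(masks),
        )
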