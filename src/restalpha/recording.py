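"""Core container for multichannel EEG data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class MultichannelRecording:
    """A labeled channel x time matrix in microvolts.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)``, in microvolts.
    fs_hz
        Sampling rate in Hz.
    channel_labels
        Unique 10-20 channel names, one per data row.
    subject_id, group
        Optional cohort metadata carried through the pipeline.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: list[str]
    subject_id: str | None = None
    group: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        labels = list(self.channel_labels)
        if len(labels) != len(set(labels)):
            raise ValueError("channel labels must be unique")
        if self.data.shape[0] != len(labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(labels)} channel labels"
            )
        self.channel_labels = labels

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def channel(self, label: str) -> np.ndarray:
        """Return the time series of a single channel by label."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError as err:
            raise KeyError(f"channel {label!r} not in recording") from err
        return self.data[idx]

    def pick(self, labels: list[str]) -> "MultichannelRecording":
        """Sub-recording restricted to ``labels`` (in the given order)."""
        idx = [self.channel_labels.index(l) for l in labels]
        return replace(self, data=self.data[idx], channel_labels=list(labels))

    def copy_with(self, data: np.ndarray) -> "MultichannelRecording":
        return replace(self, data=data)
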