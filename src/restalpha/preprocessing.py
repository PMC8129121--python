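"""Signal conditioning and ROI identification.

Implements the conditioning chain applied to each resting recording —
average re-referencing, polyphase resampling to 500 Hz, zero-phase
Hamming-window FIR band-pass filtering in the 6-14 Hz alpha band, and
non-overlapping 2000 ms epoching — plus the correlation-based matching of
component topographies to the four ROI spatial templates (0.80 threshold,
one to three components retained per template) and ROI time-series
extraction by back-projection or by plain electrode-cluster averaging.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from restalpha.montage import (
    DEFAULT_CLUSTERS,
    ElectrodeClusters,
    ROI_TO_TEMPLATE,
    TopographyTemplate,
    default_templates,
)
from restalpha.recording import MultichannelRecording

__all__ = [
    "EpochedData",
    "ComponentSet",
    "TemplateUnmatchedError",
    "bandpass_filter",
    "rereference_average",
    "resample_signal",
    "epoch_signal",
    "epoch_series",
    "match_templates",
    "backproject_recording",
    "roi_time_series",
    "TopographyTemplate",
    "default_templates",
]


@dataclass
class EpochedData:
    """Non-overlapping fixed-length epochs: (epochs x channels x samples)."""

    data: np.ndarray
    epoch_length_ms: float
    fs_hz: float
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoched data must be 3-D (epochs x channels x samples)")
        n = self.epoch_length_ms * self.fs_hz / 1000.0
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch length must be an integer number of samples")
        if self.data.shape[2] != round(n):
            raise ValueError("sample count does not match epoch length")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


@dataclass
class ComponentSet:
    """Linear decomposition: scalp topographies plus component activations.

    ``topographies`` is (channels x components), ``activations``
    (components x samples); provenance records where the decomposition came
    from (``ica``, ``synthetic-truth`` or ``cluster-average``).
    """

    topographies: np.ndarray
    activations: np.ndarray
    channel_labels: list[str]
    fs_hz: float
    provenance: str = "ica"

    def __post_init__(self) -> None:
        self.topographies = np.atleast_2d(np.asarray(self.topographies, dtype=float))
        self.activations = np.atleast_2d(np.asarray(self.activations, dtype=float))
        if self.topographies.shape[1] != self.activations.shape[0]:
            raise ValueError("topography and activation component counts differ")
        if self.topographies.shape[0] != len(self.channel_labels):
            raise ValueError("topography channel count does not match labels")

    @property
    def n_components(self) -> int:
        return self.topographies.shape[1]


class TemplateUnmatchedError(RuntimeError):
    """No component reached the correlation threshold for a template."""


def bandpass_filter(
    recording: MultichannelRecording,
    low_hz: float = 6.0,
    high_hz: float = 14.0,
) -> MultichannelRecording:
    """Zero-phase Hamming-window FIR band-pass (default 6-14 Hz alpha band)."""
    if recording.fs_hz <= 2 * high_hz:
        raise ValueError("sampling rate must exceed twice the upper band edge")
    import mne

    filtered = mne.filter.filter_data(
        recording.data,
        sfreq=recording.fs_hz,
        l_freq=low_hz,
        h_freq=high_hz,
        method="fir",
        fir_window="hamming",
        fir_design="firwin",
        phase="zero",
        verbose="error",
    )
    return recording.copy_with(filtered)


def rereference_average(recording: MultichannelRecording) -> MultichannelRecording:
    """Re-reference to the instantaneous average of all electrodes."""
    if recording.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    return recording.copy_with(recording.data - recording.data.mean(axis=0, keepdims=True))


def resample_signal(
    recording: MultichannelRecording,
    target_fs: float = 500.0,
    allow_upsample: bool = False,
) -> MultichannelRecording:
    """Anti-aliased polyphase resampling (downsampling by default)."""
    if target_fs > recording.fs_hz and not allow_upsample:
        raise ValueError("upsampling requested; pass allow_upsample=True to permit")
    if target_fs == recording.fs_hz:
        return recording
    frac = Fraction(target_fs / recording.fs_hz).limit_denominator(1000)
    data = sps.resample_poly(recording.data, frac.numerator, frac.denominator, axis=1)
    out = recording.copy_with(data)
    out.fs_hz = target_fs
    return out


def epoch_signal(
    recording: MultichannelRecording,
    epoch_ms: float = 2000.0,
) -> EpochedData:
    """Cut into consecutive non-overlapping epochs; the remainder is dropped."""
    n_per = int(round(epoch_ms * recording.fs_hz / 1000.0))
    n_epochs = recording.n_samples // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording of {recording.n_samples} samples shorter than one "
            f"{epoch_ms} ms epoch"
        )
    trimmed = recording.data[:, : n_epochs * n_per]
    data = trimmed.reshape(recording.n_channels, n_epochs, n_per).swapaxes(0, 1)
    return EpochedData(
        data=data,
        epoch_length_ms=epoch_ms,
        fs_hz=recording.fs_hz,
        channel_labels=list(recording.channel_labels),
    )


def epoch_series(x: np.ndarray, fs_hz: float, epoch_ms: float = 2000.0) -> np.ndarray:
    """Epoch a single time series into a (n_epochs x n_samples) array."""
    x = np.asarray(x, dtype=float)
    n_per = int(round(epoch_ms * fs_hz / 1000.0))
    n_epochs = x.size // n_per
    if n_epochs < 1:
        raise ValueError("series shorter than one epoch")
    return x[: n_epochs * n_per].reshape(n_epochs, n_per)


def components_from_truth(
    recording: MultichannelRecording,
    sources: dict[str, np.ndarray],
) -> ComponentSet:
    """Build a ComponentSet from generator ground truth (known mixing)."""
    from restalpha.montage import roi_topography

    rois = list(sources)
    topo = np.stack(
        [roi_topography(recording.channel_labels, r) for r in rois], axis=1
    )
    acts = np.stack([sources[r] for r in rois])
    return ComponentSet(
        topographies=topo,
        activations=acts,
        channel_labels=list(recording.channel_labels),
        fs_hz=recording.fs_hz,
        provenance="synthetic-truth",
    )


def decompose_ica(
    recording: MultichannelRecording,
    n_components: int = 16,
    seed: int = 0,
) -> ComponentSet:
    """Independent component decomposition via an established solver (FastICA).

    The decomposition step is deliberately thin: any ComponentSet (from
    this helper, from an external ICA run, or generator ground truth) can
    feed template matching and back-projection.
    """
    from sklearn.decomposition import FastICA

    ica = FastICA(n_components=n_components, random_state=seed, whiten="unit-variance")
    acts = ica.fit_transform(recording.data.T).T
    return ComponentSet(
        topographies=ica.mixing_,
        activations=acts,
        channel_labels=list(recording.channel_labels),
        fs_hz=recording.fs_hz,
        provenance="ica",
    )


def match_templates(
    components: ComponentSet,
    templates: list[TopographyTemplate] | None = None,
    threshold: float = 0.80,
    max_per_template: int = 3,
    subject_id: str | None = None,
) -> dict[str, list[int]]:
    """Assign components to ROI templates by absolute Pearson correlation.

    A component is a candidate for a template when ``|r| >= threshold``
    between the topography vectors; each component goes to the template
    where its ``|r|`` is largest, and per template only the
    ``max_per_template`` strongest matches are retained.  A template left
    without any component raises :class:`TemplateUnmatchedError`.
    """
    if templates is None:
        templates = default_templates(components.channel_labels)
    for t in templates:
        if list(t.channel_labels) != list(components.channel_labels):
            raise ValueError(f"template {t.name} channel space differs from components")
    topo = components.topographies
    r = np.zeros((len(templates), components.n_components))
    for i, t in enumerate(templates):
        for j in range(components.n_components):
            v = topo[:, j]
            if np.std(v) == 0 or np.std(t.weights) == 0:
                r[i, j] = 0.0
            else:
                r[i, j] = np.corrcoef(t.weights, v)[0, 1]
    absr = np.abs(r)
    best_template = np.argmax(absr, axis=0)  # each component: at most one template
    selected: dict[str, list[int]] = {t.name: [] for t in templates}
    for i, t in enumerate(templates):
        cands = [
            j
            for j in range(components.n_components)
            if best_template[j] == i and absr[i, j] >= threshold
        ]
        cands.sort(key=lambda j: -absr[i, j])
        selected[t.name] = cands[:max_per_template]
        if not selected[t.name]:
            who = f" for subject {subject_id}" if subject_id else ""
            raise TemplateUnmatchedError(
                f"template {t.name!r} unmatched{who}: no component reached "
                f"|r| >= {threshold}"
            )
    return selected


def backproject_recording(
    components: ComponentSet,
    selection: dict[str, list[int]],
    labels: list[str] | None = None,
) -> MultichannelRecording:
    """Scalp reconstruction from the template-matched components only.

    Summing the back-projections of all selected components yields a
    recording that retains the ROI sources but sheds unselected activity
    (and with it most common-mode and far-field contamination), which is
    what the connectivity stage operates on.
    """
    if labels is None:
        labels = list(components.channel_labels)
    idx = [components.channel_labels.index(l) for l in labels]
    comp_idx = sorted({j for sel in selection.values() for j in sel})
    data = np.zeros((len(idx), components.activations.shape[1]))
    for j in comp_idx:
        data += np.outer(components.topographies[idx, j], components.activations[j])
    return MultichannelRecording(
        data=data, fs_hz=components.fs_hz, channel_labels=list(labels)
    )


def roi_time_series(
    recording: MultichannelRecording | None = None,
    components: ComponentSet | None = None,
    clusters: ElectrodeClusters = DEFAULT_CLUSTERS,
    mode: str = "cluster-average",
    selection: dict[str, list[int]] | None = None,
    threshold: float = 0.80,
) -> dict[str, np.ndarray]:
    """One time series per ROI.

    ``cluster-average`` mode averages the raw cluster electrodes of the
    recording; ``backprojection`` mode sums the scalp back-projections of
    the components matched to each ROI's template and then averages over
    that ROI's cluster electrodes.
    """
    out: dict[str, np.ndarray] = {}
    if mode == "cluster-average":
        if recording is None:
            raise ValueError("cluster-average mode needs a recording")
        for roi, cluster in clusters.as_dict().items():
            idx = [recording.channel_labels.index(l) for l in cluster]
            out[roi] = recording.data[idx].mean(axis=0)
        return out
    if mode != "backprojection":
        raise ValueError(f"unknown mode {mode!r}")
    if components is None:
        raise ValueError("backprojection mode needs a ComponentSet")
    if selection is None:
        selection = match_templates(components, threshold=threshold)
    labels = components.channel_labels
    for roi, cluster in clusters.as_dict().items():
        tname = ROI_TO_TEMPLATE[roi]
        comp_idx = selection[tname]
        idx = [labels.index(l) for l in cluster]
        # sum of back-projections of the matched components, then cluster mean
        scalp = np.zeros((len(idx), components.activations.shape[1]))
        for j in comp_idx:
            scalp += np.outer(components.topographies[idx, j], components.activations[j])
        out[roi] = scalp.mean(axis=0)
    return out
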