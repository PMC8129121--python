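"""10-20 montage geometry, ROI electrode clusters and spatial templates.

The four regions of interest (ROIs) are the left/right frontal and
left/right parieto-occipital electrode clusters used for alpha activity and
connectivity analysis.  Electrode positions come from the standard 10-20
montage shipped with MNE and are used both to build the fixed
Gaussian-falloff projection weights of the synthetic generator and the
spatial templates that component topographies are matched against.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

ROI_NAMES = ("frontal_L", "frontal_R", "posterior_L", "posterior_R")

#: ROI electrode clusters (10-20 labels).
CLUSTERS: dict[str, tuple[str, ...]] = {
    "frontal_L": ("F1", "FC1", "C1", "FC3"),
    "frontal_R": ("F2", "FC2", "C2", "FC4"),
    "posterior_L": ("PO7", "PO3", "O1"),
    "posterior_R": ("PO8", "PO4", "O2"),
}

#: Fixed electrode order of the 14x14 cluster connectivity matrix.
CLUSTER_ELECTRODE_ORDER: tuple[str, ...] = (
    "F1", "FC1", "C1", "FC3",
    "F2", "FC2", "C2", "FC4",
    "PO7", "PO3", "O1",
    "PO8", "PO4", "O2",
)

#: 64-channel eyes-closed resting montage (easycap-style layout).
DEFAULT_64_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8", "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10", "AF7",
    "AF3", "AF4", "AF8", "F5", "F1", "F2", "F6", "FT9", "FT7", "FC3", "FC4",
    "FT8", "FT10", "C5", "C1", "C2", "C6", "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6", "PO7", "PO3", "POz", "PO4", "PO8",
)

#: Minimal montage (the 14 cluster electrodes) for fast simulation runs.
CLUSTER_14_MONTAGE: tuple[str, ...] = CLUSTER_ELECTRODE_ORDER


@dataclass(frozen=True)
class ElectrodeClusters:
    """The four disjoint ROI electrode label sets (14 electrodes total)."""

    frontal_L: tuple[str, ...] = CLUSTERS["frontal_L"]
    frontal_R: tuple[str, ...] = CLUSTERS["frontal_R"]
    posterior_L: tuple[str, ...] = CLUSTERS["posterior_L"]
    posterior_R: tuple[str, ...] = CLUSTERS["posterior_R"]

    def __post_init__(self) -> None:
        labels = [l for c in self.as_dict().values() for l in c]
        if len(labels) != len(set(labels)):
            raise ValueError("ROI clusters must be disjoint")

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return {
            "frontal_L": self.frontal_L,
            "frontal_R": self.frontal_R,
            "posterior_L": self.posterior_L,
            "posterior_R": self.posterior_R,
        }

    def cluster(self, roi: str) -> tuple[str, ...]:
        d = self.as_dict()
        if roi not in d:
            raise KeyError(f"unknown ROI cluster {roi!r}")
        return d[roi]


DEFAULT_CLUSTERS = ElectrodeClusters()


@dataclass(frozen=True)
class TopographyTemplate:
    """Unit-norm spatial weight pattern of one ROI component.

    Template names follow the convention of two central-frontal templates
    (A = left, B = right) and one parieto-occipital template per hemisphere.
    """

    name: str
    channel_labels: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size != len(self.channel_labels):
            raise ValueError("weights must be 1-D, one entry per channel")
        n = np.linalg.norm(w)
        if n == 0:
            raise ValueError("template weights must be non-zero")
        object.__setattr__(self, "weights", w / n)


#: Template name -> ROI it represents.
TEMPLATE_TO_ROI: dict[str, str] = {
    "frontal-A": "frontal_L",
    "frontal-B": "frontal_R",
    "left-parieto-occipital": "posterior_L",
    "right-parieto-occipital": "posterior_R",
}
ROI_TO_TEMPLATE = {v: k for k, v in TEMPLATE_TO_ROI.items()}


@lru_cache(maxsize=4)
def _standard_positions() -> dict[str, np.ndarray]:
    import mne

    with np.errstate(all="ignore"):
        try:
            mont = mne.channels.make_standard_montage("colin27_1020")
        except ValueError:  # older MNE releases use the previous name
            mont = mne.channels.make_standard_montage("standard_1020")
    return {k: np.asarray(v) for k, v in mont.get_positions()["ch_pos"].items()}


def channel_positions(labels: tuple[str, ...] | list[str]) -> np.ndarray:
    """3-D head positions (meters) for the given 10-20 labels."""
    pos = _standard_positions()
    missing = [l for l in labels if l not in pos]
    if missing:
        raise KeyError(f"labels not in the standard 10-20 montage: {missing}")
    return np.stack([pos[l] for l in labels])


def roi_topography(
    labels: tuple[str, ...] | list[str],
    roi: str,
    sigma_m: float = 0.045,
) -> np.ndarray:
    """Fixed Gaussian-falloff projection weights of one ROI source.

    Weights peak (value 1) at the centroid of the ROI's electrode cluster
    and decay with 3-D distance with length scale ``sigma_m``.
    """
    cluster = DEFAULT_CLUSTERS.cluster(roi)
    missing = [l for l in cluster if l not in labels]
    if missing:
        raise KeyError(f"montage is missing cluster electrodes {missing} for {roi}")
    xyz = channel_positions(labels)
    center = channel_positions(cluster).mean(axis=0)
    d2 = np.sum((xyz - center) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma_m**2))


def default_templates(
    labels: tuple[str, ...] | list[str],
) -> list[TopographyTemplate]:
    """The four ROI spatial templates on the given montage."""
    return [
        TopographyTemplate(name, tuple(labels), roi_topography(labels, roi))
        for name, roi in TEMPLATE_TO_ROI.items()
    ]
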