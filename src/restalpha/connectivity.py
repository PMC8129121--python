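"""Phase-based connectivity: weighted phase lag index and time lag index.

Signals are cut into 2500 ms non-overlapping windows; per window the
complex cross-spectrum is evaluated at the grid frequency nearest the
subject's individual alpha frequency.  The weighted phase lag index
(wPLI) is ``|mean Im S| / mean |Im S|`` over windows — a [0, 1] coupling
measure blind to zero-lag (volume-conduction) interactions.  The time lag
index (TLI) converts the circular-mean cross-spectral phase to signed
milliseconds; positive values mean the phase of the first signal lags the
second, so the second signal leads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from restalpha.montage import CLUSTER_ELECTRODE_ORDER, DEFAULT_CLUSTERS, ElectrodeClusters
from restalpha.preprocessing import epoch_series
from restalpha.recording import MultichannelRecording

__all__ = [
    "CrossSpectrumSet",
    "ConnectivityResult",
    "window_segments",
    "cross_spectrum_at",
    "wpli",
    "tli",
    "cluster_connectivity",
]

WINDOW_MS = 2500.0


@dataclass
class CrossSpectrumSet:
    """Per-window complex cross-spectral values at one target frequency."""

    values: np.ndarray  # complex, one per window
    freq_hz: float      # grid frequency actually evaluated
    window_length_ms: float = WINDOW_MS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=complex).ravel()
        if self.values.size < 1:
            raise ValueError("need at least one window")

    @property
    def n_windows(self) -> int:
        return self.values.size


@dataclass
class ConnectivityResult:
    """wPLI and TLI for one ordered signal pair at one frequency."""

    pair: tuple[str, str]
    freq_hz: float
    wpli: float
    tli_ms: float


def window_segments(
    x: np.ndarray,
    fs_hz: float,
    window_ms: float = WINDOW_MS,
) -> np.ndarray:
    """Non-overlapping windows (n_windows x n_samples); remainder discarded."""
    try:
        return epoch_series(x, fs_hz, epoch_ms=window_ms)
    except ValueError as err:
        raise ValueError(f"signal shorter than one {window_ms} ms window") from err


def _tapered_coef(windows: np.ndarray, fs_hz: float, freq_hz: float) -> tuple[np.ndarray, float]:
    """Hann-tapered DFT coefficient of each window at the nearest grid frequency."""
    n = windows.shape[1]
    k = int(round(freq_hz * n / fs_hz))
    grid_freq = k * fs_hz / n
    taper = np.hanning(n)
    basis = taper * np.exp(-2j * np.pi * k * np.arange(n) / n)
    return windows @ basis, grid_freq


def cross_spectrum_at(
    x_windows: np.ndarray,
    y_windows: np.ndarray,
    fs_hz: float,
    freq_hz: float,
) -> CrossSpectrumSet:
    """Per-window cross-spectrum S_xy at the grid frequency nearest ``freq_hz``.

    Phase convention: ``arg S_xy > 0`` iff x lags y (y leads).
    """
    x_windows = np.atleast_2d(x_windows)
    y_windows = np.atleast_2d(y_windows)
    if x_windows.shape != y_windows.shape:
        raise ValueError("window arrays must have identical shapes")
    X, grid_freq = _tapered_coef(x_windows, fs_hz, freq_hz)
    Y, _ = _tapered_coef(y_windows, fs_hz, freq_hz)
    window_ms = 1000.0 * x_windows.shape[1] / fs_hz
    return CrossSpectrumSet(
        values=np.conj(X) * Y, freq_hz=grid_freq, window_length_ms=window_ms
    )


def wpli(cs: CrossSpectrumSet) -> float:
    """Weighted phase lag index in [0, 1]; 0 for pure zero-lag coupling.

    The zero-denominator convention is applied with a relative tolerance:
    imaginary parts that are negligible against the cross-spectrum
    magnitude (pure real coupling up to round-off) count as zero.
    """
    im = np.imag(cs.values)
    denom = np.mean(np.abs(im))
    scale = np.mean(np.abs(cs.values))
    if denom <= 1e-12 * scale or denom == 0:
        return 0.0
    return float(abs(np.mean(im)) / denom)


def tli(cs: CrossSpectrumSet, freq_hz: float | None = None) -> float:
    """Time lag index in signed milliseconds (positive: first signal lags).

    The phase lag is the circular (resultant-vector) mean of the
    per-window cross-spectral phases; a vanishing resultant (uniform
    phases) yields NaN.
    """
    f = cs.freq_hz if freq_hz is None else freq_hz
    resultant = np.sum(cs.values)
    if abs(resultant) < 1e-300 or f <= 0:
        return float("nan")
    dphi = np.angle(resultant)
    return float(1000.0 * dphi / (2.0 * np.pi * f))


def connectivity_pair(
    x: np.ndarray,
    y: np.ndarray,
    fs_hz: float,
    freq_hz: float,
    pair: tuple[str, str] = ("x", "y"),
    window_ms: float = WINDOW_MS,
) -> ConnectivityResult:
    """wPLI and TLI between two raw series at one evaluation frequency."""
    cs = cross_spectrum_at(
        window_segments(x, fs_hz, window_ms),
        window_segments(y, fs_hz, window_ms),
        fs_hz,
        freq_hz,
    )
    return ConnectivityResult(pair=pair, freq_hz=cs.freq_hz, wpli=wpli(cs), tli_ms=tli(cs))


# the three inter-cluster feature definitions: (name, cluster A, cluster B);
# TLI order is frontal-first for intra pairs and left-first for the
# inter-hemispheric pair
_FEATURE_PAIRS = (
    ("intra_L", "frontal_L", "posterior_L"),
    ("intra_R", "frontal_R", "posterior_R"),
    ("inter", "posterior_L", "posterior_R"),
)


def cluster_connectivity(
    recording: MultichannelRecording,
    iaf_hz: float | None,
    clusters: ElectrodeClusters = DEFAULT_CLUSTERS,
    window_ms: float = WINDOW_MS,
) -> tuple[pd.DataFrame, dict[str, float], dict[str, float]]:
    """14x14 electrode wPLI matrix plus the three wPLI and three TLI features.

    The wPLI features are means over inter-cluster electrode pairs (left
    intra-hemispheric, right intra-hemispheric, inter-hemispheric
    posterior); TLI features are computed on cluster-mean time series for
    the same pairs.  Evaluation frequency is the subject's posterior IAF;
    when missing, 10 Hz is used.
    """
    if iaf_hz is None or np.isnan(iaf_hz):
        iaf_hz = 10.0
    order = list(CLUSTER_ELECTRODE_ORDER)
    missing = [l for l in order if l not in recording.channel_labels]
    if missing:
        raise KeyError(f"recording is missing cluster electrodes {missing}")
    fs = recording.fs_hz
    windows = {l: window_segments(recording.channel(l), fs, window_ms) for l in order}
    coefs = {}
    grid_freq = None
    for l in order:
        coefs[l], grid_freq = _tapered_coef(windows[l], fs, iaf_hz)

    n = len(order)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cs = CrossSpectrumSet(
                values=np.conj(coefs[order[i]]) * coefs[order[j]],
                freq_hz=grid_freq,
                window_length_ms=window_ms,
            )
            mat[i, j] = mat[j, i] = wpli(cs)
    matrix = pd.DataFrame(mat, index=order, columns=order)

    wpli_features: dict[str, float] = {}
    for name, ca, cb in _FEATURE_PAIRS:
        pairs = [
            matrix.loc[a, b]
            for a in clusters.cluster(ca)
            for b in clusters.cluster(cb)
        ]
        wpli_features[f"wpli_{name}"] = float(np.mean(pairs))

    tli_features: dict[str, float] = {}
    cluster_means = {
        roi: np.mean([recording.channel(l) for l in cl], axis=0)
        for roi, cl in clusters.as_dict().items()
    }
    for name, ca, cb in _FEATURE_PAIRS:
        cs = cross_spectrum_at(
            window_segments(cluster_means[ca], fs, window_ms),
            window_segments(cluster_means[cb], fs, window_ms),
            fs,
            iaf_hz,
        )
        tli_features[f"tli_{name}"] = tli(cs)
    return matrix, wpli_features, tli_features
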