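"""Synthetic eyes-closed resting EEG cohorts with controllable alpha structure.

The generator emulates the group-level structure that the downstream
pipeline is designed to detect: subject-specific alpha peaks (7-13 Hz) over
four ROI sources (left/right x frontal/parieto-occipital), a posterior >
frontal amplitude gradient, 1/f background activity, and within-hemisphere
fronto-posterior phase coupling with a configurable signed lead/lag.

Generative model per subject and hemisphere
-------------------------------------------
A narrow-band "driver" oscillation at the hemisphere's posterior alpha
frequency couples the two ROI sources:

* posterior source = driver advanced by ``lag_ms`` (positive lag => the
  posterior phase leads, i.e. the frontal signal lags the posterior one),
* frontal source  = ``c * driver + sqrt(1 - c^2) * independent`` where the
  independent component is narrow-band at the frontal alpha frequency and
  ``c`` is the coupling strength in [0, 1].

Each source is scaled to its configured microvolt RMS, mixed with 1/f
background noise, projected to the scalp through fixed Gaussian-falloff
topographies, and corrupted by white sensor noise.  All randomness derives
from a single integer seed, so identical (config, seed) pairs give
bit-identical recordings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from restalpha.montage import DEFAULT_64_MONTAGE, ROI_NAMES, roi_topography
from restalpha.recording import MultichannelRecording

HEMISPHERES = ("L", "R")
_ROI_OF = {"L": ("frontal_L", "posterior_L"), "R": ("frontal_R", "posterior_R")}


def _check_roi_dict(d: dict, what: str) -> dict[str, float]:
    missing = [r for r in ROI_NAMES if r not in d]
    if missing:
        raise ValueError(f"{what} missing ROIs {missing}")
    return {r: float(d[r]) for r in ROI_NAMES}


def _check_hemi_dict(d: dict, what: str) -> dict[str, float]:
    missing = [h for h in HEMISPHERES if h not in d]
    if missing:
        raise ValueError(f"{what} missing hemispheres {missing}")
    return {h: float(d[h]) for h in HEMISPHERES}


@dataclass
class GroupGenConfig:
    """Group-level generative parameters.

    All per-ROI dicts are keyed by ``frontal_L/frontal_R/posterior_L/
    posterior_R``; per-hemisphere dicts by ``L/R``.  Amplitudes are the
    microvolt RMS of the alpha source; ``lag_ms`` is signed with positive
    values meaning the frontal signal lags the posterior one.
    """

    group_label: str
    iaf_mean_hz: dict[str, float]
    iaf_sd_hz: dict[str, float]
    amp_mean_uv: dict[str, float]
    amp_sd_uv: dict[str, float]
    coupling_strength: dict[str, float]
    lag_ms_mean: dict[str, float]
    lag_ms_sd: dict[str, float]
    noise_exponent: float = 1.0
    background_uv: float = 1.5
    sensor_noise_uv: float = 1.0

    def __post_init__(self) -> None:
        self.iaf_mean_hz = _check_roi_dict(self.iaf_mean_hz, "iaf_mean_hz")
        self.iaf_sd_hz = _check_roi_dict(self.iaf_sd_hz, "iaf_sd_hz")
        self.amp_mean_uv = _check_roi_dict(self.amp_mean_uv, "amp_mean_uv")
        self.amp_sd_uv = _check_roi_dict(self.amp_sd_uv, "amp_sd_uv")
        self.coupling_strength = _check_hemi_dict(self.coupling_strength, "coupling_strength")
        self.lag_ms_mean = _check_hemi_dict(self.lag_ms_mean, "lag_ms_mean")
        self.lag_ms_sd = _check_hemi_dict(self.lag_ms_sd, "lag_ms_sd")
        for roi, m in self.iaf_mean_hz.items():
            if not 7.0 <= m <= 13.0:
                raise ValueError(f"iaf_mean_hz[{roi}]={m} outside [7, 13]")
        for d in (self.iaf_sd_hz, self.amp_sd_uv, self.lag_ms_sd):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative sd {v} for {k}")
        for h, c in self.coupling_strength.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling_strength[{h}]={c} outside [0, 1]")
        if self.sensor_noise_uv < 0 or self.background_uv < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "GroupGenConfig":
        return cls(**d)


@dataclass
class SubjectGenParams:
    """Per-subject realization of the group generative parameters."""

    subject_id: str
    group_label: str
    iaf_hz: dict[str, float]
    amp_uv: dict[str, float]
    coupling_strength: dict[str, float]
    lag_ms: dict[str, float]
    noise_exponent: float
    background_uv: float
    sensor_noise_uv: float
    rng_seed: int


def sample_subject_params(
    config: GroupGenConfig,
    n_subjects: int,
    seed: int,
    id_prefix: str | None = None,
) -> list[SubjectGenParams]:
    """Draw per-subject parameters from the configured normal distributions.

    IAF draws are clipped to [7, 13] Hz and lag draws to 80% of the half
    alpha period (the unambiguous phase range at the subject's posterior
    alpha frequency).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    prefix = id_prefix if id_prefix is not None else config.group_label
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    child_seeds = ss.generate_state(n_subjects) % (2**31)
    out = []
    for i in range(n_subjects):
        iaf = {
            r: float(np.clip(rng.normal(config.iaf_mean_hz[r], config.iaf_sd_hz[r]), 7.0, 13.0))
            for r in ROI_NAMES
        }
        amp = {
            r: float(max(rng.normal(config.amp_mean_uv[r], config.amp_sd_uv[r]), 0.0))
            for r in ROI_NAMES
        }
        lag = {}
        for h in HEMISPHERES:
            half_period_ms = 500.0 / config.iaf_mean_hz[_ROI_OF[h][1]]
            bound = 0.8 * half_period_ms
            lag[h] = float(
                np.clip(rng.normal(config.lag_ms_mean[h], config.lag_ms_sd[h]), -bound, bound)
            )
        out.append(
            SubjectGenParams(
                subject_id=f"{prefix}{i + 1:02d}",
                group_label=config.group_label,
                iaf_hz=iaf,
                amp_uv=amp,
                coupling_strength=dict(config.coupling_strength),
                lag_ms=lag,
                noise_exponent=config.noise_exponent,
                background_uv=config.background_uv,
                sensor_noise_uv=config.sensor_noise_uv,
                rng_seed=int(child_seeds[i]),
            )
        )
    return out


def _narrowband(rng: np.random.Generator, n: int, fs: float, f0: float,
                sigma_hz: float = 0.25) -> np.ndarray:
    """Unit-RMS narrow-band Gaussian noise centered at ``f0`` (bandwidth < 1 Hz)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.exp(-((freqs - f0) ** 2) / (2.0 * sigma_hz**2))
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / np.sqrt(np.mean(x**2))


def _pure_tone(rng: np.random.Generator, n: int, fs: float, f0: float) -> np.ndarray:
    """Unit-RMS sinusoid with random phase (exact-oracle mode)."""
    t = np.arange(n) / fs
    return np.sqrt(2.0) * np.sin(2.0 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))


def _pink(rng: np.random.Generator, n: int, fs: float, exponent: float,
          rms: float) -> np.ndarray:
    """1/f^exponent background noise with the requested RMS."""
    if rms == 0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    x = np.fft.irfft(spec, n=n)
    return rms * x / np.sqrt(np.mean(x**2))


def _advance(x: np.ndarray, seconds: float, fs: float) -> np.ndarray:
    """Circular fractional-sample time advance (ideal band-limited shift)."""
    n = x.size
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return np.fft.irfft(np.fft.rfft(x) * np.exp(2j * np.pi * freqs * seconds), n=n)


def synthesize_sources(
    params: SubjectGenParams,
    duration_s: float = 120.0,
    fs_hz: float = 500.0,
    pure_sine: bool = False,
) -> dict[str, np.ndarray]:
    """Generate the four ROI source time series of one subject.

    Returns a dict keyed by ROI name.  ``pure_sine=True`` replaces the
    narrow-band noise oscillators with random-phase sinusoids, which makes
    the phase relations exact for oracle tests.
    """
    n = int(round(duration_s * fs_hz))
    if n < int(round(2.5 * fs_hz)):
        raise ValueError("duration must cover at least one 2500 ms window")
    rng = np.random.default_rng(params.rng_seed)
    osc = _pure_tone if pure_sine else _narrowband
    sources: dict[str, np.ndarray] = {}
    for h in HEMISPHERES:
        frontal_roi, posterior_roi = _ROI_OF[h]
        f_post = params.iaf_hz[posterior_roi]
        lag_ms = params.lag_ms[h]
        if abs(lag_ms) > 500.0 / f_post:
            raise ValueError(
                f"lag {lag_ms} ms exceeds half the alpha period at {f_post} Hz "
                "(phase-wrap ambiguity)"
            )
        c = params.coupling_strength[h]
        driver = osc(rng, n, fs_hz, f_post)
        indep = osc(rng, n, fs_hz, params.iaf_hz[frontal_roi])
        posterior = _advance(driver, lag_ms / 1000.0, fs_hz)
        frontal = c * driver + np.sqrt(1.0 - c**2) * indep
        frontal = frontal / np.sqrt(np.mean(frontal**2))
        sources[frontal_roi] = params.amp_uv[frontal_roi] * frontal + _pink(
            rng, n, fs_hz, params.noise_exponent, params.background_uv
        )
        sources[posterior_roi] = params.amp_uv[posterior_roi] * posterior + _pink(
            rng, n, fs_hz, params.noise_exponent, params.background_uv
        )
    return sources


def project_to_scalp(
    sources: dict[str, np.ndarray],
    montage: tuple[str, ...] | list[str] = DEFAULT_64_MONTAGE,
    sensor_noise_uv: float = 1.0,
    rng: np.random.Generator | int | None = None,
    fs_hz: float = 500.0,
    subject_id: str | None = None,
    group: str | None = None,
) -> MultichannelRecording:
    """Mix ROI sources to scalp channels with fixed Gaussian topographies.

    Each source is projected with a spatial weight pattern peaking over its
    ROI electrode cluster; independent white sensor noise is added per
    channel.  The montage must contain all 14 cluster electrodes.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    labels = list(montage)
    n = len(next(iter(sources.values())))
    data = np.zeros((len(labels), n))
    for roi, series in sources.items():
        w = roi_topography(labels, roi)
        data += np.outer(w, series)
    if sensor_noise_uv > 0:
        data += sensor_noise_uv * rng.standard_normal(data.shape)
    return MultichannelRecording(
        data=data, fs_hz=fs_hz, channel_labels=labels,
        subject_id=subject_id, group=group,
    )


def generate_subject(
    params: SubjectGenParams,
    duration_s: float = 120.0,
    fs_hz: float = 500.0,
    montage: tuple[str, ...] | list[str] = DEFAULT_64_MONTAGE,
    pure_sine: bool = False,
    keep_truth_components: bool = False,
) -> MultichannelRecording:
    """Sources plus scalp projection for one subject, fully seeded.

    With ``keep_truth_components=True`` the recording's ``meta`` carries a
    ``synthetic-truth`` ComponentSet (the true mixing and source
    activations), usable in place of an ICA decomposition for template
    matching and back-projection.
    """
    sources = synthesize_sources(params, duration_s, fs_hz, pure_sine=pure_sine)
    rec = project_to_scalp(
        sources,
        montage,
        sensor_noise_uv=params.sensor_noise_uv,
        rng=np.random.default_rng(params.rng_seed + 1),
        fs_hz=fs_hz,
        subject_id=params.subject_id,
        group=params.group_label,
    )
    if keep_truth_components:
        from restalpha.preprocessing import components_from_truth

        rec.meta["components"] = components_from_truth(rec, sources)
    return rec


def generate_cohort(
    config_hsg: GroupGenConfig,
    config_lsg: GroupGenConfig,
    n_per_group: int = 24,
    seed: int = 0,
    duration_s: float = 120.0,
    fs_hz: float = 500.0,
    montage: tuple[str, ...] | list[str] = DEFAULT_64_MONTAGE,
    pure_sine: bool = False,
    keep_truth_components: bool = False,
) -> tuple[list[MultichannelRecording], pd.DataFrame]:
    """Balanced two-group cohort plus a ground-truth parameter table."""
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    recordings: list[MultichannelRecording] = []
    rows = []
    for offset, config in ((0, config_hsg), (1, config_lsg)):
        params = sample_subject_params(config, n_per_group, seed=seed * 2 + offset)
        for p in params:
            recordings.append(
                generate_subject(
                    p, duration_s, fs_hz, montage, pure_sine=pure_sine,
                    keep_truth_components=keep_truth_components,
                )
            )
            row = {"subject_id": p.subject_id, "group": p.group_label}
            row.update({f"true_iaf_{r}": p.iaf_hz[r] for r in ROI_NAMES})
            row.update({f"true_amp_{r}": p.amp_uv[r] for r in ROI_NAMES})
            row.update({f"true_lag_ms_{h}": p.lag_ms[h] for h in HEMISPHERES})
            row.update({f"true_coupling_{h}": p.coupling_strength[h] for h in HEMISPHERES})
            rows.append(row)
    return recordings, pd.DataFrame(rows)


def default_group_configs() -> tuple[GroupGenConfig, GroupGenConfig]:
    """The shipped (HSG, LSG) demo parameter sets.

    These encode the direction of every reported group difference: slower
    and weaker right posterior alpha, weaker right intra-hemispheric
    coupling, and a reversed right fronto-posterior lag in the
    high-schizotypy group.
    """
    text = resources.files("restalpha").joinpath("data/default_cohort.json").read_text()
    d = json.loads(text)
    return (
        GroupGenConfig.from_dict(d["HSG"]),
        GroupGenConfig.from_dict(d["LSG"]),
    )
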