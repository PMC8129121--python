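"""Small helpers shared across test modules."""

from restalpha.montage import ROI_NAMES
from restalpha.simulate import GroupGenConfig


def make_default_like_config(**overrides) -> GroupGenConfig:
    """A compact generator config with deterministic means and no dispersion."""
    base = dict(
        group_label="HSG",
        iaf_mean_hz={r: 10.0 for r in ROI_NAMES},
        iaf_sd_hz={r: 0.0 for r in ROI_NAMES},
        amp_mean_uv={"frontal_L": 1.0, "frontal_R": 1.0,
                     "posterior_L": 3.0, "posterior_R": 3.0},
        amp_sd_uv={r: 0.0 for r in ROI_NAMES},
        coupling_strength={"L": 0.5, "R": 0.5},
        lag_ms_mean={"L": -10.0, "R": 5.0},
        lag_ms_sd={"L": 0.0, "R": 0.0},
        background_uv=0.0,
        sensor_noise_uv=0.0,
    )
    base.update(overrides)
    return GroupGenConfig(**base)
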