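"""File I/O: EDF and BrainVision ingest, delimited-text interchange.

The canonical on-disk interchange format is delimited text: per subject a
``<id>.tsv`` channel x time matrix (first column the 10-20 label, values
in microvolts) plus a ``<id>.json`` sidecar with the sampling rate and
cohort metadata.  EDF (.edf) and BrainVision (.vhdr) recordings are read
through MNE and converted to microvolts; writing is text-only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from restalpha.montage import _standard_positions
from restalpha.recording import MultichannelRecording

__all__ = [
    "read_recording",
    "write_recording_txt",
    "read_cohort_dir",
    "write_cohort_dir",
    "read_feature_table",
    "write_feature_table",
]


def _canonical_labels(labels: list[str]) -> list[str]:
    """Map labels case-insensitively onto standard 10-20 names."""
    std = {name.upper(): name for name in _standard_positions()}
    out = []
    for l in labels:
        key = l.strip().upper()
        out.append(std.get(key, l.strip()))
    return out


def read_recording(path: str | Path, fmt: str | None = None) -> MultichannelRecording:
    """Read one recording; format inferred from the extension if omitted.

    Supported: ``edf``, ``brainvision`` (.vhdr) and ``delimited`` (.tsv
    with a JSON sidecar).  Channel data are returned in microvolts.
    """
    path = Path(path)
    if fmt is None:
        fmt = {
            ".edf": "edf",
            ".vhdr": "brainvision",
            ".tsv": "delimited",
            ".txt": "delimited",
        }.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}")
    if fmt == "delimited":
        return _read_delimited(path)
    import mne

    if fmt == "edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif fmt == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    data_uv = raw.get_data() * 1e6  # MNE returns Volts
    return MultichannelRecording(
        data=data_uv,
        fs_hz=float(raw.info["sfreq"]),
        channel_labels=_canonical_labels(list(raw.ch_names)),
        subject_id=path.stem,
    )


def _read_delimited(path: Path) -> MultichannelRecording:
    table = pd.read_csv(path, sep="\t", header=None)
    labels = _canonical_labels([str(v) for v in table.iloc[:, 0]])
    data = table.iloc[:, 1:].to_numpy(dtype=float)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"delimited recording {path.name} has no {sidecar.name} sidecar "
            "(required for the sampling rate and microvolt units)"
        )
    meta = json.loads(sidecar.read_text())
    if "fs_hz" not in meta:
        raise ValueError(f"sidecar {sidecar.name} missing fs_hz")
    return MultichannelRecording(
        data=data,
        fs_hz=float(meta["fs_hz"]),
        channel_labels=labels,
        subject_id=meta.get("subject_id", path.stem),
        group=meta.get("group"),
    )


def write_recording_txt(rec: MultichannelRecording, directory: str | Path,
                        fmt: str = "%.4f") -> Path:
    """Write one recording as ``<id>.tsv`` + ``<id>.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = rec.subject_id or "recording"
    path = directory / f"{stem}.tsv"
    with open(path, "w") as fh:
        for label, row in zip(rec.channel_labels, rec.data):
            fh.write(label + "\t" + "\t".join(fmt % v for v in row) + "\n")
    sidecar = {
        "fs_hz": rec.fs_hz,
        "subject_id": rec.subject_id,
        "group": rec.group,
        "units": "uV",
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def write_cohort_dir(
    recordings: list[MultichannelRecording],
    truth: pd.DataFrame | None,
    directory: str | Path,
) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        write_recording_txt(rec, directory)
    if truth is not None:
        truth.to_csv(directory / "ground_truth.tsv", sep="\t", index=False)
    return directory


def read_cohort_dir(directory: str | Path) -> list[MultichannelRecording]:
    directory = Path(directory)
    recs = []
    for path in sorted(directory.glob("*.tsv")):
        if path.name == "ground_truth.tsv":
            continue
        recs.append(read_recording(path, fmt="delimited"))
    if not recs:
        raise FileNotFoundError(f"no .tsv recordings in {directory}")
    return recs


def write_feature_table(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
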