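"""On-disk formats: delimited channel-matrix recordings, template sets,
run-length-encoded label sequences, and metrics tables.

The delimited recording format is a comma-separated channels x samples
matrix: a header row ``channel,s0,s1,...`` followed by one row per channel
whose first field is the channel label. Sampling rate, subject id,
annotations and bad channels live in a JSON sidecar next to the matrix
(same stem, ``.json``). Intervals are half-open, 0-based samples.

EDF recordings are read through :mod:`mne` when it is installed; EDF is
read-only here.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .microstates import LabelSequence, TemplateSet
from .recording import Recording

__all__ = [
    "write_recording",
    "read_recording",
    "write_templates",
    "read_templates",
    "write_labels",
    "read_labels",
    "write_metrics",
    "read_metrics",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as a delimited matrix plus JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("channel," + ",".join(f"s{i}" for i in range(rec.n_samples)) + "\n")
        for name, row in zip(rec.ch_names, rec.data):
            fh.write(name + "," + ",".join(f"{v:.17g}" for v in row) + "\n")
    meta = {
        "sfreq": rec.sfreq,
        "subject_id": rec.subject_id,
        "annotations": [[int(a), int(b)] for a, b in rec.annotations],
        "bad_channels": list(rec.bad_channels),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def _read_matrix(path: Path) -> Recording:
    names: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        if not header or header[0] != "channel":
            raise ValueError(f"{path}: first header field must be 'channel'")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split(",")
            if not fields[0]:
                raise ValueError(f"{path}:{lineno}: missing channel label in column 1")
            names.append(fields[0])
            try:
                rows.append(np.array(fields[1:], dtype=float))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: non-numeric sample value ({err})")
    lengths = {r.size for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"{path}: rows have unequal sample counts {sorted(lengths)}")
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    if "sfreq" not in meta:
        raise ValueError(f"{path}: sampling rate missing (no JSON sidecar)")
    return Recording(
        data=np.vstack(rows),
        sfreq=float(meta["sfreq"]),
        ch_names=names,
        annotations=[tuple(x) for x in meta.get("annotations", [])],
        bad_channels=list(meta.get("bad_channels", [])),
        subject_id=str(meta.get("subject_id", path.stem)),
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF requires the optional mne dependency") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    ann = []
    for onset, dur, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        if "bad" in desc.lower():
            start = int(round(onset * raw.info["sfreq"]))
            ann.append((start, start + int(round(dur * raw.info["sfreq"]))))
    return Recording(
        data=raw.get_data(),
        sfreq=float(raw.info["sfreq"]),
        ch_names=list(raw.ch_names),
        annotations=ann,
        bad_channels=list(raw.info["bads"]),
        subject_id=path.stem,
    )


def read_recording(path: str | Path, fmt: str | None = None) -> Recording:
    """Read a recording from a delimited matrix (``.csv``) or EDF file."""
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "matrix")
    if fmt == "edf":
        return _read_edf(path)
    return _read_matrix(path)


def write_templates(ts: TemplateSet, path: str | Path, ch_names: list[str] | None = None) -> Path:
    """Templates as delimited text (rows = channels, columns = classes)
    plus a JSON sidecar with fit diagnostics."""
    path = Path(path)
    labels = ts.labels or tuple(f"T{i}" for i in range(ts.k))
    with open(path, "w") as fh:
        fh.write("channel," + ",".join(labels) + "\n")
        for c in range(ts.n_channels):
            name = ch_names[c] if ch_names else f"ch{c}"
            fh.write(name + "," + ",".join(f"{v:.17g}" for v in ts.maps[:, c]) + "\n")
    meta = {
        "labels": list(labels),
        "gev": ts.gev,
        "cv": ts.cv,
        "provenance": ts.provenance,
        "restarts": ts.restarts,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_templates(path: str | Path) -> TemplateSet:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    meta = json.loads(_sidecar(path).read_text())
    return TemplateSet(
        maps=df.to_numpy().T,
        labels=tuple(meta["labels"]),
        gev=meta.get("gev", float("nan")),
        cv=meta.get("cv", float("nan")),
        provenance=meta.get("provenance", ""),
        restarts=meta.get("restarts", 0),
    )


def write_labels(seq: LabelSequence, path: str | Path) -> Path:
    """Run-length-encoded label sequence: start_sample,end_sample,label
    (half-open intervals; masked stretches carry the label '-')."""
    path = Path(path)
    lab = seq.labels
    change = np.flatnonzero(np.diff(lab)) + 1
    starts = np.r_[0, change]
    ends = np.r_[change, lab.size]
    with open(path, "w") as fh:
        fh.write("start_sample,end_sample,label\n")
        for a, b in zip(starts, ends):
            name = "-" if lab[a] < 0 else seq.class_names[lab[a]]
            fh.write(f"{a},{b},{name}\n")
    return path


def read_labels(
    path: str | Path, sfreq: float, class_names: tuple[str, ...] = ("A", "B", "C", "D")
) -> LabelSequence:
    df = pd.read_csv(path)
    n = int(df["end_sample"].iloc[-1])
    lab = np.full(n, -1, dtype=np.int64)
    lut = {c: i for i, c in enumerate(class_names)}
    for _, row in df.iterrows():
        if row["label"] != "-":
            lab[int(row["start_sample"]):int(row["end_sample"])] = lut[row["label"]]
    return LabelSequence(labels=lab, sfreq=sfreq, class_names=class_names)


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    metrics.to_csv(path, index=True)
    return path


def read_metrics(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)
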