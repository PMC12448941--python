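"""File I/O: EDF export/import, the internal session container, TSV tables.

EDF is the clinical interchange format for electrophysiology; sessions can
be exported to EDF (16-bit quantized) and read back through MNE.  The
internal container is a NumPy ``.npz`` archive with a JSON metadata block —
bit-exact, used between pipeline stages.  Tables are TSV with a fixed
column order and floats at 6 significant digits.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    BipolarPair,
    BipolarSession,
    ChannelInfo,
    GroundTruth,
    RecordingSession,
    TractSet,
)
from .errors import ConfigurationError, DataError

__all__ = [
    "save_session",
    "load_session",
    "write_edf",
    "read_edf",
    "write_table",
    "read_table",
    "write_tracts_tsv",
    "read_tracts_tsv",
    "save_ground_truth",
    "load_ground_truth",
]


# ---------------------------------------------------------------------------
# internal container (bit-exact)

def save_session(session: RecordingSession | BipolarSession, path: str | Path) -> Path:
    """Lossless save of a session (raw or bipolar) to an ``.npz`` archive."""
    path = Path(path)
    if isinstance(session, BipolarSession):
        meta = {"kind": "bipolar", "fs": session.fs,
                "pairs": [vars(p) for p in session.pairs]}
    else:
        meta = {"kind": "recording", "fs": session.fs,
                "channels": [vars(c) for c in session.channels]}
    np.savez(path, samples=session.samples, meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8))
    return path


def load_session(path: str | Path) -> RecordingSession | BipolarSession:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        with np.load(path) as z:
            samples = z["samples"]
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
    except Exception as exc:  # corrupt archive -> clean error, no partial session
        raise DataError(f"cannot read session container {path}: {exc}") from exc
    if meta["kind"] == "bipolar":
        pairs = [BipolarPair(**p) for p in meta["pairs"]]
        return BipolarSession(samples=samples, fs=meta["fs"], pairs=pairs)
    channels = [ChannelInfo(**c) for c in meta["channels"]]
    return RecordingSession(samples=samples, fs=meta["fs"], channels=channels)


# ---------------------------------------------------------------------------
# EDF

def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _channel_label(ch: ChannelInfo) -> str:
    return f"{ch.lead}.{ch.hemisphere}.{ch.region}.{ch.contact}"


def write_edf(session: RecordingSession, path: str | Path) -> Path:
    """Export a session to EDF (one-second records, int16 quantization).

    Requires an integer sampling rate; the recording is truncated to whole
    seconds.  Channel metadata is packed into the 16-character EDF label as
    ``lead.hemisphere.region.contact`` and the subject id into the patient
    field, so a round trip restores the full channel table.
    """
    path = Path(path)
    fs = session.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError(f"EDF export needs an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per one-second record
    n_records = session.n_times // spr
    if n_records == 0:
        raise DataError("recording shorter than one EDF record (1 s)")
    if n_records * spr != session.n_times:
        warnings.warn("recording truncated to whole seconds for EDF export")
    ns = session.n_channels
    data = session.samples[:, : n_records * spr]

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    scale = phys_max / 32767.0
    digital = np.round(data / scale[:, None]).astype("<i2")

    subject = session.channels[0].subject if session.channels else "unknown"
    header = b"".join([
        _edf_field("0", 8),
        _edf_field(subject, 80),
        _edf_field("tractgain synthetic session", 80),
        _edf_field("01.01.00", 8),
        _edf_field("00.00.00", 8),
        _edf_field(256 * (1 + ns), 8),
        _edf_field("", 44),
        _edf_field(n_records, 8),
        _edf_field(1, 8),
        _edf_field(ns, 4),
    ])
    labels = b"".join(_edf_field(_channel_label(c), 16) for c in session.channels)
    transducer = b"".join(_edf_field("", 80) for _ in range(ns))
    phys_dim = b"".join(_edf_field("uV", 8) for _ in range(ns))
    pmin = b"".join(_edf_field(f"{-m:.6g}"[:8], 8) for m in phys_max)
    pmax = b"".join(_edf_field(f"{m:.6g}"[:8], 8) for m in phys_max)
    dmin = b"".join(_edf_field(-32767, 8) for _ in range(ns))
    dmax = b"".join(_edf_field(32767, 8) for _ in range(ns))
    prefilter = b"".join(_edf_field("", 80) for _ in range(ns))
    spr_f = b"".join(_edf_field(spr, 8) for _ in range(ns))
    reserved = b"".join(_edf_field("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header + labels + transducer + phys_dim + pmin + pmax
                 + dmin + dmax + prefilter + spr_f + reserved)
        for r in range(n_records):
            sl = slice(r * spr, (r + 1) * spr)
            for c in range(ns):
                fh.write(digital[c, sl].tobytes())
    return path


def _parse_label(label: str, subject: str) -> ChannelInfo:
    parts = label.strip().split(".")
    if len(parts) != 4:
        raise DataError(f"EDF channel label {label!r} not parseable as lead.hemi.region.contact")
    lead, hemi, region, contact = parts
    return ChannelInfo(subject=subject.strip() or "unknown", hemisphere=hemi,
                       lead=lead, region=region, contact=int(contact))


def read_edf(path: str | Path) -> RecordingSession:
    """Load an EDF file through MNE into a :class:`RecordingSession` (µV)."""
    import mne

    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:
        raise DataError(f"cannot read EDF file {path}: {exc}") from exc
    with open(path, "rb") as fh:
        fh.seek(8)
        subject = fh.read(80).decode("ascii", errors="replace").strip()
    channels = [_parse_label(name, subject) for name in raw.ch_names]
    samples = raw.get_data() * 1e6  # MNE scales the uV dimension to volts
    return RecordingSession(samples=samples, fs=float(raw.info["sfreq"]), channels=channels)


# ---------------------------------------------------------------------------
# tables

def write_table(df: pd.DataFrame, path: str | Path, columns: list[str] | None = None) -> Path:
    """TSV with fixed column order and floats at 6 significant digits."""
    path = Path(path)
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise DataError(f"table is missing required column(s): {missing}")
        df = df[columns]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t")


TRACT_COLUMNS = ["subject", "hemisphere", "pathway", "streamline", "point",
                 "x", "y", "z", "l1", "l2", "l3"]


def write_tracts_tsv(
    tracts: dict[tuple[str, str, str], TractSet], path: str | Path
) -> Path:
    """Per-point tract table keyed by (subject, hemisphere, pathway)."""
    rows = []
    for (subject, hemi, pathway), ts in tracts.items():
        for si, (line, ev) in enumerate(zip(ts.streamlines, ts.eigenvalues)):
            for pi, (x, y, z) in enumerate(line):
                rows.append((subject, hemi, pathway, si, pi, x, y, z, *ev))
    df = pd.DataFrame(rows, columns=TRACT_COLUMNS)
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.8g")
    return Path(path)


def read_tracts_tsv(path: str | Path) -> dict[tuple[str, str, str], TractSet]:
    df = read_table(path)
    missing = [c for c in TRACT_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"tract table missing column(s): {missing}")
    out: dict[tuple[str, str, str], TractSet] = {}
    for key, grp in df.groupby(["subject", "hemisphere", "pathway"], sort=True):
        lines, evs = [], []
        for _, sgrp in grp.groupby("streamline", sort=True):
            sgrp = sgrp.sort_values("point")
            lines.append(sgrp[["x", "y", "z"]].to_numpy(dtype=float))
            evs.append(sgrp.iloc[0][["l1", "l2", "l3"]].to_numpy(dtype=float))
        out[tuple(key)] = TractSet(streamlines=lines, eigenvalues=np.array(evs),
                                   region_pair=("", ""))
    return out


# ---------------------------------------------------------------------------
# ground-truth sidecar

def save_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    d = {}
    for k, v in vars(truth).items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
        elif isinstance(v, tuple):
            d[k] = list(v)
        else:
            d[k] = v
    Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))
    return Path(path)


def load_ground_truth(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    if d.get("filter_sos") is not None:
        d["filter_sos"] = np.asarray(d["filter_sos"])
    if d.get("pathway_fa") is not None:
        d["pathway_fa"] = np.asarray(d["pathway_fa"])
    if d.get("true_beta") is not None:
        d["true_beta"] = tuple(d["true_beta"])
    return GroundTruth(**d)
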