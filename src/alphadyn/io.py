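"""Recording file I/O: CSV with a JSON sidecar, and 16-bit EDF.

CSV layout is samples x channels with a header row of channel names, plus a
sidecar JSON (same stem, ``.json``) carrying sampling rate, subject id,
condition and group.  EDF files are written by a minimal built-in EDF writer
(16-bit samples, 1-s data records) and read back through MNE; EDF metadata
not expressible in the format (group/condition) travels in the same sidecar.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .simulate import Recording

logger = logging.getLogger(__name__)

__all__ = ["read_recording", "write_recording", "write_recording_csv", "write_recording_edf"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _write_sidecar(rec: Recording, path: Path) -> None:
    meta = {
        "fs": rec.fs,
        "channel_names": list(rec.channel_names),
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "group": rec.group,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def write_recording_csv(rec: Recording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(path, index=False, float_format="%.10g")
    _write_sidecar(rec, path)
    return path


def _edf_header_field(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_recording_edf(rec: Recording, path: str | Path) -> Path:
    """Minimal EDF writer: int16 samples, one-second data records.

    Physical scaling is per channel over its actual range, so the round-trip
    is exact to 16-bit quantization of that range.
    """
    path = Path(path)
    fs = rec.fs
    spr = int(round(fs))  # samples per 1-s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_rec = rec.n_samples // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record")
    data = rec.data[:, : n_rec * spr]
    n_ch = rec.n_channels

    # integer physical bounds: they must fit EDF's 8-ASCII-char fields exactly
    phys_min = np.floor(data.min(axis=1)) - 1.0
    phys_max = np.ceil(data.max(axis=1)) + 1.0
    span = phys_max - phys_min
    dig_min, dig_max = -32768, 32767
    scale = (dig_max - dig_min) / span
    digital = np.clip(
        np.rint((data - phys_min[:, None]) * scale[:, None]) + dig_min,
        dig_min,
        dig_max,
    ).astype("<i2")

    header = b"".join(
        [
            _edf_header_field("0", 8),  # version
            _edf_header_field(f"{rec.subject_id} {rec.group}", 80),
            _edf_header_field(f"cond {rec.condition}", 80),
            _edf_header_field("01.01.00", 8),
            _edf_header_field("00.00.00", 8),
            _edf_header_field(str(256 * (1 + n_ch)), 8),
            _edf_header_field("", 44),
            _edf_header_field(str(n_rec), 8),
            _edf_header_field("1", 8),  # record duration, s
            _edf_header_field(str(n_ch), 4),
        ]
    )
    sig_fields = [
        b"".join(_edf_header_field(name, 16) for name in rec.channel_names),
        b"".join(_edf_header_field("EEG", 80) for _ in range(n_ch)),
        b"".join(_edf_header_field("uV", 8) for _ in range(n_ch)),
        b"".join(_edf_header_field(str(int(v)), 8) for v in phys_min),
        b"".join(_edf_header_field(str(int(v)), 8) for v in phys_max),
        b"".join(_edf_header_field(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(_edf_header_field(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(_edf_header_field("", 80) for _ in range(n_ch)),
        b"".join(_edf_header_field(str(spr), 8) for _ in range(n_ch)),
        b"".join(_edf_header_field("", 32) for _ in range(n_ch)),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in sig_fields:
            fh.write(block)
        # data records: per record, all samples of ch0, then ch1, ...
        recs = digital.reshape(n_ch, n_rec, spr)
        for r in range(n_rec):
            fh.write(recs[:, r].tobytes())
    _write_sidecar(rec, path)
    return path


def write_recording(rec: Recording, path: str | Path, fmt: Optional[str] = None) -> Path:
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return write_recording_csv(rec, path)
    if fmt == "edf":
        return write_recording_edf(rec, path)
    raise ValueError(f"unsupported recording format {fmt!r}")


def _read_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if not sc.exists():
        raise FileNotFoundError(
            f"missing sidecar {sc.name}: the CSV format carries fs, subject_id, "
            "condition and group in a JSON sidecar"
        )
    meta = json.loads(sc.read_text())
    for key in ("fs", "subject_id", "condition", "group"):
        if key not in meta:
            raise ValueError(f"sidecar {sc.name} is missing required field {key!r}")
    return meta


def read_recording(path: str | Path) -> Recording:
    """Read a CSV+sidecar or EDF recording into a validated `Recording`."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        meta = _read_sidecar(path)
        df = pd.read_csv(path)
        data = df.to_numpy(dtype=np.float64).T
        names = list(df.columns)
        if "channel_names" in meta and list(meta["channel_names"]) != names:
            raise ValueError("sidecar channel_names disagree with CSV header")
        return Recording(
            data, float(meta["fs"]), names, meta["subject_id"],
            meta["condition"], meta["group"],
        )
    if suffix == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
        data = raw.get_data()
        # mne scales EDF "uV" channels to volts; undo to recover physical units
        data = data * 1e6
        names = list(raw.ch_names)
        sc = _sidecar_path(path)
        if sc.exists():
            meta = json.loads(sc.read_text())
        else:
            meta = {"subject_id": path.stem, "condition": "pre", "group": "low"}
            logger.warning("EDF %s has no sidecar; using placeholder labels", path.name)
        return Recording(
            data,
            float(raw.info["sfreq"]),
            names,
            meta.get("subject_id", path.stem),
            meta.get("condition", "pre"),
            meta.get("group", "low"),
        )
    raise ValueError(f"unsupported recording file {path.name!r}")
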