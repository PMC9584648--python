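"""Reading and writing recordings, montages and result tables.

Two on-disk recording formats are supported:

* **EDF** (European Data Format): read through MNE's native EDF reader;
  written by a small built-in writer (EDF is a fixed-layout 16-bit format,
  one second per data record).  Round-tripping is exact up to the 16-bit
  amplitude quantization the format imposes.
* **delimited matrix**: a tab-separated file whose header row holds the
  channel labels and whose subsequent rows are samples (one column per
  channel), with a JSON sidecar carrying the sampling rate and state tag.

Montages travel as ``label,region,hemisphere,x,y`` CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Montage, Recording

logger = logging.getLogger(__name__)

_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as EDF with 1-s data records.

    The sampling rate must be a whole number of samples per second; the
    trailing partial second is discarded.  Amplitudes are scaled per channel
    to the full 16-bit digital range.
    """
    path = Path(path)
    fs = rec.fs_hz
    spr = int(round(fs))
    if abs(fs - spr) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    n_records = rec.n_samples // spr
    if n_records < 1:
        raise ValueError("recording shorter than one 1-s EDF record")
    data = rec.data[:, : n_records * spr]

    pmins = data.min(axis=1)
    pmaxs = data.max(axis=1)
    flat = pmaxs - pmins <= 0
    pmaxs = np.where(flat, pmins + 1.0, pmaxs)

    ns = rec.n_channels
    header_bytes = 256 + 256 * ns
    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad(f"Startdate X X X X state={rec.state}", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(header_bytes), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(ns), 4))

        for label in rec.labels:
            fh.write(_pad(label, 16))
        for _ in rec.labels:
            fh.write(_pad("", 80))  # transducer
        for _ in rec.labels:
            fh.write(_pad("uV", 8))
        for v in pmins:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        for v in pmaxs:
            fh.write(_pad(f"{v:.6g}"[:8], 8))
        fh.write(_pad(str(_DIG_MIN), 8) * ns)
        fh.write(_pad(str(_DIG_MAX), 8) * ns)
        for _ in rec.labels:
            fh.write(_pad("", 80))  # prefiltering
        fh.write(_pad(str(spr), 8) * ns)
        fh.write(_pad("", 32) * ns)

        # physical→digital scaling uses the printed (8-char) header values so
        # the reader inverts the transform exactly
        pmins_r = np.array([float(f"{v:.6g}"[:8]) for v in pmins])
        pmaxs_r = np.array([float(f"{v:.6g}"[:8]) for v in pmaxs])
        gain = (_DIG_MAX - _DIG_MIN) / (pmaxs_r - pmins_r)
        for r in range(n_records):
            chunk = data[:, r * spr : (r + 1) * spr]
            dig = np.rint((chunk - pmins_r[:, None]) * gain[:, None] + _DIG_MIN)
            dig = np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2")
            fh.write(dig.tobytes())
    return path


def read_edf(path: str | Path, state: str = "synthetic") -> Recording:
    """Read an EDF recording via MNE, returning amplitudes in µV."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data(units="uV")
    state_tag = state
    with open(path, "rb") as fh:  # recording-id header field, offset 88
        fh.seek(88)
        rec_id = fh.read(80).decode("ascii", errors="replace")
    if "state=" in rec_id:
        state_tag = rec_id.split("state=")[1].split()[0]
    return Recording(tuple(raw.ch_names), float(raw.info["sfreq"]), data,
                     state_tag)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_matrix(rec: Recording, path: str | Path) -> Path:
    """Write a recording as TSV (header = labels, rows = samples) + sidecar."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.labels))
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")
    _sidecar_path(path).write_text(
        json.dumps({"fs_hz": rec.fs_hz, "state": rec.state}) + "\n"
    )
    return path


def read_matrix(path: str | Path, fs_hint: float | None = None,
                state: str | None = None) -> Recording:
    """Read a delimited-matrix recording.

    The sampling rate comes from the JSON sidecar or ``fs_hint``; a missing
    rate is an error.  Duplicate header labels are rejected.
    """
    path = Path(path)
    fs, state_tag = fs_hint, state
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        fs = meta.get("fs_hz", fs)
        state_tag = state_tag or meta.get("state")
    if fs is None:
        raise ValueError(
            f"no sampling rate for {path}: provide fs_hint or a sidecar "
            f"{sidecar.name} with an 'fs_hz' field"
        )
    with open(path) as fh:  # pandas mangles duplicate headers; check raw line
        header = fh.readline().rstrip("\n")
    sep = "\t" if "\t" in header else ","
    labels = header.split(sep)
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate channel labels in {path} header")
    df = pd.read_csv(path, sep=sep)
    return Recording(tuple(labels), float(fs), df.to_numpy(dtype=float).T,
                     state_tag or "synthetic")


def read_recording(path: str | Path, format: str | None = None,
                   fs_hint: float | None = None,
                   state: str | None = None) -> Recording:
    """Read EDF or delimited-matrix recordings, dispatching on extension.

    ``format`` may be ``"edf"`` or ``"matrix"``; when None it is inferred
    from the file suffix (.edf → EDF, anything else → matrix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "matrix"
    if format == "edf":
        return read_edf(path, state=state or "synthetic")
    if format == "matrix":
        return read_matrix(path, fs_hint=fs_hint, state=state)
    raise ValueError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# montage CSV


def write_montage_csv(mont: Montage, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {"label": l, "region": info.region, "hemisphere": info.hemisphere,
         "x": info.x, "y": info.y}
        for l, info in mont.channels.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_montage_csv(path: str | Path) -> Montage:
    df = pd.read_csv(path)
    required = {"label", "region", "hemisphere", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"montage file {path} lacks columns: {sorted(missing)}")
    return Montage.from_mapping(
        {
            str(r.label): (str(r.region), str(r.hemisphere), float(r.x),
                           float(r.y))
            for r in df.itertuples()
        }
    )


def write_connectivity_csv(matrix: np.ndarray, labels: tuple[str, ...],
                           path: str | Path) -> Path:
    """Square connectivity matrix as CSV with channel-label headers."""
    path = Path(path)
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(path)
    return path
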