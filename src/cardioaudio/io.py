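"""On-disk formats: EDF continuous recordings, TSV tables, JSON sidecars.

Continuous data are written as plain EDF (one file per subject, 16-bit
samples, 1-second data records), EEG channels in microvolts and ECG in
millivolts.  The writer/reader pair here implements the EDF container
directly so round-trips are exact to one quantization step; files are
standard EDF and open in any EDF-aware tool.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ContinuousRecording, SensorLayout, validate_events

_EDF_DATE = "01.01.20"
_EDF_TIME = "00.00.00"


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _phys_bounds(x: np.ndarray) -> tuple[float, float]:
    """Symmetric physical range, printed and re-parsed so writer and reader
    use the identical value (keeps quantization error within one step)."""
    amax = float(np.max(np.abs(x))) if x.size else 1.0
    if amax == 0:
        amax = 1.0
    s = f"{amax * 1.0001:.6g}"[:8]
    amax = float(s)
    return -amax, amax


def write_edf(rec: ContinuousRecording, path: str | Path) -> None:
    """Write a recording as EDF with 1-s data records (zero-padded tail)."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))
    n_rec = int(np.ceil(rec.n_samples / spr))
    ns = rec.n_channels

    padded = np.zeros((ns, n_rec * spr))
    padded[:, :rec.n_samples] = rec.data
    dmin, dmax = -32768, 32767
    scaled = np.empty_like(padded, dtype="<i2")
    pmins, pmaxs = [], []
    for i in range(ns):
        pmin, pmax = _phys_bounds(padded[i])
        pmins.append(pmin)
        pmaxs.append(pmax)
        gain = (dmax - dmin) / (pmax - pmin)
        scaled[i] = np.clip(np.round((padded[i] - pmin) * gain + dmin),
                            dmin, dmax).astype("<i2")

    units = {"eeg": "uV", "mastoid": "uV", "ecg": "mV"}
    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii("X X X X", 80))
        fh.write(_ascii("Startdate 01-JAN-2020 X X X", 80))
        fh.write(_ascii(_EDF_DATE, 8))
        fh.write(_ascii(_EDF_TIME, 8))
        fh.write(_ascii(256 * (ns + 1), 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(n_rec, 8))
        fh.write(_ascii("1", 8))
        fh.write(_ascii(ns, 4))
        for name in rec.ch_names:
            fh.write(_ascii(name, 16))
        for kind in rec.ch_kinds:
            fh.write(_ascii(kind, 80))
        for kind in rec.ch_kinds:
            fh.write(_ascii(units.get(kind, ""), 8))
        for p in pmins:
            fh.write(_ascii(f"{p:.6g}"[:8], 8))
        for p in pmaxs:
            fh.write(_ascii(f"{p:.6g}"[:8], 8))
        for _ in range(ns):
            fh.write(_ascii(dmin, 8))
        for _ in range(ns):
            fh.write(_ascii(dmax, 8))
        for _ in range(ns):
            fh.write(_ascii("", 80))
        for _ in range(ns):
            fh.write(_ascii(spr, 8))
        for _ in range(ns):
            fh.write(_ascii("", 32))
        # data records: per record, all samples of signal 1, then signal 2...
        blocks = scaled.reshape(ns, n_rec, spr)
        fh.write(np.ascontiguousarray(
            np.transpose(blocks, (1, 0, 2))).tobytes())


def read_edf(path: str | Path) -> ContinuousRecording:
    """Read an EDF file written by :func:`write_edf` (plain EDF, one
    sampling rate across signals)."""
    with open(path, "rb") as fh:
        header = fh.read(256)
        if len(header) < 256:
            raise ValueError("truncated EDF header")
        n_rec = int(header[236:244].decode("ascii"))
        rec_dur = float(header[244:252].decode("ascii"))
        ns = int(header[252:256].decode("ascii"))
        sig = fh.read(256 * ns)
        if len(sig) < 256 * ns:
            raise ValueError("truncated EDF signal header")

        def field(offset, width):
            base = offset * ns
            return [sig[base + i * width: base + (i + 1) * width]
                    .decode("ascii").strip() for i in range(ns)]

        labels = field(0, 16)
        kinds = field(16, 80)
        pmin = np.array([float(v) for v in field(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in field(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in field(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in field(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in field(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError("mixed sampling rates are not supported")
        spr = spr[0]
        fs = spr / rec_dur

        raw = fh.read(n_rec * ns * spr * 2)
        if len(raw) < n_rec * ns * spr * 2:
            raise ValueError("truncated EDF data section")
    digital = np.frombuffer(raw, dtype="<i2").reshape(n_rec, ns, spr)
    digital = np.transpose(digital, (1, 0, 2)).reshape(ns, -1).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]
    known = {"eeg", "ecg", "mastoid"}
    bad = set(kinds) - known
    if bad:
        raise ValueError(f"unknown channel kinds in EDF: {sorted(bad)}")
    return ContinuousRecording(data, fs, labels, kinds)


# ---------------------------------------------------------------------------
# tables and sidecars

def read_events(path: str | Path, fs: float | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"attention": str, "delay": str})
    return validate_events(df, fs)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_behavior(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_layout(path: str | Path) -> SensorLayout:
    return SensorLayout.from_frame(pd.read_csv(path, sep="\t"))


def write_layout(layout: SensorLayout, path: str | Path) -> None:
    layout.to_frame().to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
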