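"""Reading and writing continuous recordings and result tables.

Two containers are supported:

* EDF (European Data Format, 16-bit): the standard EEG interchange format.
  The writer uses 1-s data records, a symmetric physical range per channel,
  and requires an integer sampling rate and a whole number of seconds.
* A delimited UTF-8 text format (one column per channel, ``#``-prefixed
  header carrying fs and start offset), bit-exact on round-trip and meant
  for small human-inspectable fixtures.

Event series travel as sidecar delimited files (index, time_s).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import ContinuousRecording, EventSeries

_EDF_DMIN, _EDF_DMAX = -32768, 32767


def _fmt(field: str, width: int) -> bytes:
    s = str(field)[:width]
    return s.ljust(width).encode("ascii")


def _phys_bound(x: np.ndarray) -> float:
    """Symmetric physical bound rounded up to 4 significant digits so that
    the 8-char header field represents it exactly."""
    m = float(np.max(np.abs(x))) if x.size else 0.0
    if m == 0.0:
        return 1.0
    exp = int(np.floor(np.log10(m)))
    q = 10.0 ** (exp - 3)
    return float(np.ceil(m / q) * q)


def write_edf(rec: ContinuousRecording, path) -> None:
    """Write a recording as 16-bit EDF with 1-s data records."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF export requires an integer sampling rate, got {fs}")
    spr = int(round(fs))
    if rec.n_samples % spr:
        raise ValueError(
            f"EDF export requires a whole number of seconds "
            f"({rec.n_samples} samples at {spr} Hz); pad or trim first"
        )
    n_rec = rec.n_samples // spr
    ns = rec.n_channels
    bounds = [_phys_bound(ch) for ch in rec.data]
    # Re-parse the formatted bound so header and scaling agree exactly.
    bounds = [float(f"{b:.8g}"[:8]) for b in bounds]

    with open(path, "wb") as f:
        f.write(_fmt("0", 8))
        f.write(_fmt("X X X X", 80))          # local patient id
        f.write(_fmt("Startdate X X X X", 80))
        f.write(_fmt("01.01.00", 8))
        f.write(_fmt("00.00.00", 8))
        f.write(_fmt(str(256 * (1 + ns)), 8))
        f.write(_fmt("", 44))
        f.write(_fmt(str(n_rec), 8))
        f.write(_fmt("1", 8))                 # record duration, s
        f.write(_fmt(str(ns), 4))
        for lab in rec.channel_labels:
            f.write(_fmt(lab, 16))
        for _ in range(ns):
            f.write(_fmt("", 80))             # transducer
        for _ in range(ns):
            f.write(_fmt("uV", 8))
        for b in bounds:
            f.write(_fmt(f"{-b:.8g}"[:8], 8))
        for b in bounds:
            f.write(_fmt(f"{b:.8g}"[:8], 8))
        for _ in range(ns):
            f.write(_fmt(str(_EDF_DMIN), 8))
        for _ in range(ns):
            f.write(_fmt(str(_EDF_DMAX), 8))
        for _ in range(ns):
            f.write(_fmt("", 80))             # prefiltering
        for _ in range(ns):
            f.write(_fmt(str(spr), 8))
        for _ in range(ns):
            f.write(_fmt("", 32))

        scale = [(_EDF_DMAX - _EDF_DMIN) / (2 * b) for b in bounds]
        for r in range(n_rec):
            for c in range(ns):
                seg = rec.data[c, r * spr : (r + 1) * spr]
                dig = np.round((seg + bounds[c]) * scale[c] + _EDF_DMIN)
                dig = np.clip(dig, _EDF_DMIN, _EDF_DMAX).astype("<i2")
                f.write(dig.tobytes())


def read_edf(path) -> ContinuousRecording:
    """Read a 16-bit EDF file into a recording (physical units honored)."""
    with open(path, "rb") as f:
        hdr = f.read(256)
        if len(hdr) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        n_rec = int(hdr[236:244].decode("ascii"))
        rec_dur = float(hdr[244:252].decode("ascii"))
        ns = int(hdr[252:256].decode("ascii"))
        sig = f.read(256 * ns)

        def field(off, width, i):
            base = off * ns + i * width
            return sig[base:base + width].decode("ascii").strip()

        labels = [field(0, 16, i) for i in range(ns)]
        pmin = [float(field(16 + 80 + 8, 8, i) or "nan") for i in range(ns)]
        pmax = [float(field(16 + 80 + 8 + 8, 8, i) or "nan") for i in range(ns)]
        dmin = [int(field(16 + 80 + 8 + 16, 8, i)) for i in range(ns)]
        dmax = [int(field(16 + 80 + 8 + 24, 8, i)) for i in range(ns)]
        spr = [int(field(16 + 80 + 8 + 32 + 80, 8, i)) for i in range(ns)]

        if any(not l for l in labels):
            raise ValueError(f"{path}: missing channel labels")
        if len(set(spr)) != 1:
            raise ValueError(f"{path}: non-uniform sampling rate across channels: {spr}")
        fs = spr[0] / rec_dur

        raw = f.read(2 * sum(spr) * n_rec)
        # widen before arithmetic: int16 minus the digital minimum overflows
        dig = np.frombuffer(raw, dtype="<i2").astype(np.int64)
        data = np.empty((ns, spr[0] * n_rec))
        per_rec = sum(spr)
        for c in range(ns):
            off = sum(spr[:c])
            g = (pmax[c] - pmin[c]) / (dmax[c] - dmin[c])
            for r in range(n_rec):
                seg = dig[r * per_rec + off : r * per_rec + off + spr[c]]
                data[c, r * spr[c] : (r + 1) * spr[c]] = (seg - dmin[c]) * g + pmin[c]

    return ContinuousRecording(data, fs, tuple(labels))


def edf_quantization_step(rec: ContinuousRecording) -> np.ndarray:
    """Per-channel physical value of one 16-bit step as written by write_edf."""
    return np.array(
        [2 * float(f"{_phys_bound(ch):.8g}"[:8]) / (_EDF_DMAX - _EDF_DMIN) for ch in rec.data]
    )


def write_delimited(rec: ContinuousRecording, path) -> None:
    with open(path, "w", encoding="utf-8") as f:
        f.write("# mrcpkit continuous recording\n")
        f.write(f"# fs_hz={rec.fs!r} start_offset={rec.start_offset!r}\n")
        f.write(",".join(rec.channel_labels) + "\n")
        np.savetxt(f, rec.data.T, fmt="%.17g", delimiter=",")


def read_delimited(path) -> ContinuousRecording:
    fs = None
    offset = 0.0
    with open(path, "r", encoding="utf-8") as f:
        pos = f.tell()
        line = f.readline()
        while line.startswith("#"):
            for tok in line[1:].split():
                if tok.startswith("fs_hz="):
                    fs = float(tok.split("=", 1)[1])
                elif tok.startswith("start_offset="):
                    offset = float(tok.split("=", 1)[1])
            pos = f.tell()
            line = f.readline()
        if fs is None:
            raise ValueError(f"{path}: header does not declare fs_hz")
        labels = [s.strip() for s in line.strip().split(",")]
        if any(not l for l in labels):
            raise ValueError(f"{path}: missing channel labels")
        f.seek(pos)
        df = pd.read_csv(f, float_precision="round_trip")
    return ContinuousRecording(df.to_numpy().T, fs, tuple(labels), offset)


def read_recording(path, format: str | None = None) -> ContinuousRecording:
    """Read EDF or delimited recording; format inferred from the extension."""
    fmt = format or ("edf" if str(path).lower().endswith(".edf") else "delimited")
    if fmt == "edf":
        return read_edf(path)
    if fmt in ("delimited", "csv"):
        return read_delimited(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_recording(rec: ContinuousRecording, path, format: str | None = None) -> None:
    fmt = format or ("edf" if str(path).lower().endswith(".edf") else "delimited")
    if fmt == "edf":
        write_edf(rec, path)
    elif fmt in ("delimited", "csv"):
        write_delimited(rec, path)
    else:
        raise ValueError(f"unknown recording format {fmt!r}")


def write_events(events: EventSeries, path) -> None:
    df = pd.DataFrame(
        {"index": np.arange(len(events)), "time_s": events.onset_times}
    )
    df.to_csv(path, index=False)


def read_events(path, source: str = "emg-detected") -> EventSeries:
    df = pd.read_csv(path)
    return EventSeries(df["time_s"].to_numpy(), source=source)


def write_table(rows, path, columns=None) -> None:
    """Write result rows (list of dicts or DataFrame) as a delimited table.

    Column order is fixed by `columns` when given; an empty input yields a
    header-only file.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=columns)
    if columns is not None:
        df = df.reindex(columns=columns)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
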