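"""Readers and writers for ECG waveforms, beat annotations and RR intervals.

Waveforms travel as EDF (European Data Format); beats and RR intervals as
plain one-column CSV/TSV text.  The EDF support here is deliberately minimal:
uncompressed 16-bit EDF with ordinary signal channels, which is what wearable
ECG exports contain.  EDF+ annotation streams are not interpreted.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .types import BeatAnnotation, DataError, ECGRecord, Phase, PhaseSegmentation, RRSequence

__all__ = [
    "ChannelNotFoundError",
    "CorruptEDFError",
    "read_edf",
    "write_edf",
    "read_beats",
    "write_beats",
    "read_rr",
    "write_rr",
    "read_phases",
    "rr_from_beats",
    "beats_from_rr",
]


class CorruptEDFError(DataError):
    """The file is not parseable as EDF."""


class ChannelNotFoundError(DataError):
    """The requested channel is not present in the EDF file."""


_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value: str, width: int) -> bytes:
    out = value.encode("ascii", errors="replace")[:width]
    return out.ljust(width)


def write_edf(records: ECGRecord | Sequence[ECGRecord], path: str | Path) -> None:
    """Write one or more equal-rate channels as 16-bit EDF.

    Samples are quantized onto each signal's physical min/max range, so a
    read-back reproduces them up to one quantization step.  When ``fs`` is a
    whole number and divides the sample count, one-second data records are
    used and the sampling frequency round-trips exactly; otherwise the whole
    signal is stored as a single data record.
    """
    if isinstance(records, ECGRecord):
        records = [records]
    if not records:
        raise DataError("need at least one channel to write")
    fs = records[0].fs
    n = records[0].samples.size
    if any(r.fs != fs or r.samples.size != n for r in records):
        raise DataError("all EDF channels must share sampling frequency and length")

    if float(fs).is_integer() and n % int(fs) == 0:
        spr = int(fs)
        n_records = n // spr
        duration_str = "1"
    else:
        spr = n
        n_records = 1
        duration_str = f"{n / fs:.8g}"[:8]
        if not math.isclose(float(duration_str), n / fs, rel_tol=1e-9):
            warnings.warn(
                "record duration does not fit the EDF header exactly; "
                "sampling frequency will round-trip approximately",
                stacklevel=2,
            )

    ns = len(records)
    digitals, pmins, pmaxs = [], [], []
    for record in records:
        samples = record.samples
        pmin, pmax = float(samples.min()), float(samples.max())
        if pmax == pmin:  # flat signal still needs a nonzero physical range
            pmin, pmax = pmin - 1.0, pmax + 1.0
        scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)
        digital = np.round((samples - pmin) / scale).astype(np.int64) + _DIG_MIN
        digitals.append(np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2"))
        pmins.append(pmin)
        pmaxs.append(pmax)

    header = b"".join(
        [
            _ascii("0", 8),
            _ascii("X X X X", 80),
            _ascii("Startdate X X X X", 80),
            _ascii("01.01.00", 8),
            _ascii("00.00.00", 8),
            _ascii(str(256 + 256 * ns), 8),
            _ascii("", 44),
            _ascii(str(n_records), 8),
            _ascii(duration_str, 8),
            _ascii(str(ns), 4),
        ]
    )

    def field(width: int, values: list[str]) -> bytes:
        return b"".join(_ascii(v, width) for v in values)

    signal_header = b"".join(
        [
            field(16, [r.channel_label for r in records]),
            field(80, [""] * ns),
            field(8, ["mV"] * ns),
            field(8, [f"{p:.8g}"[:8] for p in pmins]),
            field(8, [f"{p:.8g}"[:8] for p in pmaxs]),
            field(8, [str(_DIG_MIN)] * ns),
            field(8, [str(_DIG_MAX)] * ns),
            field(80, [""] * ns),
            field(8, [str(spr)] * ns),
            field(32, [""] * ns),
        ]
    )
    body = np.empty((n_records, ns, spr), dtype="<i2")
    for c, digital in enumerate(digitals):
        body[:, c, :] = digital.reshape(n_records, spr)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(signal_header)
        fh.write(body.tobytes())


def _parse_edf_header(raw: bytes) -> dict:
    if len(raw) < 256:
        raise CorruptEDFError("file shorter than the 256-byte EDF header")
    try:
        n_records = int(raw[236:244].decode("ascii").strip())
        duration = float(raw[244:252].decode("ascii").strip())
        n_signals = int(raw[252:256].decode("ascii").strip())
    except (UnicodeDecodeError, ValueError) as exc:
        raise CorruptEDFError(f"unparseable EDF header: {exc}") from exc
    if n_signals <= 0 or n_records < 0 or duration <= 0:
        raise CorruptEDFError("EDF header fields out of range")
    return {"n_records": n_records, "duration": duration, "n_signals": n_signals}


def read_edf(path: str | Path, channel: int | str = 0) -> ECGRecord:
    """Read one channel of an EDF/EDF+ file.

    Parameters
    ----------
    path : path
        EDF file to read.
    channel : int or str
        Channel index (0-based) or header label (whitespace-insensitive).

    Raises
    ------
    FileNotFoundError, ChannelNotFoundError, CorruptEDFError
    """
    path = Path(path)
    with open(path, "rb") as fh:
        raw = fh.read()
    head = _parse_edf_header(raw[:256])
    ns = head["n_signals"]
    sig_hdr = raw[256 : 256 + ns * 256]
    if len(sig_hdr) < ns * 256:
        raise CorruptEDFError("truncated EDF signal header")

    def fields(offset: int, width: int) -> list[str]:
        base = ns * offset
        return [
            sig_hdr[base + i * width : base + (i + 1) * width].decode("ascii", "replace").strip()
            for i in range(ns)
        ]

    labels = fields(0, 16)
    try:
        pmin = [float(v) for v in fields(16 + 80 + 8, 8)]
        pmax = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dmin = [int(v) for v in fields(16 + 80 + 8 + 16, 8)]
        dmax = [int(v) for v in fields(16 + 80 + 8 + 24, 8)]
        spr = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]
    except ValueError as exc:
        raise CorruptEDFError(f"unparseable EDF signal header: {exc}") from exc

    if isinstance(channel, str):
        try:
            idx = labels.index(channel.strip())
        except ValueError:
            raise ChannelNotFoundError(
                f"channel {channel!r} not in {labels!r}"
            ) from None
    else:
        idx = int(channel)
        if not 0 <= idx < ns:
            raise ChannelNotFoundError(f"channel index {idx} out of range (n={ns})")

    record_len = sum(spr)
    data = np.frombuffer(raw[256 + ns * 256 :], dtype="<i2")
    if data.size < head["n_records"] * record_len:
        raise CorruptEDFError("EDF data section shorter than the header promises")
    data = data[: head["n_records"] * record_len].reshape(head["n_records"], record_len)
    start = sum(spr[:idx])
    digital = data[:, start : start + spr[idx]].reshape(-1).astype(float)
    if dmax[idx] == dmin[idx]:
        raise CorruptEDFError("degenerate digital range in EDF signal header")
    scale = (pmax[idx] - pmin[idx]) / (dmax[idx] - dmin[idx])
    samples = (digital - dmin[idx]) * scale + pmin[idx]
    fs = spr[idx] / head["duration"]
    return ECGRecord(samples=samples, fs=fs, channel_label=labels[idx])


_HEADER_UNITS = {
    "sample": "samples",
    "samples": "samples",
    "sample_index": "samples",
    "time": "seconds",
    "time_s": "seconds",
    "seconds": "seconds",
    "s": "seconds",
    "ms": "ms",
    "time_ms": "ms",
    "milliseconds": "ms",
}


def _read_first_column(path: str | Path) -> tuple[list[str], list[int]]:
    """First whitespace/comma/tab-separated token of each non-blank line."""
    tokens, rows = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            token = line.replace(",", " ").replace("\t", " ").split()[0]
            tokens.append(token)
            rows.append(lineno)
    return tokens, rows


def read_beats(
    path: str | Path,
    fs: float | None = None,
    unit: str | None = None,
    source: str = "detected",
    label: str = "",
) -> BeatAnnotation:
    """Read a one-beat-per-row annotation file.

    Rows hold either sample indices (``unit="samples"``, requires ``fs``),
    seconds (default) or milliseconds.  A recognized single-word header
    (``sample``, ``time_s``, ``ms``, ...) declares the unit; an explicit
    ``unit`` argument overrides it.  There is no value-based autodetection:
    a silent misparse is worse than a required flag.

    Duplicate rows are collapsed with a warning; remaining non-monotonic
    times raise :class:`~cardioqc.types.DataError`.
    """
    tokens, rows = _read_first_column(path)
    if tokens:
        try:
            float(tokens[0])
        except ValueError:
            header_unit = _HEADER_UNITS.get(tokens[0].lower())
            if header_unit is None:
                raise DataError(
                    f"{path}: unrecognized header {tokens[0]!r} "
                    f"(expected one of {sorted(set(_HEADER_UNITS))})"
                )
            if unit is None:
                unit = header_unit
            tokens, rows = tokens[1:], rows[1:]
    if unit is None:
        unit = "seconds"
    if unit not in ("samples", "seconds", "ms"):
        raise ValueError(f"unit must be 'samples', 'seconds' or 'ms', got {unit!r}")
    if unit == "samples" and fs is None:
        raise ValueError("unit='samples' requires the sampling frequency fs")

    values = np.empty(len(tokens))
    for k, (token, row) in enumerate(zip(tokens, rows)):
        try:
            values[k] = float(token)
        except ValueError:
            raise DataError(f"{path}: row {row}: non-numeric beat value {token!r}") from None
    if unit == "samples":
        times = values / fs
    elif unit == "ms":
        times = values / 1000.0
    else:
        times = values

    if times.size:
        keep = np.concatenate(([True], np.diff(times) != 0))
        if not keep.all():
            warnings.warn(
                f"{path}: collapsed {int((~keep).sum())} duplicate beat rows", stacklevel=2
            )
            times = times[keep]
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise DataError(f"{path}: beat times are not strictly increasing")
    return BeatAnnotation(times=times, source=source, label=label)


def write_beats(beats: BeatAnnotation, path: str | Path) -> None:
    """Write beat times as one-column CSV in seconds with a ``time_s`` header."""
    pd.DataFrame({"time_s": beats.times}).to_csv(path, index=False)


def read_rr(path: str | Path) -> RRSequence:
    """Read a one-interval-per-row RR file (milliseconds).

    Polar HRM-style exports are tolerated: when a ``[HRData]`` section marker
    is present only the rows after it are parsed, and other bracketed
    sections are ignored.  A single leading text header (e.g. ``rr_ms``) is
    also accepted.  An empty file yields an empty sequence.
    """
    with open(path) as fh:
        lines = [(lineno, line.strip()) for lineno, line in enumerate(fh, start=1)]
    lines = [(n, l) for n, l in lines if l]

    markers = [k for k, (_, l) in enumerate(lines) if l.lower() == "[hrdata]"]
    if markers:
        lines = lines[markers[-1] + 1 :]
    lines = [(n, l) for n, l in lines if not l.startswith("[")]

    if lines:
        first_token = lines[0][1].replace(",", " ").split()[0]
        try:
            float(first_token)
        except ValueError:
            lines = lines[1:]  # single text header tolerated

    intervals = np.empty(len(lines))
    for k, (lineno, line) in enumerate(lines):
        token = line.replace(",", " ").replace("\t", " ").split()[0]
        try:
            value = float(token)
        except ValueError:
            raise DataError(f"{path}: row {lineno}: non-numeric RR interval {token!r}") from None
        if not np.isfinite(value) or value <= 0:
            raise DataError(f"{path}: row {lineno}: non-positive RR interval {value}")
        intervals[k] = value
    return RRSequence(intervals=intervals)


def write_rr(rr: RRSequence, path: str | Path) -> None:
    """Write RR intervals as one-column CSV in milliseconds."""
    pd.DataFrame({"rr_ms": rr.intervals}).to_csv(path, index=False)


def read_phases(path: str | Path) -> PhaseSegmentation:
    """Read a phase table with columns ``label, start, end`` (seconds)."""
    df = pd.read_csv(path)
    expected = {"label", "start", "end"}
    if not expected.issubset(df.columns):
        raise DataError(f"{path}: phase file needs columns {sorted(expected)}")
    phases = tuple(
        Phase(label=str(r.label), start=float(r.start), end=float(r.end))
        for r in df.itertuples()
    )
    return PhaseSegmentation(phases=phases)


def rr_from_beats(beats: BeatAnnotation) -> RRSequence:
    """Differences of consecutive beat times, in milliseconds."""
    if len(beats) < 2:
        raise DataError("need at least 2 beats to form RR intervals")
    return RRSequence(intervals=np.diff(beats.times) * 1000.0)


def beats_from_rr(
    rr: RRSequence, start: float = 0.0, source: str = "detected", label: str = ""
) -> BeatAnnotation:
    """Cumulative-sum inverse of :func:`rr_from_beats` (n intervals → n+1 beats)."""
    times = start + np.concatenate(([0.0], np.cumsum(rr.intervals) / 1000.0))
    return BeatAnnotation(times=times, source=source, label=label)
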