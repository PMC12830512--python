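"""Acquisition-record CSV format with SHA-256 integrity footprint.

Canonical byte layout (UTF-8, LF newlines)::

    # batch_number=<text>
    # operator=<text>
    # scan_range_mm=<number>
    # acquisition_time_s=<number>
    # origin_mm=<number>
    # front_mm=<number>
    # timestamp=<ISO-8601 text>
    position_mm,counts
    <position>,<integer count>
    ...
    # sha256=<hex digest of every byte above>

Optional provenance keys (sorted) may follow ``timestamp``; they are part
of the hashed span.  The footprint line covers metadata AND data so that
any alteration of origin/front values (which determine Rf) is detected.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ParseError
from .simulate import AcquisitionMetadata, Chromatogram

__all__ = [
    "AcquisitionRecord",
    "serialize_record",
    "parse_record",
    "write_record",
    "read_record",
]

_META_KEYS = (
    "batch_number",
    "operator",
    "scan_range_mm",
    "acquisition_time_s",
    "origin_mm",
    "front_mm",
    "timestamp",
)
_HEADER = "position_mm,counts"
_FOOTPRINT_PREFIX = "# sha256="


@dataclass
class AcquisitionRecord:
    """A parsed or freshly serialized acquisition file."""

    chromatogram: Chromatogram
    footprint_hex: str | None = None

    @property
    def integrity(self) -> str:
        return self.chromatogram.integrity


def _fmt_num(x: float) -> str:
    """Shortest decimal text that round-trips the value through float()."""
    f = float(x)
    if f.is_integer():
        return str(int(f))
    return repr(f)


def _body_bytes(chromatogram: Chromatogram) -> bytes:
    meta = chromatogram.metadata
    lines = [
        f"# batch_number={meta.batch_number}",
        f"# operator={meta.operator}",
        f"# scan_range_mm={_fmt_num(meta.scan_range_mm)}",
        f"# acquisition_time_s={_fmt_num(meta.acquisition_time_s)}",
        f"# origin_mm={_fmt_num(meta.origin_mm)}",
        f"# front_mm={_fmt_num(meta.front_mm)}",
        f"# timestamp={meta.timestamp}",
    ]
    for key, value in sorted(meta.extra):
        lines.append(f"# {key}={value}")
    lines.append(_HEADER)
    for pos, count in zip(chromatogram.positions_mm, chromatogram.counts):
        lines.append(f"{_fmt_num(pos)},{int(count)}")
    return ("\n".join(lines) + "\n").encode("utf-8")


def serialize_record(chromatogram: Chromatogram) -> bytes:
    """Canonical bytes of the record, footprint line included."""
    body = _body_bytes(chromatogram)
    digest = hashlib.sha256(body).hexdigest()
    return body + f"{_FOOTPRINT_PREFIX}{digest}\n".encode("utf-8")


def _parse_number(text: str, line_no: int, what: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"non-numeric {what}: {text!r}", line_no) from None


def parse_record(data: bytes) -> AcquisitionRecord:
    """Parse record bytes; integrity is verified/failed/unhashed.

    Raises :class:`ParseError` (naming the offending line) on structural
    problems: missing header, non-numeric fields, non-monotone positions.
    """
    try:
        text = data.decode("utf-8")
    except UnicodeDecodeError as exc:
        raise ParseError(f"not valid UTF-8: {exc}") from None

    lines = text.split("\n")
    if lines and lines[-1] == "":
        lines.pop()

    footprint_hex: str | None = None
    if lines and lines[-1].startswith(_FOOTPRINT_PREFIX):
        footprint_line = lines.pop()
        footprint_hex = footprint_line[len(_FOOTPRINT_PREFIX):].strip().lower()
        hashed_span = data[: data.rfind(footprint_line.encode("utf-8"))]
        integrity = (
            "verified"
            if hashlib.sha256(hashed_span).hexdigest() == footprint_hex
            else "failed"
        )
    else:
        integrity = "unhashed"

    meta: dict[str, str] = {}
    extra: list[tuple[str, str]] = []
    row_positions: list[float] = []
    row_counts: list[int] = []
    header_seen = False
    for i, line in enumerate(lines, start=1):
        if not header_seen:
            if line.startswith("# "):
                key, sep, value = line[2:].partition("=")
                if not sep:
                    raise ParseError(f"malformed metadata line: {line!r}", i)
                if key in _META_KEYS:
                    meta[key] = value
                else:
                    extra.append((key, value))
                continue
            if line != _HEADER:
                raise ParseError(
                    f"expected header {_HEADER!r}, got {line!r}", i
                )
            header_seen = True
            continue
        if line == "":
            continue
        pos_text, sep, count_text = line.partition(",")
        if not sep:
            raise ParseError(f"malformed data row: {line!r}", i)
        pos = _parse_number(pos_text, i, "position")
        try:
            count = int(count_text)
        except ValueError:
            raise ParseError(f"non-integer counts: {count_text!r}", i) from None
        if count < 0:
            raise ParseError(f"negative counts: {count}", i)
        if row_positions and pos <= row_positions[-1]:
            raise ParseError(
                f"non-monotone position {pos} after {row_positions[-1]}", i
            )
        row_positions.append(pos)
        row_counts.append(count)

    if not header_seen:
        raise ParseError(f"missing header line {_HEADER!r}")
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise ParseError("missing metadata keys: " + ", ".join(missing))
    if not row_positions:
        raise ParseError("record contains no data rows")

    n_header_lines = 7 + len(extra) + 1
    try:
        metadata = AcquisitionMetadata(
            batch_number=meta["batch_number"],
            operator=meta["operator"],
            scan_range_mm=_parse_number(meta["scan_range_mm"], 3, "scan_range_mm"),
            acquisition_time_s=_parse_number(
                meta["acquisition_time_s"], 4, "acquisition_time_s"
            ),
            origin_mm=_parse_number(meta["origin_mm"], 5, "origin_mm"),
            front_mm=_parse_number(meta["front_mm"], 6, "front_mm"),
            timestamp=meta["timestamp"],
            extra=tuple(extra),
        )
        chromatogram = Chromatogram(
            positions_mm=np.array(row_positions),
            counts=np.array(row_counts, dtype=np.int64),
            dwell_s=metadata.acquisition_time_s / len(row_counts),
            metadata=metadata,
            integrity=integrity,
        )
    except ValueError as exc:
        raise ParseError(str(exc), n_header_lines) from None
    return AcquisitionRecord(chromatogram=chromatogram, footprint_hex=footprint_hex)


def write_record(chromatogram: Chromatogram, path: str | Path) -> str:
    """Serialize to ``path``; returns the footprint hex digest."""
    data = serialize_record(chromatogram)
    Path(path).write_bytes(data)
    return data.decode("utf-8").rsplit(_FOOTPRINT_PREFIX, 1)[1].strip()


def read_record(path: str | Path) -> AcquisitionRecord:
    return parse_record(Path(path).read_bytes())
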