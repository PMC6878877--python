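"""Single-pass CrystFEL stream scanner with byte-span indexing.

A CrystFEL stream file is a text log of serial-crystallography indexing:
a header (command line, geometry file, target cell), followed by one
"chunk" per detector frame.  Each chunk names the image file/event, lists
the peaks found by the peak search and contains zero or more "crystal"
blocks — one per indexing solution — with the refined unit cell, lattice
centering, predicted detector shift, diffraction resolution limit and the
integrated reflection list.

This module scans a stream once, parsing the scalar fields of every chunk
and crystal while recording the *byte* span of each block, so that any
subset of the stream can later be re-extracted verbatim (bit-exact) without
reformatting.  Byte offsets, not character offsets, define spans; streams
are treated as ASCII/UTF-8.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

__all__ = [
    "ByteSpan",
    "ChunkRecord",
    "CrystalRecord",
    "StreamFormatError",
    "StreamTruncationError",
    "scan_stream",
    "parse_event_suffix",
    "read_span",
]

#: Accepted magic first lines (CrystFEL 0.7.0 writes format 2.3).
MAGIC_PREFIXES = ("CrystFEL stream format 2.2", "CrystFEL stream format 2.3")

CHUNK_BEGIN = "----- Begin chunk -----"
CHUNK_END = "----- End chunk -----"
CRYSTAL_BEGIN = "--- Begin crystal"
CRYSTAL_END = "--- End crystal"
PEAKS_BEGIN = "Peaks from peak search"
PEAKS_END = "End of peak list"
REFL_BEGIN = "Reflections measured after indexing"
REFL_END = "End of reflections"

#: ``predict_refine/det_shift x = -0.30 y = 0.40 mm``
_DET_SHIFT_RE = re.compile(
    r"predict_refine/det_shift\s+x\s*=\s*(\S+)\s+y\s*=\s*(\S+)\s+mm"
)
#: ``... = 2.50 nm^-1 or 4.00 A`` — the Angstrom figure is the one kept.
_RES_A_RE = re.compile(r"nm\^-1\s+or\s+(\S+)\s+A\b")


class StreamFormatError(ValueError):
    """The file is not a recognizable CrystFEL stream."""


class StreamTruncationError(StreamFormatError):
    """A block was opened but never closed; ``offset`` is where it began."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (block begins at byte offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class ByteSpan:
    """Half-open byte range [start, end) into a file."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CrystalRecord:
    """One indexing solution inside a chunk.

    Cell axes are stored in Angstrom (the stream prints nm), angles in
    degrees, detector shifts in mm, resolution limit in Angstrom.
    """

    a: Optional[float] = None
    b: Optional[float] = None
    c: Optional[float] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    gamma: Optional[float] = None
    lattice_type: Optional[str] = None
    centering: Optional[str] = None
    unique_axis: Optional[str] = None
    det_shift_x: Optional[float] = None
    det_shift_y: Optional[float] = None
    resolution_limit_A: Optional[float] = None
    num_reflections: Optional[int] = None
    num_saturated_reflections: Optional[int] = None
    num_implausible_reflections: Optional[int] = None
    crystal_span: ByteSpan = ByteSpan(0, 0)
    reflections_span: Optional[ByteSpan] = None


@dataclass
class ChunkRecord:
    """One diffraction frame parsed from a stream."""

    source_path: str
    filename: Optional[str] = None
    event: Optional[int] = None
    serial: Optional[int] = None
    indexed_by: Optional[str] = None
    photon_energy_eV: Optional[float] = None
    num_peaks: Optional[int] = None
    peak_resolution_A: Optional[float] = None
    chunk_span: ByteSpan = ByteSpan(0, 0)
    peaks_span: Optional[ByteSpan] = None
    crystals: list[CrystalRecord] = field(default_factory=list)


def _iter_lines(data: bytes) -> Iterator[tuple[int, int, str]]:
    """Yield (start_offset, end_offset, decoded_text) per line.

    ``end_offset`` includes the terminating newline, so concatenating all
    [start, end) spans reproduces the file byte-for-byte.
    """
    pos = 0
    n = len(data)
    while pos < n:
        nl = data.find(b"\n", pos)
        end = n if nl == -1 else nl + 1
        yield pos, end, data[pos:end].decode("utf-8", errors="replace").rstrip("\r\n")
        pos = end


def _try_float(text: str) -> Optional[float]:
    try:
        v = float(text)
    except ValueError:
        return None
    return v

def _try_int(text: str) -> Optional[int]:
    try:
        return int(text)
    except ValueError:
        return None


def parse_event_suffix(line: str) -> tuple[str, Optional[int]]:
    """Split an image reference into (filename, event index).

    Multi-event HDF5/CXI files are referenced as ``name.cxi //<event>``;
    a line without the ``//`` delimiter is a single-frame file and the
    event is absent (None).
    """
    if not line.strip():
        raise ValueError("empty file-list line")
    if "//" not in line:
        return line.strip(), None
    name, _, ev_text = line.partition("//")
    ev_text = ev_text.strip()
    ev = _try_int(ev_text)
    if ev is None or ev < 0:
        raise ValueError(f"invalid event number {ev_text!r} in line {line!r}")
    return name.strip(), ev


def read_span(path: str | Path, span: ByteSpan) -> str:
    """Return exactly the bytes [span.start, span.end) of *path* as text."""
    p = Path(path)
    size = p.stat().st_size
    if span.end > size:
        raise ValueError(f"span [{span.start}, {span.end}) exceeds file size {size}")
    with open(p, "rb") as fh:
        fh.seek(span.start)
        return fh.read(len(span)).decode("utf-8")


def scan_stream(path: str | Path) -> tuple[list[ChunkRecord], ByteSpan]:
    """Scan a stream file, returning its chunks and the header byte span.

    The header span covers everything before the first chunk (including
    the embedded geometry file, which is captured but not parsed).  Every
    chunk between begin/end markers is returned in file order.  Optional
    fields that are missing or unparseable are left absent (None); only a
    structural defect (missing magic line, unterminated block) raises.
    """
    path = str(path)
    data = Path(path).read_bytes()

    first_nl = data.find(b"\n")
    first_line = (data if first_nl == -1 else data[:first_nl]).decode(
        "utf-8", errors="replace"
    )
    if not first_line.startswith(MAGIC_PREFIXES):
        raise StreamFormatError(
            f"{path}: not a CrystFEL stream (first line {first_line!r})"
        )

    chunks: list[ChunkRecord] = []
    header_end: Optional[int] = None

    chunk: Optional[ChunkRecord] = None
    chunk_start = 0
    crystal: Optional[CrystalRecord] = None
    crystal_start = 0
    peaks_start: Optional[int] = None
    refl_start: Optional[int] = None
    in_peaks = False
    in_refl = False

    for start, end, text in _iter_lines(data):
        line = text.strip()

        if chunk is None:
            if line == CHUNK_BEGIN:
                if header_end is None:
                    header_end = start
                chunk = ChunkRecord(source_path=path)
                chunk_start = start
            continue

        # --- inside a chunk ---
        if in_peaks:
            if line == PEAKS_END:
                chunk.peaks_span = ByteSpan(peaks_start, end)
                in_peaks = False
            continue
        if in_refl:
            if line == REFL_END:
                assert crystal is not None
                crystal.reflections_span = ByteSpan(refl_start, end)
                in_refl = False
            continue

        if crystal is not None:
            if line.startswith(CRYSTAL_END):
                crystal.crystal_span = ByteSpan(crystal_start, end)
                chunk.crystals.append(crystal)
                crystal = None
            elif line == REFL_BEGIN:
                in_refl = True
                refl_start = start
            elif line.startswith("Cell parameters"):
                # "Cell parameters 6.15 12.24 16.05 nm, 90.0 90.0 90.0 deg"
                toks = line.split()
                if len(toks) >= 9:
                    axes = [_try_float(t) for t in toks[2:5]]
                    angles = [_try_float(t.rstrip(",")) for t in toks[6:9]]
                    if None not in axes:
                        crystal.a, crystal.b, crystal.c = (10.0 * v for v in axes)
                    if None not in angles:
                        crystal.alpha, crystal.beta, crystal.gamma = angles
            elif line.startswith("lattice_type ="):
                crystal.lattice_type = line.split("=", 1)[1].strip() or None
            elif line.startswith("centering ="):
                crystal.centering = line.split("=", 1)[1].strip() or None
            elif line.startswith("unique_axis ="):
                crystal.unique_axis = line.split("=", 1)[1].strip() or None
            elif line.startswith("predict_refine/det_shift"):
                m = _DET_SHIFT_RE.search(line)
                if m:
                    crystal.det_shift_x = _try_float(m.group(1))
                    crystal.det_shift_y = _try_float(m.group(2))
            elif line.startswith("diffraction_resolution_limit ="):
                m = _RES_A_RE.search(line)
                if m:
                    crystal.resolution_limit_A = _try_float(m.group(1))
            elif line.startswith("num_reflections ="):
                crystal.num_reflections = _try_int(line.split("=", 1)[1].strip())
            elif line.startswith("num_saturated_reflections ="):
                crystal.num_saturated_reflections = _try_int(
                    line.split("=", 1)[1].strip()
                )
            elif line.startswith("num_implausible_reflections ="):
                crystal.num_implausible_reflections = _try_int(
                    line.split("=", 1)[1].strip()
                )
            continue

        # --- chunk level, outside any sub-block ---
        if line == CHUNK_END:
            chunk.chunk_span = ByteSpan(chunk_start, end)
            chunks.append(chunk)
            chunk = None
        elif line.startswith(CRYSTAL_BEGIN):
            crystal = CrystalRecord()
            crystal_start = start
        elif line == PEAKS_BEGIN:
            in_peaks = True
            peaks_start = start
        elif line.startswith("Image filename:"):
            chunk.filename = line.split(":", 1)[1].strip() or None
        elif line.startswith("Event:"):
            ev = line.split(":", 1)[1].strip()
            chunk.event = _try_int(ev.lstrip("/").strip())
        elif line.startswith("Image serial number:"):
            chunk.serial = _try_int(line.split(":", 1)[1].strip())
        elif line.startswith("indexed_by ="):
            chunk.indexed_by = line.split("=", 1)[1].strip() or None
        elif line.startswith("photon_energy_eV ="):
            chunk.photon_energy_eV = _try_float(line.split("=", 1)[1].strip())
        elif line.startswith("num_peaks ="):
            chunk.num_peaks = _try_int(line.split("=", 1)[1].strip())
        elif line.startswith("peak_resolution ="):
            m = _RES_A_RE.search(line)
            if m:
                chunk.peak_resolution_A = _try_float(m.group(1))
        # unknown lines are preserved in the spans but ignored here

    if crystal is not None:
        raise StreamTruncationError(f"{path}: unterminated crystal block", crystal_start)
    if chunk is not None:
        raise StreamTruncationError(f"{path}: unterminated chunk", chunk_start)

    header_span = ByteSpan(0, len(data) if header_end is None else header_end)
    return chunks, header_span
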