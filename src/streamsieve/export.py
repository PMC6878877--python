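"""Export the current selection: sorted, limited, partitioned; as a
``.dat`` table, a ``.lst`` file list, or an extracted stream subset.

The stream subset writer is the reason the parameter table records byte
spans: each selected crystal's chunk is copied verbatim from its source
stream, with every *other* crystal block of that chunk removed, so a
multi-crystal frame exports as one chunk per selected crystal, each
repeating the full frame text.  No bytes are reformatted, so re-scanning
the subset reproduces the selected rows' parameter values exactly.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .dat_table import ParameterTable
from .stream_io import (
    CHUNK_BEGIN,
    CRYSTAL_BEGIN,
    CRYSTAL_END,
    ByteSpan,
    read_span,
)

__all__ = [
    "SortSpec",
    "PartitionSpec",
    "StreamIntegrityError",
    "sort_order",
    "apply_limit",
    "partition_rows",
    "write_lst",
    "write_stream_subset",
    "partition_filename",
]

logger = logging.getLogger(__name__)


class StreamIntegrityError(RuntimeError):
    """Recorded byte spans no longer match the stream file on disk."""


@dataclass(frozen=True)
class SortSpec:
    """Ordered sort keys; empty = intrinsic file order."""

    keys: tuple[tuple[str, bool], ...] = ()  # (field, ascending)

    @classmethod
    def parse(cls, text: str) -> "SortSpec":
        """Parse ``field:asc,other:desc`` command-line syntax."""
        keys = []
        for part in text.split(","):
            if not part:
                continue
            name, _, direction = part.partition(":")
            if direction not in ("", "asc", "desc"):
                raise ValueError(f"bad sort direction {direction!r}")
            keys.append((name, direction != "desc"))
        return cls(tuple(keys))


@dataclass
class PartitionSpec:
    """Bin the selection by one field, one output per bin.

    Categorical fields get one bin per category.  Numeric fields use
    explicit ``edges`` or ``nbins`` equal-width bins over the selection's
    finite range; numeric bins are half-open with the last bin closed.
    Rows missing the field go to a "none" bin.
    """

    field: str
    edges: Optional[Sequence[float]] = None
    nbins: Optional[int] = None

    def __post_init__(self) -> None:
        if self.edges is not None:
            e = np.asarray(self.edges, dtype=float)
            if len(e) < 2 or not np.all(np.diff(e) > 0):
                raise ValueError("partition edges must be strictly increasing")
        if self.nbins is not None and self.nbins < 1:
            raise ValueError("nbins must be >= 1")


def _sort_key(table: ParameterTable, name: str) -> tuple[np.ndarray, np.ndarray]:
    """(comparable key array, missing mask) for one sort field."""
    dtype = table.dtype_of(name)
    missing = table.missing_mask(name)
    col = table.column(name)
    if dtype in ("real", "integer"):
        key = col.astype(float)
        key = np.where(missing, 0.0, key)  # placeholder; missing ranked separately
    elif dtype == "flag":
        key = col.astype(int).astype(float)
    else:
        # lexicographic order via codes
        uniq, codes = np.unique(np.asarray(col, dtype=str), return_inverse=True)
        key = codes.astype(float)
    return key, missing


def sort_order(table: ParameterTable, spec: SortSpec) -> np.ndarray:
    """Stable permutation of row indices realizing the sort spec.

    Missing sentinels sort last regardless of direction; equal keys keep
    intrinsic (file) order.
    """
    order = np.arange(len(table))
    for name, ascending in reversed(spec.keys):
        key, missing = _sort_key(table, name)
        if not ascending:
            key = -key
        # lexsort is stable; last key is primary: missing-last, then value
        order = order[np.lexsort((key[order], missing[order]))]
    return order


def apply_limit(
    order: Sequence[int],
    mask: np.ndarray,
    n: int,
    mode: str = "first",
    seed: Optional[int] = None,
) -> list[int]:
    """Limit the sorted selection to *n* rows.

    ``first`` takes the first n rows in sort order; ``random`` draws a
    uniform sample without replacement (reproducible for a fixed seed)
    and returns it in sort order.
    """
    if n < 0:
        raise ValueError("limit must be >= 0")
    selected = [i for i in order if mask[i]]
    if n >= len(selected):
        return selected
    if mode == "first":
        return selected[:n]
    if mode == "random":
        rng = np.random.default_rng(seed)
        positions = rng.choice(len(selected), size=n, replace=False)
        chosen = sorted(int(p) for p in positions)
        logger.info("random limit: %d of %d rows, seed=%r", n, len(selected), seed)
        return [selected[p] for p in chosen]
    raise ValueError(f"unknown limit mode {mode!r}")


def partition_rows(
    table: ParameterTable, mask: np.ndarray, spec: PartitionSpec
) -> list[tuple[str, list[int]]]:
    """Split the selection into disjoint labelled bins by one field."""
    dtype = table.dtype_of(spec.field)
    rows = np.nonzero(np.asarray(mask, dtype=bool))[0]
    missing = table.missing_mask(spec.field)
    out: list[tuple[str, list[int]]] = []

    if dtype in ("categorical", "text", "flag"):
        col = table.column(spec.field)
        values = sorted({str(col[i]) for i in rows if not missing[i]})
        for v in values:
            out.append((v, [int(i) for i in rows if not missing[i] and str(col[i]) == v]))
    else:
        vals = table.column(spec.field).astype(float)
        finite_rows = [int(i) for i in rows if not missing[i]]
        if spec.edges is not None:
            edges = np.asarray(spec.edges, dtype=float)
        else:
            nbins = spec.nbins or 1
            if finite_rows:
                lo = min(vals[i] for i in finite_rows)
                hi = max(vals[i] for i in finite_rows)
            else:
                lo, hi = 0.0, 1.0
            if lo == hi:
                hi = lo + 1.0
            edges = np.linspace(lo, hi, nbins + 1)
        for b in range(len(edges) - 1):
            lo, hi = edges[b], edges[b + 1]
            last = b == len(edges) - 2
            members = [
                i
                for i in finite_rows
                if (lo <= vals[i] < hi) or (last and vals[i] == hi)
            ]
            out.append((f"{lo:g}-{hi:g}", members))

    none_rows = [int(i) for i in rows if missing[i]]
    if none_rows:
        out.append(("none", none_rows))
    return out


def partition_filename(stem: str, field: str, label: str, ext: str) -> str:
    """``<stem>_<field>_<label><ext>`` with the label made filesystem-safe."""
    safe = re.sub(r"[^A-Za-z0-9_.+-]", "_", label)
    return f"{stem}_{field}_{safe}{ext}"


def write_lst(table: ParameterTable, rows: Sequence[int], path: str | Path) -> None:
    """Write a frame list: one line per unique (filename, event).

    Multi-crystal frames are deduplicated (this is a frame list, meant as
    indexing input, not a crystal list); events use the ``name //event``
    convention.  Order follows first appearance among *rows*.
    """
    filenames = table.column("filename")
    events = (
        table.column("event").astype(np.int64)
        if "event" in table.field_names
        else np.full(len(table), -1, dtype=np.int64)
    )
    seen: set[tuple[str, int]] = set()
    with open(path, "w", encoding="utf-8") as fh:
        for i in rows:
            key = (str(filenames[i]), int(events[i]))
            if key in seen:
                continue
            seen.add(key)
            name, ev = key
            fh.write(f"{name} //{ev}\n" if ev >= 0 else f"{name}\n")


def _header_text(stream_path: str) -> str:
    data = Path(stream_path).read_bytes()
    marker = CHUNK_BEGIN.encode()
    pos = data.find(marker)
    end = len(data) if pos == -1 else data.rfind(b"\n", 0, pos) + 1
    return data[:end].decode("utf-8")


def _crystal_spans_in_chunk(chunk_text: str) -> list[tuple[int, int]]:
    """Character spans of crystal blocks within one chunk's text."""
    spans = []
    start = None
    pos = 0
    for line in chunk_text.splitlines(keepends=True):
        stripped = line.strip()
        if stripped.startswith(CRYSTAL_BEGIN) and start is None:
            start = pos
        pos += len(line)
        if stripped.startswith(CRYSTAL_END) and start is not None:
            spans.append((start, pos))
            start = None
    return spans


def write_stream_subset(
    table: ParameterTable, rows: Sequence[int], path: str | Path
) -> None:
    """Extract the selected crystals into a new, valid stream file.

    The output carries the header block of the first selected row's
    source stream, then one chunk per selected row: the original chunk
    text with every crystal block removed except the selected one
    (unindexed rows copy their chunk verbatim).  Rows from streams with
    differing headers trigger a warning; the first header is used.
    """
    rows = list(rows)
    for col in ("source", "chunk_start", "chunk_end", "crystal_start", "crystal_end"):
        if col not in table.field_names:
            raise KeyError(f"table lacks span column {col!r}; not generated from streams")
    sources = table.column("source")
    c_start = table.column("chunk_start").astype(np.int64)
    c_end = table.column("chunk_end").astype(np.int64)
    x_start = table.column("crystal_start").astype(np.int64)
    x_end = table.column("crystal_end").astype(np.int64)

    headers: dict[str, str] = {}
    first_header: Optional[str] = None
    with open(path, "w", encoding="utf-8") as fh:
        for i in rows:
            src = str(sources[i])
            if src not in headers:
                headers[src] = _header_text(src)
            if first_header is None:
                first_header = headers[src]
                fh.write(first_header)
            elif headers[src] != first_header:
                logger.warning(
                    "stream %s has a different header; using the first one", src
                )
            chunk_text = read_span(src, ByteSpan(int(c_start[i]), int(c_end[i])))
            if not chunk_text.lstrip().startswith(CHUNK_BEGIN):
                raise StreamIntegrityError(
                    f"{src}: recorded chunk span no longer starts a chunk"
                )
            if x_start[i] < 0:  # unindexed frame: chunk verbatim
                fh.write(chunk_text)
                continue
            rel = (int(x_start[i] - c_start[i]), int(x_end[i] - c_start[i]))
            spans = _crystal_spans_in_chunk(chunk_text)
            if rel not in spans:
                raise StreamIntegrityError(
                    f"{src}: recorded crystal span {rel} not found in chunk"
                )
            kept = []
            pos = 0
            for s, e in spans:
                kept.append(chunk_text[pos:s])
                if (s, e) == rel:
                    kept.append(chunk_text[s:e])
                pos = e
            kept.append(chunk_text[pos:])
            fh.write("".join(kept))
        if first_header is None:  # empty selection: still a valid stream
            fh.write("CrystFEL stream format 2.3\n")
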