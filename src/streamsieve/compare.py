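"""Comparison mode: the same frames processed several ways, side by side.

When a data set is re-indexed under different conditions (different
integration radii, geometry, indexing program...), each condition yields
its own parameter table over the same diffraction patterns.  Merging the
tables links equivalent frames through a *comparison ID* (one integer per
distinct pattern) and tags each row with a *comparison group* (which input
table it came from).  Six comparison filters then select rows by looking
at whole equivalence classes rather than single rows:

``min`` / ``max``
    keep, per pattern, exactly the one row whose parameter is extremal
    among its finite values (ties break to the lowest group, then lowest
    row index); patterns with no finite value select nothing.
``all_between`` / ``any_between``
    a pattern qualifies when every group / at least one row has the
    parameter in [lo, hi); *all rows* of qualifying patterns are selected,
    so with one row per group per pattern the selection size is exactly
    (number of groups) x (qualifying patterns).
``all_same`` / ``any_different``
    a pattern qualifies when all its rows carry an identical value
    (missing equals missing; reals optionally within an absolute
    tolerance) — ``any_different`` is the exact class-level complement.

The persistent merged format is an extended ``.dat`` with ``comp_id`` and
``comp_group`` columns plus ``#group <i> <name>`` header comment lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dat_table import (
    ConfigSpec,
    DatFormatError,
    FieldSpec,
    ParameterTable,
    read_dat,
    write_dat,
)

__all__ = [
    "COMPARISON_KINDS",
    "ComparisonLeaf",
    "ComparisonTable",
    "merge_tables",
    "evaluate_comparison_leaf",
    "pair_values",
    "write_merged",
    "read_merged",
]

COMPARISON_KINDS = ("min", "max", "all_between", "any_between", "all_same", "any_different")


@dataclass(frozen=True)
class ComparisonLeaf:
    """Filter-tree leaf evaluated per frame-equivalence class."""

    kind: str
    field: str
    min: Optional[float] = None
    max: Optional[float] = None
    tol: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in COMPARISON_KINDS:
            raise ValueError(f"unknown comparison filter {self.kind!r}")
        needs_bounds = self.kind in ("all_between", "any_between")
        if needs_bounds and (self.min is None or self.max is None):
            raise ValueError(f"{self.kind} requires min and max bounds")
        if not needs_bounds and (self.min is not None or self.max is not None):
            raise ValueError(f"{self.kind} takes no bounds")


class ComparisonTable(ParameterTable):
    """Merged ParameterTable carrying comp_id/comp_group and group names."""

    def __init__(self, table: ParameterTable, group_names: Sequence[str]):
        super().__init__(
            table.df, table.fields, provenance=table.provenance, comments=table.comments
        )
        for required in ("comp_id", "comp_group"):
            if required not in self._by_name:
                raise DatFormatError(f"merged table lacks {required!r} column")
        self.group_names = list(group_names)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)


def merge_tables(
    tables: Sequence[ParameterTable],
    group_names: Optional[Sequence[str]] = None,
    match_on: str = "full-path",
) -> ComparisonTable:
    """Concatenate tables of the same frames, assigning comparison IDs.

    Rows are appended in group order.  The equivalence key is
    (image filename, event); with ``match_on="basename"`` only the final
    path component of the filename is compared, so the same frames staged
    under different directories still match.  comp_id values are assigned
    by first appearance of the key, scanning the groups in order, and are
    therefore contiguous 0..F-1.
    """
    tables = list(tables)
    if len(tables) < 2:
        raise ValueError("comparison mode needs at least two input tables")
    if match_on not in ("full-path", "basename"):
        raise ValueError(f"unknown match_on {match_on!r}")
    if group_names is None:
        group_names = [f"g{i}" for i in range(len(tables))]
    if len(group_names) != len(tables):
        raise ValueError("one group name per table required")
    for t in tables:
        if "filename" not in t.field_names:
            raise DatFormatError("input table lacks a 'filename' column")

    ids: dict[tuple[str, int], int] = {}
    comp_id_parts: list[np.ndarray] = []
    comp_group_parts: list[np.ndarray] = []
    for g, t in enumerate(tables):
        names = t.column("filename")
        events = (
            t.column("event").astype(np.int64)
            if "event" in t.field_names
            else np.full(len(t), -1, dtype=np.int64)
        )
        cid = np.empty(len(t), dtype=np.int64)
        for i, (nm, ev) in enumerate(zip(names, events)):
            key_name = Path(str(nm)).name if match_on == "basename" else str(nm)
            key = (key_name, int(ev))
            cid[i] = ids.setdefault(key, len(ids))
        comp_id_parts.append(cid)
        comp_group_parts.append(np.full(len(t), g, dtype=np.int64))

    order = tables[0].field_names
    df = pd.concat([t.df[order] for t in tables], ignore_index=True)
    df["comp_id"] = np.concatenate(comp_id_parts)
    df["comp_group"] = np.concatenate(comp_group_parts)
    fields = list(tables[0].fields) + [
        FieldSpec("comp_id", "integer"),
        FieldSpec("comp_group", "integer"),
    ]
    merged = ParameterTable(
        df, fields, provenance=np.concatenate([t.provenance for t in tables])
    )
    return ComparisonTable(merged, group_names)


def _require_merged(table: ParameterTable) -> int:
    if "comp_id" not in table.field_names or "comp_group" not in table.field_names:
        raise DatFormatError("not a merged comparison table (no comp_id/comp_group)")
    if isinstance(table, ComparisonTable):
        return table.n_groups
    grp = table.column("comp_group")
    return int(grp.max()) + 1 if len(grp) else 0


def evaluate_comparison_leaf(
    table: ParameterTable,
    kind: str,
    field: str,
    lo: Optional[float] = None,
    hi: Optional[float] = None,
    tol: float = 0.0,
) -> np.ndarray:
    """Evaluate one comparison filter to a boolean row mask."""
    n_groups = _require_merged(table)
    if kind not in COMPARISON_KINDS:
        raise ValueError(f"unknown comparison filter {kind!r}")
    dtype = table.dtype_of(field)
    values = table.column(field)
    missing = table.missing_mask(field)
    cid = table.column("comp_id").astype(np.int64)
    grp = table.column("comp_group").astype(np.int64)
    n = len(table)
    mask = np.zeros(n, dtype=bool)
    if n == 0:
        return mask

    if kind in ("min", "max"):
        ok = ~missing
        sub = pd.DataFrame(
            {
                "cid": cid[ok],
                "val": values[ok].astype(float) if dtype in ("real", "integer") else values[ok],
                "grp": grp[ok],
                "idx": np.nonzero(ok)[0],
            }
        )
        ascending = [kind == "min", True, True]
        winners = (
            sub.sort_values(["val", "grp", "idx"], ascending=ascending, kind="stable")
            .drop_duplicates("cid")
        )
        mask[winners["idx"].to_numpy()] = True
        return mask

    if kind in ("all_between", "any_between"):
        if lo is None or hi is None:
            raise ValueError(f"{kind} requires bounds")
        num = values.astype(float)
        with np.errstate(invalid="ignore"):
            in_range = ~missing & (num >= lo) & (num < hi)
        if kind == "any_between":
            good = pd.Series(in_range).groupby(cid).any()
            qualifying = set(good.index[good])
        else:
            hits = pd.DataFrame({"cid": cid[in_range], "grp": grp[in_range]})
            per_class = hits.drop_duplicates().groupby("cid").size()
            qualifying = set(per_class.index[per_class == n_groups])
        mask[:] = np.isin(cid, list(qualifying))
        return mask

    # all_same / any_different
    same = np.zeros(n, dtype=bool)
    frame = pd.DataFrame({"cid": cid, "missing": missing, "i": np.arange(n)})
    for _, g in frame.groupby("cid"):
        idx = g["i"].to_numpy()
        miss = g["missing"].to_numpy()
        if miss.all():
            ok_same = True
        elif miss.any():
            ok_same = False
        else:
            vals = values[idx]
            if dtype == "real":
                v = vals.astype(float)
                ok_same = float(v.max() - v.min()) <= tol
            else:
                ok_same = len(set(map(str, vals))) == 1 if dtype in ("categorical", "text") else len(set(vals.tolist())) == 1
        same[idx] = ok_same
    return same if kind == "all_same" else ~same


def pair_values(
    table: ParameterTable,
    field: str,
    group_x: int,
    group_y: int,
    reduce: str = "first",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pattern (x, y) value pairs for two comparison groups.

    One pair per comparison ID with a non-missing value in both groups;
    multi-crystal classes contribute one row per group, chosen by *reduce*
    (``first`` = lowest row index, or ``min`` / ``max`` of the value).
    Pairs are returned ordered by comparison ID.  ``group_x == group_y``
    is allowed and yields the diagonal.
    """
    _require_merged(table)
    if reduce not in ("first", "min", "max"):
        raise ValueError(f"unknown reduce {reduce!r}")
    values = table.column(field).astype(float)
    missing = table.missing_mask(field)
    cid = table.column("comp_id").astype(np.int64)
    grp = table.column("comp_group").astype(np.int64)

    def side(g: int) -> dict[int, float]:
        ok = (grp == g) & ~missing
        sub = pd.DataFrame({"cid": cid[ok], "val": values[ok]})
        if reduce == "first":
            red = sub.groupby("cid", sort=True)["val"].first()
        elif reduce == "min":
            red = sub.groupby("cid", sort=True)["val"].min()
        else:
            red = sub.groupby("cid", sort=True)["val"].max()
        return dict(red.items())

    xs_map, ys_map = side(group_x), side(group_y)
    common = sorted(set(xs_map) & set(ys_map))
    xs = np.array([xs_map[c] for c in common], dtype=float)
    ys = np.array([ys_map[c] for c in common], dtype=float)
    return xs, ys


def write_merged(table: ComparisonTable, path: str | Path) -> None:
    """Persist a merged table as extended .dat with #group comments."""
    comments = [f"#group {i} {name}" for i, name in enumerate(table.group_names)]
    write_dat(table, path, comments=comments)


def read_merged(path: str | Path, config: Optional[ConfigSpec] = None) -> ComparisonTable:
    """Load a merged table written by :func:`write_merged`."""
    cfg = config or ConfigSpec()
    cfg.fields.setdefault("comp_id", FieldSpec("comp_id", "integer"))
    cfg.fields.setdefault("comp_group", FieldSpec("comp_group", "integer"))
    table = read_dat(path, cfg)
    names: dict[int, str] = {}
    for line in table.comments:
        parts = line.split(maxsplit=2)
        if len(parts) >= 3 and parts[0] == "#group":
            try:
                names[int(parts[1])] = parts[2]
            except ValueError:
                continue
    if names:
        group_names = [names.get(i, f"g{i}") for i in range(max(names) + 1)]
    else:
        grp = table.column("comp_group")
        group_names = [f"g{i}" for i in range(int(grp.max()) + 1 if len(grp) else 0)]
    return ComparisonTable(table, group_names)
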