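"""Independent brute-force oracles for the filter engines.

Everything here is deliberately written as naive per-row / per-class
Python recursion, sharing no code path with the vectorized library
implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np

from streamsieve.filter_engine import (
    Between,
    Flag,
    GreaterEqual,
    Group,
    InSet,
    LessThan,
)


def _cell(table, field, i):
    """(value, is_missing) for one cell, judged from the raw cell alone."""
    v = table.df[field].iloc[i]
    dtype = table.dtype_of(field)
    if dtype == "real":
        v = float(v)
        return v, math.isnan(v)
    if dtype == "integer":
        v = int(v)
        return v, v == -1
    if dtype == "categorical":
        return str(v), str(v) == "none"
    if dtype == "text":
        return str(v), str(v) == "-"
    return bool(v), False


def row_passes(node, table, i: int) -> bool:
    """Recursive single-row filter evaluation (no vectorization)."""
    if isinstance(node, Group):
        results = [row_passes(c, table, i) for c in node.children]
        if not results:
            return True
        return all(results) if node.op == "AND" else any(results)
    if isinstance(node, Between):
        v, miss = _cell(table, node.field, i)
        return (not miss) and node.min <= v < node.max
    if isinstance(node, LessThan):
        v, miss = _cell(table, node.field, i)
        return (not miss) and v < node.max
    if isinstance(node, GreaterEqual):
        v, miss = _cell(table, node.field, i)
        return (not miss) and v >= node.min
    if isinstance(node, InSet):
        v, _ = _cell(table, node.field, i)
        return str(v) in node.values
    if isinstance(node, Flag):
        flagged = bool(table.df["flag"].iloc[i])
        return flagged if node.mode == "only_flagged" else not flagged
    raise TypeError(f"oracle cannot evaluate {node!r}")


def brute_force_mask(node, table) -> np.ndarray:
    return np.array([row_passes(node, table, i) for i in range(len(table))])


# -- comparison filters -----------------------------------------------------

def _classes(table):
    """comp_id -> list of (row index, group, value, missing)."""
    out: dict[int, list] = {}
    for i in range(len(table)):
        cid = int(table.df["comp_id"].iloc[i])
        grp = int(table.df["comp_group"].iloc[i])
        out.setdefault(cid, []).append((i, grp))
    return out


def brute_force_comparison(table, kind, field, lo=None, hi=None, tol=0.0, n_groups=None):
    """Class-by-class re-derivation of the six comparison filters."""
    if n_groups is None:
        n_groups = table.n_groups
    mask = np.zeros(len(table), dtype=bool)
    for cid, members in _classes(table).items():
        cells = [(i, g, *_cell(table, field, i)) for i, g in members]
        finite = [(i, g, v) for i, g, v, miss in cells if not miss]
        if kind in ("min", "max"):
            if not finite:
                continue
            best = (min if kind == "min" else max)(
                finite, key=lambda t: (t[2], -1, -1)
            )[2]
            candidates = sorted(
                [(g, i) for i, g, v in finite if v == best]
            )
            mask[candidates[0][1]] = True
        elif kind == "any_between":
            if any(lo <= v < hi for _, _, v in finite):
                for i, _ in members:
                    mask[i] = True
        elif kind == "all_between":
            groups_hit = {g for _, g, v in finite if lo <= v < hi}
            if groups_hit == set(range(n_groups)):
                for i, _ in members:
                    mask[i] = True
        elif kind in ("all_same", "any_different"):
            missing_flags = [miss for _, _, _, miss in cells]
            if all(missing_flags):
                same = True
            elif any(missing_flags):
                same = False
            else:
                values = [v for _, _, v in finite]
                if isinstance(values[0], str):
                    same = len(set(values)) == 1
                else:
                    same = max(values) - min(values) <= tol
            if same == (kind == "all_same"):
                for i, _ in members:
                    mask[i] = True
        else:
            raise ValueError(kind)
    return mask


# -- random instance generators --------------------------------------------

def random_leaf(rng: np.random.Generator, numeric_fields, cat_fields, cat_values):
    kinds = ["between", "lessthan", "greaterequal", "inset", "flag"]
    kind = kinds[rng.integers(len(kinds))]
    if kind == "flag" or (kind == "inset" and not cat_fields):
        return Flag(["exclude_flagged", "only_flagged"][rng.integers(2)])
    if kind == "inset":
        f = cat_fields[rng.integers(len(cat_fields))]
        values = [v for v in cat_values[f] if rng.random() < 0.5]
        return InSet(f, frozenset(values))
    f = numeric_fields[rng.integers(len(numeric_fields))]
    lo, hi = sorted(rng.uniform(-2, 12, size=2))
    if kind == "between":
        return Between(f, float(lo), float(hi))
    if kind == "lessthan":
        return LessThan(f, float(hi))
    return GreaterEqual(f, float(lo))


def random_tree(rng, numeric_fields, cat_fields, cat_values, depth=3):
    if depth == 0 or rng.random() < 0.4:
        return random_leaf(rng, numeric_fields, cat_fields, cat_values)
    op = "AND" if rng.random() < 0.5 else "OR"
    n_children = int(rng.integers(0, 4))
    return Group(
        op,
        [
            random_tree(rng, numeric_fields, cat_fields, cat_values, depth - 1)
            for _ in range(n_children)
        ],
    )
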