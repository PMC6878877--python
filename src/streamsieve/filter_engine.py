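"""Boolean filter trees over parameter tables.

A selection is defined by a tree: inner nodes are AND/OR groups, leaves
are predicates on one column.  Evaluating the tree against a table yields
a boolean mask, one value per row — the "current selection" that every
plot and export operates on.

Semantics (chosen so plot-drawn ranges compose cleanly):

* ``Between(field, lo, hi)`` is half-open: lo <= value < hi.  Two
  adjacent drawn ranges therefore never double-count a row, and Between
  equals GreaterEqual AND LessThan.
* Missing numeric values (NaN for reals, -1 for integers) fail every
  range predicate — an unindexed frame is never "in range".  Missing
  categoricals are selectable only through the explicit "none" category
  of an InSet filter.
* An empty group is all-true (the neutral element), so a fresh session
  selects the whole data set.

Trees serialize to a small XML dialect; parse -> serialize is the
identity on trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Union

import numpy as np
from lxml import etree

from .compare import ComparisonLeaf, evaluate_comparison_leaf
from .dat_table import ParameterTable

__all__ = [
    "FilterNode",
    "Group",
    "Between",
    "LessThan",
    "GreaterEqual",
    "InSet",
    "Flag",
    "ComparisonLeaf",
    "FilterParseError",
    "evaluate",
    "parse_filter",
    "serialize_filter",
    "set_range_filter",
]


class FilterParseError(ValueError):
    """Malformed filter XML."""


@dataclass(frozen=True)
class Between:
    field: str
    min: float
    max: float


@dataclass(frozen=True)
class LessThan:
    field: str
    max: float


@dataclass(frozen=True)
class GreaterEqual:
    field: str
    min: float


@dataclass(frozen=True)
class InSet:
    field: str
    values: frozenset[str]


@dataclass(frozen=True)
class Flag:
    mode: str  # "exclude_flagged" | "only_flagged"

    def __post_init__(self) -> None:
        if self.mode not in ("exclude_flagged", "only_flagged"):
            raise ValueError(f"unknown flag mode {self.mode!r}")


@dataclass
class Group:
    op: str  # "AND" | "OR"
    children: list["FilterNode"] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.op not in ("AND", "OR"):
            raise ValueError(f"unknown group operator {self.op!r}")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Group)
            and self.op == other.op
            and self.children == other.children
        )


FilterNode = Union[Group, Between, LessThan, GreaterEqual, InSet, Flag, ComparisonLeaf]


def _numeric_values(table: ParameterTable, name: str) -> tuple[np.ndarray, np.ndarray]:
    """(float values, valid mask) for a numeric column; sentinels invalid."""
    dtype = table.dtype_of(name)
    if dtype not in ("real", "integer"):
        raise TypeError(f"field {name!r} is {dtype}, range filters need a numeric field")
    return table.column(name).astype(float), ~table.missing_mask(name)


def evaluate(node: FilterNode, table: ParameterTable) -> np.ndarray:
    """Evaluate a filter tree to a boolean mask over the table's rows."""
    n = len(table)
    if isinstance(node, Group):
        if not node.children:
            return np.ones(n, dtype=bool)
        masks = [evaluate(child, table) for child in node.children]
        combined = masks[0].copy()
        for m in masks[1:]:
            combined = combined & m if node.op == "AND" else combined | m
        return combined
    if isinstance(node, Between):
        v, ok = _numeric_values(table, node.field)
        with np.errstate(invalid="ignore"):
            return ok & (v >= node.min) & (v < node.max)
    if isinstance(node, LessThan):
        v, ok = _numeric_values(table, node.field)
        with np.errstate(invalid="ignore"):
            return ok & (v < node.max)
    if isinstance(node, GreaterEqual):
        v, ok = _numeric_values(table, node.field)
        with np.errstate(invalid="ignore"):
            return ok & (v >= node.min)
    if isinstance(node, InSet):
        col = table.column(node.field)
        return np.isin(np.asarray(col, dtype=object), list(node.values))
    if isinstance(node, Flag):
        flags = table.column("flag").astype(bool)
        return flags if node.mode == "only_flagged" else ~flags
    if isinstance(node, ComparisonLeaf):
        return evaluate_comparison_leaf(
            table, node.kind, node.field, node.min, node.max, node.tol
        )
    raise TypeError(f"not a filter node: {node!r}")


# -- XML (de)serialization --------------------------------------------------

_COMPARISON_TAGS = {
    "min": "min",
    "max": "max",
    "all_between": "allbetween",
    "any_between": "anybetween",
    "all_same": "allsame",
    "any_different": "anydifferent",
}
_TAG_TO_KIND = {tag: kind for kind, tag in _COMPARISON_TAGS.items()}


def _node_to_element(node: FilterNode) -> etree._Element:
    if isinstance(node, Group):
        el = etree.Element(node.op.lower())
        for child in node.children:
            el.append(_node_to_element(child))
        return el
    if isinstance(node, Between):
        return etree.Element(
            "between", field=node.field, min=repr(node.min), max=repr(node.max)
        )
    if isinstance(node, LessThan):
        return etree.Element("lessthan", field=node.field, max=repr(node.max))
    if isinstance(node, GreaterEqual):
        return etree.Element("greaterequal", field=node.field, min=repr(node.min))
    if isinstance(node, InSet):
        return etree.Element("in", field=node.field, values=",".join(sorted(node.values)))
    if isinstance(node, Flag):
        return etree.Element("flag", mode=node.mode)
    if isinstance(node, ComparisonLeaf):
        el = etree.Element(_COMPARISON_TAGS[node.kind], field=node.field)
        if node.min is not None:
            el.set("min", repr(node.min))
        if node.max is not None:
            el.set("max", repr(node.max))
        if node.tol:
            el.set("tol", repr(node.tol))
        return el
    raise TypeError(f"not a filter node: {node!r}")


def serialize_filter(node: FilterNode) -> str:
    """Serialize a tree to its XML document text."""
    return etree.tostring(
        _node_to_element(node), pretty_print=True, encoding="unicode"
    )


def _req(el: etree._Element, attr: str) -> str:
    value = el.get(attr)
    if value is None:
        raise FilterParseError(f"<{el.tag}> missing attribute {attr!r}")
    return value


def _element_to_node(el: etree._Element) -> FilterNode:
    tag = el.tag
    if tag in ("and", "or"):
        return Group(tag.upper(), [_element_to_node(c) for c in el])
    if tag == "between":
        return Between(_req(el, "field"), float(_req(el, "min")), float(_req(el, "max")))
    if tag == "lessthan":
        return LessThan(_req(el, "field"), float(_req(el, "max")))
    if tag == "greaterequal":
        return GreaterEqual(_req(el, "field"), float(_req(el, "min")))
    if tag == "in":
        values = [v for v in _req(el, "values").split(",") if v != ""]
        return InSet(_req(el, "field"), frozenset(values))
    if tag == "flag":
        return Flag(_req(el, "mode"))
    if tag in _TAG_TO_KIND:
        kind = _TAG_TO_KIND[tag]
        lo = el.get("min")
        hi = el.get("max")
        return ComparisonLeaf(
            kind,
            _req(el, "field"),
            min=float(lo) if lo is not None else None,
            max=float(hi) if hi is not None else None,
            tol=float(el.get("tol", "0")),
        )
    raise FilterParseError(f"unknown filter element <{tag}>")


def parse_filter(xml_text: str) -> FilterNode:
    """Parse the XML filter dialect into a tree."""
    try:
        root = etree.fromstring(xml_text.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        raise FilterParseError(f"malformed filter XML: {exc}") from None
    return _element_to_node(root)


def set_range_filter(root: FilterNode, field: str, lo: float, hi: float) -> Group:
    """Install/replace the managed Between filter for *field* under *root*.

    Mirrors drawing a range on a plot: if a Between leaf for the field
    already sits directly under the root group its bounds are replaced,
    otherwise a new leaf is appended.  Everything else is untouched.
    """
    if not isinstance(root, Group):
        raise TypeError("filter root must be a Group")
    for i, child in enumerate(root.children):
        if isinstance(child, Between) and child.field == field:
            root.children[i] = Between(field, lo, hi)
            return root
    root.children.append(Between(field, lo, hi))
    return root
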