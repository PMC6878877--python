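"""The ``.dat`` parameter-table model.

A ``.dat`` file is a plain text table — one header line of field names,
then one row per item (per crystal, or per unindexed frame).  Columns are
typed (integer, real, categorical, text, flag) either by an external XML
configuration or by inference (all-numeric columns become real, anything
else categorical).  Missing values use fixed sentinels so the table stays
a rectangular whitespace-separated file:

========== ==========
dtype      sentinel
========== ==========
real       ``nan``
integer    ``-1``
categorical ``none``
text       empty
flag       false (0)
========== ==========

The reader splits rows on any run of whitespace; the writer always emits
tabs.  Reading a written table is a fixed point: read -> write -> read
yields an equal table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "DTYPES",
    "FieldSpec",
    "ParameterTable",
    "ConfigSpec",
    "DatFormatError",
    "read_dat",
    "write_dat",
    "concat_tables",
    "load_config",
]

logger = logging.getLogger(__name__)

DTYPES = ("integer", "real", "categorical", "text", "flag")

#: Missing-value sentinel per dtype, as written to file.
SENTINEL_TOKEN = {
    "real": "nan",
    "integer": "-1",
    "categorical": "none",
    "text": "-",
    "flag": "0",
}

_PANDAS_DTYPE = {
    "integer": np.int64,
    "real": np.float64,
    "categorical": object,
    "text": object,
    "flag": bool,
}


class DatFormatError(ValueError):
    """Structural defect in a ``.dat`` file (ragged row, duplicate header...)."""


@dataclass(frozen=True)
class FieldSpec:
    name: str
    dtype: str
    display_name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        if self.dtype not in DTYPES:
            raise ValueError(f"unknown dtype {self.dtype!r} for field {self.name!r}")


@dataclass
class ConfigSpec:
    """External configuration: field typings, category colors, defaults."""

    fields: dict[str, FieldSpec] = field(default_factory=dict)
    colors: dict[tuple[str, str], str] = field(default_factory=dict)
    default_histograms: list[str] = field(default_factory=list)


class ParameterTable:
    """Typed columns x rows; one row per crystal or unindexed frame.

    Thin wrapper over a :class:`pandas.DataFrame` that carries the ordered
    :class:`FieldSpec` list, per-row provenance (the source file each row
    came from) and optional header comment lines.  A boolean ``flag``
    column always exists (default false) to support manual flagging
    workflows.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        fields: Sequence[FieldSpec],
        provenance: Optional[Sequence[str]] = None,
        comments: Optional[list[str]] = None,
    ):
        names = [f.name for f in fields]
        if len(set(names)) != len(names):
            raise DatFormatError("duplicate field names")
        if list(df.columns) != names:
            raise ValueError("DataFrame columns do not match field specs")
        self.fields = list(fields)
        self.df = df.reset_index(drop=True)
        if "flag" not in names:
            self.fields.append(FieldSpec("flag", "flag"))
            self.df = self.df.assign(flag=np.zeros(len(df), dtype=bool))
        if provenance is None:
            provenance = [""] * len(self.df)
        if len(provenance) != len(self.df):
            raise ValueError("provenance length mismatch")
        self.provenance = np.asarray(provenance, dtype=object)
        self.comments = list(comments or [])
        self._by_name = {f.name: f for f in self.fields}

    # -- basic introspection ------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]

    def spec(self, name: str) -> FieldSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"no such field: {name!r}") from None

    def dtype_of(self, name: str) -> str:
        return self.spec(name).dtype

    def column(self, name: str) -> np.ndarray:
        self.spec(name)
        return self.df[name].to_numpy()

    def missing_mask(self, name: str) -> np.ndarray:
        """True where the column holds its missing sentinel."""
        dtype = self.dtype_of(name)
        col = self.df[name].to_numpy()
        if dtype == "real":
            return np.isnan(col.astype(float))
        if dtype == "integer":
            return col == -1
        if dtype == "categorical":
            return col == "none"
        if dtype == "text":
            return col == SENTINEL_TOKEN["text"]
        return np.zeros(len(col), dtype=bool)

    def categories(self, name: str) -> list[str]:
        """Distinct values of a categorical column, sorted, 'none' last."""
        if self.dtype_of(name) != "categorical":
            raise ValueError(f"field {name!r} is not categorical")
        vals = sorted(set(map(str, self.column(name))))
        if "none" in vals:
            vals.remove("none")
            vals.append("none")
        return vals

    def equals(self, other: "ParameterTable") -> bool:
        if self.field_names != other.field_names:
            return False
        if [f.dtype for f in self.fields] != [f.dtype for f in other.fields]:
            return False
        if len(self) != len(other):
            return False
        for f in self.fields:
            a, b = self.column(f.name), other.column(f.name)
            if f.dtype == "real":
                a, b = a.astype(float), b.astype(float)
                if not np.array_equal(a, b, equal_nan=True):
                    return False
            elif not np.array_equal(a, b):
                return False
        return True

    def take(self, rows: Sequence[int]) -> "ParameterTable":
        rows = list(rows)
        return ParameterTable(
            self.df.iloc[rows].reset_index(drop=True),
            self.fields,
            provenance=self.provenance[rows],
            comments=self.comments,
        )


# -- parsing helpers --------------------------------------------------------

def _parse_column(tokens: list[str], dtype: str, name: str) -> np.ndarray:
    try:
        if dtype == "real":
            return np.array([float(t) for t in tokens], dtype=np.float64)
        if dtype == "integer":
            return np.array([int(float(t)) for t in tokens], dtype=np.int64)
        if dtype == "flag":
            return np.array(
                [t.lower() in ("1", "true", "yes") for t in tokens], dtype=bool
            )
    except ValueError as exc:
        raise DatFormatError(f"column {name!r}: {exc}") from None
    return np.array(tokens, dtype=object)


def _infer_dtype(tokens: Iterable[str]) -> str:
    for t in tokens:
        try:
            float(t)
        except ValueError:
            return "categorical"
    return "real"


def read_dat(path: str | Path, config: Optional[ConfigSpec] = None) -> ParameterTable:
    """Read a ``.dat`` table, typing columns per *config* or by inference.

    Leading ``#`` lines are kept as comments (used by merged comparison
    tables for their group-name records).  The column literally named
    ``flag`` is always typed as a flag.
    """
    path = Path(path)
    comments: list[str] = []
    header: Optional[list[str]] = None
    columns: list[list[str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if header is None and line.lstrip().startswith("#"):
                comments.append(line)
                continue
            tokens = line.split()
            if header is None:
                header = tokens
                if len(set(header)) != len(header):
                    raise DatFormatError(f"{path}: duplicate header name")
                columns = [[] for _ in header]
                continue
            if len(tokens) != len(header):
                raise DatFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(tokens)}"
                )
            for col, tok in zip(columns, tokens):
                col.append(tok)
    if header is None:
        raise DatFormatError(f"{path}: empty file, no header")

    fields: list[FieldSpec] = []
    data = {}
    for name, tokens in zip(header, columns):
        if config is not None and name in config.fields:
            fspec = config.fields[name]
        elif name == "flag":
            fspec = FieldSpec("flag", "flag")
        else:
            fspec = FieldSpec(name, _infer_dtype(tokens))
        fields.append(fspec)
        data[name] = _parse_column(tokens, fspec.dtype, name)
    n = len(columns[0]) if columns else 0
    df = pd.DataFrame(data, columns=header, index=range(n))
    return ParameterTable(df, fields, provenance=[str(path)] * n, comments=comments)


def _format_value(value, dtype: str) -> str:
    if dtype == "real":
        v = float(value)
        return "nan" if math.isnan(v) else repr(v)
    if dtype == "integer":
        return str(int(value))
    if dtype == "flag":
        return "1" if value else "0"
    text = str(value)
    return text if text else SENTINEL_TOKEN["text"]


def write_dat(
    table: ParameterTable,
    path: str | Path,
    rows: Optional[Sequence[int]] = None,
    comments: Optional[Sequence[str]] = None,
) -> None:
    """Write the table (or the given rows, in the given order) tab-separated.

    Missing sentinels are written literally, so a round trip preserves
    NaN / -1 / "none" exactly.
    """
    if not table.fields:
        raise DatFormatError("cannot write a table with no fields")
    if rows is None:
        rows = range(len(table))
    sub = table.df.iloc[list(rows)]
    dtypes = [f.dtype for f in table.fields]
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments if comments is not None else table.comments:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("\t".join(table.field_names) + "\n")
        for row in sub.itertuples(index=False):
            fh.write(
                "\t".join(_format_value(v, d) for v, d in zip(row, dtypes)) + "\n"
            )


def concat_tables(tables: Sequence[ParameterTable]) -> ParameterTable:
    """Append tables row-wise, aligning columns by name.

    Headers must share the same field *set*; order may differ (the first
    table's order wins).  Per-row provenance is preserved.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no tables to concatenate")
    first = tables[0]
    names = set(first.field_names)
    for i, t in enumerate(tables[1:], start=1):
        other = set(t.field_names)
        if other != names:
            missing = sorted(names - other)
            extra = sorted(other - names)
            raise DatFormatError(
                f"table {i} field mismatch: missing {missing}, unexpected {extra}"
            )
    order = first.field_names
    df = pd.concat([t.df[order] for t in tables], ignore_index=True)
    provenance = np.concatenate([t.provenance for t in tables])
    return ParameterTable(df, first.fields, provenance=provenance)


def load_config(path: str | Path) -> ConfigSpec:
    """Load the XML configuration (field typings, colors, default plots).

    Unknown elements are ignored with a logged warning, so configs written
    for richer front ends still load.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise DatFormatError(f"{path}: malformed XML: {exc}") from None
    spec = ConfigSpec()
    root = tree.getroot()
    for el in root.iter():
        if el is root or not isinstance(el.tag, str):
            continue
        if el.tag == "field":
            name = el.get("name")
            dtype = el.get("type", "real")
            if name is None:
                logger.warning("config %s: <field> without name ignored", path)
                continue
            spec.fields[name] = FieldSpec(
                name, dtype, display_name=el.get("display", ""), units=el.get("units", "")
            )
        elif el.tag == "color":
            f, v, rgb = el.get("field"), el.get("value"), el.get("rgb")
            if None in (f, v, rgb):
                logger.warning("config %s: incomplete <color> ignored", path)
                continue
            spec.colors[(f, v)] = rgb
        elif el.tag == "defaultHistograms":
            spec.default_histograms = (el.get("fields") or "").split()
        else:
            logger.warning("config %s: unknown element <%s> ignored", path, el.tag)
    return spec
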