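"""Headless computation of the five diagnostic plot types.

Every operation here returns plain arrays — the data behind a plot — and
never touches a rendering backend, so the whole analysis path is testable
without a display.  Each plot type supports the overlay semantics of an
interactive session: the *full set* is drawn semi-transparent, the
*current selection* opaque, so both populations are computed over shared
bin edges (derived from the full set's finite range, never the
selection's, so overlays always align).

Display modes: ``overlay`` (both populations), ``selection_only``,
``full_only``.  Optional matplotlib rendering to static image files is
provided separately by the ``render_*`` helpers; rendering never alters
the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import numpy as np

from .compare import pair_values
from .dat_table import ConfigSpec, ParameterTable

__all__ = [
    "DISPLAY_MODES",
    "HistData",
    "Hist2DData",
    "AggData",
    "histogram_data",
    "hist2d_data",
    "scatter_data",
    "pixel_data",
    "aggregate_data",
    "comparison_hist2d_data",
    "render_histogram",
    "render_hist2d",
    "render_scatter",
]

DISPLAY_MODES = ("overlay", "selection_only", "full_only")

Bins = Union[int, Sequence[float]]


def _check_mode(mode: str) -> None:
    if mode not in DISPLAY_MODES:
        raise ValueError(f"unknown display mode {mode!r}")


def _finite_column(table: ParameterTable, name: str) -> tuple[np.ndarray, np.ndarray]:
    """(float values, finite mask) — sentinel-aware."""
    values = table.column(name).astype(float)
    return values, ~table.missing_mask(name) & np.isfinite(values)


def _edges(values: np.ndarray, finite: np.ndarray, bins: Bins) -> np.ndarray:
    if not isinstance(bins, int):
        e = np.asarray(bins, dtype=float)
        if len(e) < 2 or not np.all(np.diff(e) > 0):
            raise ValueError("bin edges must be strictly increasing")
        return e
    if not finite.any():
        raise ValueError("no finite values to bin")
    lo = float(values[finite].min())
    hi = float(values[finite].max())
    if lo == hi:
        hi = lo + 1.0
    return np.linspace(lo, hi, bins + 1)


@dataclass
class HistData:
    """1-D histogram of one parameter, full set and selection together."""

    edges: np.ndarray
    full_counts: np.ndarray
    sel_counts: np.ndarray
    #: per-category (full, selection) counts when stacked
    stacks: dict[str, tuple[np.ndarray, np.ndarray]] = dc_field(default_factory=dict)
    colors: dict[str, str] = dc_field(default_factory=dict)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


@dataclass
class Hist2DData:
    """2-D (density) histogram; ``counts`` is the displayed population."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    full_counts: np.ndarray
    sel_counts: np.ndarray

    def argmax_center(self) -> tuple[float, float]:
        """(x, y) center of the most populated bin of the displayed grid."""
        ix, iy = np.unravel_index(int(np.argmax(self.counts)), self.counts.shape)
        cx = 0.5 * (self.x_edges[ix] + self.x_edges[ix + 1])
        cy = 0.5 * (self.y_edges[iy] + self.y_edges[iy + 1])
        return float(cx), float(cy)


@dataclass
class AggData:
    """Binned statistic of one parameter (mean +/- spread per bin)."""

    labels: list
    values: np.ndarray
    spreads: np.ndarray
    #: one series per split category: label-aligned statistic arrays
    series: dict[str, np.ndarray] = dc_field(default_factory=dict)


def histogram_data(
    table: ParameterTable,
    field: str,
    mask: Optional[np.ndarray] = None,
    bins: Bins = 64,
    stack_field: Optional[str] = None,
    config: Optional[ConfigSpec] = None,
) -> HistData:
    """Histogram a numeric field over full set and selection.

    Equal-width bins over the full set's finite range unless explicit
    edges are given; the last bin is right-closed (numpy convention).
    Missing values never count.  ``stack_field`` partitions the counts by
    a categorical column (e.g. cell centering), with colors taken from
    the configuration when available.
    """
    values, finite = _finite_column(table, field)
    mask = np.ones(len(table), dtype=bool) if mask is None else np.asarray(mask, bool)
    edges = _edges(values, finite, bins)
    full_counts, _ = np.histogram(values[finite], bins=edges)
    sel_counts, _ = np.histogram(values[finite & mask], bins=edges)
    data = HistData(edges, full_counts, sel_counts)
    if stack_field is not None:
        cats = table.categories(stack_field)
        col = table.column(stack_field)
        for cat in cats:
            in_cat = np.asarray(col, dtype=object) == cat
            f, _ = np.histogram(values[finite & in_cat], bins=edges)
            s, _ = np.histogram(values[finite & in_cat & mask], bins=edges)
            data.stacks[cat] = (f, s)
            if config is not None and (stack_field, cat) in config.colors:
                data.colors[cat] = config.colors[(stack_field, cat)]
    return data


def hist2d_data(
    table: ParameterTable,
    field_x: str,
    field_y: str,
    bins: Bins = 64,
    mask: Optional[np.ndarray] = None,
    mode: str = "overlay",
    bins_y: Optional[Bins] = None,
) -> Hist2DData:
    """2-D histogram (density map) of two numeric fields."""
    _check_mode(mode)
    xv, xf = _finite_column(table, field_x)
    yv, yf = _finite_column(table, field_y)
    finite = xf & yf
    mask = np.ones(len(table), dtype=bool) if mask is None else np.asarray(mask, bool)
    x_edges = _edges(xv, finite, bins)
    y_edges = _edges(yv, finite, bins if bins_y is None else bins_y)
    full_counts, _, _ = np.histogram2d(xv[finite], yv[finite], bins=(x_edges, y_edges))
    sel = finite & mask
    sel_counts, _, _ = np.histogram2d(xv[sel], yv[sel], bins=(x_edges, y_edges))
    counts = sel_counts if mode == "selection_only" else full_counts
    return Hist2DData(x_edges, y_edges, counts, full_counts, sel_counts)


def scatter_data(
    table: ParameterTable,
    field_x: str,
    field_y: str,
    color_field: Optional[str] = None,
    mask: Optional[np.ndarray] = None,
    mode: str = "selection_only",
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Point arrays (x, y, color value) for the displayed population.

    One point per displayed row with finite x and y.  Categorical color
    fields are mapped to their category index.
    """
    _check_mode(mode)
    xv, xf = _finite_column(table, field_x)
    yv, yf = _finite_column(table, field_y)
    shown = xf & yf
    if mode == "selection_only":
        m = np.ones(len(table), dtype=bool) if mask is None else np.asarray(mask, bool)
        shown = shown & m
    color = None
    if color_field is not None:
        if table.dtype_of(color_field) in ("categorical", "text"):
            cats = sorted(set(map(str, table.column(color_field))))
            lookup = {c: i for i, c in enumerate(cats)}
            color = np.array([lookup[str(v)] for v in table.column(color_field)], float)
        else:
            color = table.column(color_field).astype(float)
        color = color[shown]
    return xv[shown], yv[shown], color


def pixel_data(
    table: ParameterTable,
    field_x: str,
    field_y: str,
    color_field: str,
    mask: Optional[np.ndarray] = None,
    reduce: str = "mean",
) -> dict[tuple[int, int], float]:
    """Raster-scan map: reduce a parameter per integer (x, y) position.

    Built for fixed-target rastering, where each frame carries its chip
    position; multiple crystals on one position are reduced by ``mean``
    (or ``median`` / ``count``).  Unoccupied positions are simply absent.
    """
    if reduce not in ("mean", "median", "count"):
        raise ValueError(f"unknown reduction {reduce!r}")
    mask = np.ones(len(table), dtype=bool) if mask is None else np.asarray(mask, bool)
    xv, xf = _finite_column(table, field_x)
    yv, yf = _finite_column(table, field_y)
    cv, cf = _finite_column(table, color_field)
    ok = mask & xf & yf & cf
    cells: dict[tuple[int, int], list[float]] = {}
    for x, y, v in zip(xv[ok], yv[ok], cv[ok]):
        cells.setdefault((int(round(x)), int(round(y))), []).append(float(v))
    if reduce == "count":
        return {k: float(len(v)) for k, v in cells.items()}
    fn = np.mean if reduce == "mean" else np.median
    return {k: float(fn(v)) for k, v in cells.items()}


def aggregate_data(
    table: ParameterTable,
    bin_field: str,
    value_field: str,
    stat: str = "mean",
    spread: str = "stddev",
    split_field: Optional[str] = None,
    mask: Optional[np.ndarray] = None,
) -> AggData:
    """Bin one axis and compute a statistic of another per bin.

    The classic use is average unit-cell volume per run, with optional
    population-standard-deviation error bars.  ``split_field`` (e.g. the
    comparison group) yields one additional statistic series per split
    category.  Empty bins carry NaN.
    """
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown statistic {stat!r}")
    if spread not in ("stddev", "none"):
        raise ValueError(f"unknown spread {spread!r}")
    mask = np.ones(len(table), dtype=bool) if mask is None else np.asarray(mask, bool)
    vv, vf = _finite_column(table, value_field)
    bin_dtype = table.dtype_of(bin_field)
    if bin_dtype in ("categorical", "text"):
        keys = np.asarray(table.column(bin_field), dtype=object)
        key_missing = table.missing_mask(bin_field)
    elif bin_dtype == "integer":
        keys = table.column(bin_field).astype(np.int64)
        key_missing = table.missing_mask(bin_field)
    else:
        raise TypeError("bin_field must be categorical or integer-valued")
    ok = mask & vf & ~key_missing
    labels = sorted(set(keys[ok].tolist()))

    def stat_of(sel: np.ndarray) -> tuple[float, float]:
        if not sel.any():
            return float("nan"), float("nan")
        v = vv[sel]
        center = float(np.mean(v)) if stat == "mean" else float(np.median(v))
        return center, float(np.std(v))  # population std

    values = np.empty(len(labels))
    spreads = np.empty(len(labels))
    for i, lab in enumerate(labels):
        values[i], spreads[i] = stat_of(ok & (keys == lab))
    data = AggData(labels, values, spreads)

    if split_field is not None:
        split_dtype = table.dtype_of(split_field)
        scol = (
            np.asarray(table.column(split_field), dtype=object)
            if split_dtype in ("categorical", "text")
            else table.column(split_field)
        )
        for sval in sorted(set(scol[ok].tolist())):
            series = np.empty(len(labels))
            for i, lab in enumerate(labels):
                series[i], _ = stat_of(ok & (keys == lab) & (scol == sval))
            data.series[str(sval)] = series
    return data


def comparison_hist2d_data(
    table: ParameterTable,
    field: str,
    group_x: int,
    group_y: int,
    bins: Bins = 64,
) -> Hist2DData:
    """2-D histogram of one parameter across two comparison groups.

    Each count is one diffraction pattern with the parameter present in
    both groups; identical groups put all mass on the diagonal.
    """
    xs, ys = pair_values(table, field, group_x, group_y)
    if len(xs) == 0:
        raise ValueError("no complete pairs between the requested groups")
    finite = np.ones(len(xs), dtype=bool)
    x_edges = _edges(xs, finite, bins)
    y_edges = _edges(ys, finite, bins)
    counts, _, _ = np.histogram2d(xs, ys, bins=(x_edges, y_edges))
    return Hist2DData(x_edges, y_edges, counts, counts, counts)


# -- optional static rendering ---------------------------------------------

def _axes(path):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5), constrained_layout=True)
    return plt, fig, ax


def render_histogram(data: HistData, path: str, title: str = "") -> None:
    plt, fig, ax = _axes(path)
    widths = np.diff(data.edges)
    if data.stacks:
        bottom = np.zeros_like(data.full_counts, dtype=float)
        for cat, (full, _sel) in data.stacks.items():
            ax.bar(data.centers, full, width=widths, bottom=bottom,
                   color=data.colors.get(cat), label=cat, alpha=0.4)
            bottom = bottom + full
        bottom = np.zeros_like(data.sel_counts, dtype=float)
        for cat, (_full, sel) in data.stacks.items():
            ax.bar(data.centers, sel, width=widths, bottom=bottom,
                   color=data.colors.get(cat))
            bottom = bottom + sel
        ax.legend()
    else:
        ax.bar(data.centers, data.full_counts, width=widths, alpha=0.4)
        ax.bar(data.centers, data.sel_counts, width=widths)
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_hist2d(data: Hist2DData, path: str, title: str = "") -> None:
    plt, fig, ax = _axes(path)
    mesh = ax.pcolormesh(data.x_edges, data.y_edges, data.counts.T)
    fig.colorbar(mesh, ax=ax, label="count")
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_scatter(x, y, color, path: str, title: str = "") -> None:
    plt, fig, ax = _axes(path)
    sc = ax.scatter(x, y, c=color, s=6)
    if color is not None:
        fig.colorbar(sc, ax=ax)
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)
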