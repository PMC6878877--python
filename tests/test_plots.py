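import numpy as np
import pandas as pd
import pytest

from streamsieve.compare import merge_tables
from streamsieve.dat_table import ConfigSpec, FieldSpec, ParameterTable
from streamsieve.plots import (
    aggregate_data,
    comparison_hist2d_data,
    hist2d_data,
    histogram_data,
    pixel_data,
    scatter_data,
)
from streamsieve.synth import generate_comparison_fixture

from conftest import make_random_table


def _table(**cols):
    fields = []
    data = {}
    for name, (dtype, values) in cols.items():
        fields.append(FieldSpec(name, dtype))
        data[name] = values
    df = pd.DataFrame(data)
    for f in fields:
        if f.dtype == "integer":
            df[f.name] = df[f.name].astype(np.int64)
    return ParameterTable(df, fields)


# -- 1D histogram -----------------------------------------------------------

def test_histogram_basic_counts():
    t = _table(v=("real", [1.0, 1.0, 2.0, 3.0]))
    h = histogram_data(t, "v", bins=2)
    assert h.edges.tolist() == [1.0, 2.0, 3.0]
    assert h.full_counts.tolist() == [2, 2]  # last bin right-closed


def test_histogram_mask_all_false_keeps_full_counts():
    t = _table(v=("real", [1.0, 2.0, 3.0]))
    h = histogram_data(t, "v", mask=np.zeros(3, dtype=bool), bins=2)
    assert h.sel_counts.sum() == 0
    assert h.full_counts.sum() == 3


def test_histogram_missing_values_excluded():
    t = _table(v=("real", [1.0, float("nan"), 3.0]))
    h = histogram_data(t, "v", bins=2)
    assert h.full_counts.sum() == 2


def test_histogram_no_finite_values_errors():
    t = _table(v=("real", [float("nan")] * 3))
    with pytest.raises(ValueError):
        histogram_data(t, "v", bins=4)


def test_stacked_counts_sum_to_totals_random():
    rng = np.random.default_rng(6)
    for seed in range(5):
        t = make_random_table(rng, 150)
        mask = rng.random(150) < 0.5
        h = histogram_data(t, "x", mask=mask, bins=7, stack_field="cat")
        full_stack = sum(f for f, _ in h.stacks.values())
        sel_stack = sum(s for _, s in h.stacks.values())
        np.testing.assert_array_equal(full_stack, h.full_counts)
        np.testing.assert_array_equal(sel_stack, h.sel_counts)
        assert (h.sel_counts <= h.full_counts).all()


def test_stacked_colors_from_config():
    t = _table(v=("real", [1.0, 2.0]), cat=("categorical", ["C", "P"]))
    cfg = ConfigSpec(colors={("cat", "C"): "#0000ff"})
    h = histogram_data(t, "v", bins=2, stack_field="cat", config=cfg)
    assert h.colors == {"C": "#0000ff"}


def test_histogram_total_invariant_under_finer_binning():
    rng = np.random.default_rng(12)
    t = make_random_table(rng, 200)
    totals = {n: histogram_data(t, "y", bins=n).full_counts.sum() for n in (4, 8, 64)}
    assert len(set(totals.values())) == 1


# -- 2D histogram -----------------------------------------------------------

def test_hist2d_count_conservation_and_rebinning():
    rng = np.random.default_rng(13)
    t = make_random_table(rng, 300)
    finite = ~t.missing_mask("x") & ~t.missing_mask("y")
    h1 = hist2d_data(t, "x", "y", bins=8)
    h2 = hist2d_data(t, "x", "y", bins=16)
    assert h1.counts.sum() == h2.counts.sum() == finite.sum()


def test_hist2d_modes():
    t = _table(x=("real", [0.0, 1.0, 2.0, 3.0]), y=("real", [0.0, 1.0, 2.0, 3.0]))
    mask = np.array([True, True, False, False])
    sel = hist2d_data(t, "x", "y", bins=2, mask=mask, mode="selection_only")
    full = hist2d_data(t, "x", "y", bins=2, mask=mask, mode="full_only")
    assert sel.counts.sum() == 2 and full.counts.sum() == 4
    # edges come from the full range in every mode, so overlays align
    np.testing.assert_array_equal(sel.x_edges, full.x_edges)
    with pytest.raises(ValueError):
        hist2d_data(t, "x", "y", bins=2, mode="sideways")


def test_selection_only_with_all_true_mask_equals_full_only():
    rng = np.random.default_rng(14)
    t = make_random_table(rng, 100)
    a = hist2d_data(t, "x", "y", bins=6, mask=np.ones(100, bool), mode="selection_only")
    b = hist2d_data(t, "x", "y", bins=6, mode="full_only")
    np.testing.assert_array_equal(a.counts, b.counts)


def test_hist2d_argmax_recovers_tight_cluster():
    rng = np.random.default_rng(15)
    n = 400
    x = np.concatenate([rng.normal(-0.3, 0.02, n), rng.uniform(-1.5, 1.5, n // 4)])
    y = np.concatenate([rng.normal(0.4, 0.02, n), rng.uniform(-1.5, 1.5, n // 4)])
    t = _table(x=("real", x.tolist()), y=("real", y.tolist()))
    edges = np.round(np.arange(-1.55, 1.56, 0.1), 10)
    h = hist2d_data(t, "x", "y", bins=edges, bins_y=edges)
    cx, cy = h.argmax_center()
    assert cx == pytest.approx(-0.3, abs=0.05)
    assert cy == pytest.approx(0.4, abs=0.05)


# -- scatter ----------------------------------------------------------------

def test_scatter_point_counts_and_modes():
    t = _table(
        x=("real", [0.0, 1.0, float("nan"), 3.0]),
        y=("real", [0.0, 1.0, 2.0, 3.0]),
    )
    mask = np.array([True, False, True, True])
    xs, ys, _ = scatter_data(t, "x", "y", mask=mask, mode="selection_only")
    assert len(xs) == 2  # finite x,y AND selected
    xs_full, _, _ = scatter_data(t, "x", "y", mask=mask, mode="full_only")
    assert len(xs_full) == 3


def test_scatter_step_data_separates_in_y():
    """Sort-position vs detector-shift view: a step is visible in y."""
    n = 100
    shift = np.where(np.arange(n) < 60, -0.3, 0.1)
    t = _table(
        pos=("real", np.arange(n, dtype=float).tolist()),
        sx=("real", shift.tolist()),
        run=("integer", (np.arange(n) // 50).tolist()),
    )
    xs, ys, cs = scatter_data(t, "pos", "sx", color_field="run")
    before = ys[xs < 60]
    after = ys[xs >= 60]
    assert before.max() < after.min()
    assert set(cs.tolist()) == {0.0, 1.0}


def test_scatter_categorical_color_uses_category_index():
    t = _table(
        x=("real", [0.0, 1.0]), y=("real", [0.0, 1.0]),
        cat=("categorical", ["P", "C"]),
    )
    _, _, cs = scatter_data(t, "x", "y", color_field="cat")
    assert cs.tolist() == [1.0, 0.0]  # sorted categories: C=0, P=1


def test_scatter_empty_table():
    t = _table(x=("real", []), y=("real", []))
    xs, ys, cs = scatter_data(t, "x", "y")
    assert len(xs) == len(ys) == 0 and cs is None


# -- pixel ------------------------------------------------------------------

def test_pixel_identity_mean_and_count():
    t = _table(
        px=("integer", [0, 0, 1]),
        py=("integer", [0, 0, 2]),
        v=("real", [10.0, 20.0, 7.0]),
    )
    assert pixel_data(t, "px", "py", "v") == {(0, 0): 15.0, (1, 2): 7.0}
    assert pixel_data(t, "px", "py", "v", reduce="count") == {(0, 0): 2.0, (1, 2): 1.0}
    with pytest.raises(ValueError):
        pixel_data(t, "px", "py", "v", reduce="sum")


# -- aggregated -------------------------------------------------------------

def test_aggregate_closed_form():
    t = _table(
        run=("categorical", ["A", "A", "A", "B"]),
        v=("real", [1.0, 2.0, 3.0, 5.0]),
    )
    agg = aggregate_data(t, "run", "v")
    assert agg.labels == ["A", "B"]
    np.testing.assert_allclose(agg.values, [2.0, 5.0])
    np.testing.assert_allclose(agg.spreads, [np.sqrt(2.0 / 3.0), 0.0])


def test_aggregate_empty_bin_is_missing():
    t = _table(
        run=("categorical", ["A", "B"]),
        v=("real", [1.0, float("nan")]),
    )
    agg = aggregate_data(t, "run", "v")
    assert agg.labels == ["A"]  # B has no finite value -> not a populated bin


def test_aggregate_split_series():
    tables, _ = generate_comparison_fixture(n_groups=2, n_frames=8, missing_prob=0.0, seed=3)
    ct = merge_tables(tables)
    agg = aggregate_data(ct, "comp_id", "volume", split_field="comp_group")
    assert set(agg.series) == {"0", "1"}
    for g in (0, 1):
        series = agg.series[str(g)]
        grp_mask = ct.column("comp_group") == g
        for i, cid in enumerate(agg.labels):
            rows = grp_mask & (ct.column("comp_id") == cid)
            np.testing.assert_allclose(series[i], ct.column("volume")[rows].mean())


# -- comparison 2D histogram ------------------------------------------------

def test_comparison_hist2d_identical_groups_on_diagonal():
    tables, _ = generate_comparison_fixture(n_groups=2, n_frames=10, missing_prob=0.0, seed=4)
    t0 = tables[0]
    ct = merge_tables([t0, t0])
    h = comparison_hist2d_data(ct, "volume", 0, 1, bins=5)
    assert h.counts.sum() == 10
    off_diag = h.counts.copy()
    np.fill_diagonal(off_diag, 0)
    assert off_diag.sum() == 0


def test_comparison_hist2d_rebinning_conserves_pairs():
    tables, _ = generate_comparison_fixture(
        n_groups=2, n_frames=30, missing_prob=0.2, seed=5
    )
    ct = merge_tables(tables)
    c1 = comparison_hist2d_data(ct, "volume", 0, 1, bins=4).counts.sum()
    c2 = comparison_hist2d_data(ct, "volume", 0, 1, bins=16).counts.sum()
    assert c1 == c2
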