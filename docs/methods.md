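# Methods

This note records the data model, the semantics that were genuinely open
design choices, the synthetic-data conditions the tests run under, and
the known limitations.

## Stream scanning and byte-span indexing

A CrystFEL stream (format 2.2/2.3, as written by CrystFEL 0.7.0) is
scanned in a single pass.  Everything before the first
`----- Begin chunk -----` line is the header span (the embedded geometry
file is captured inside it but never parsed).  For every chunk and every
crystal block the scanner records both the parsed scalar fields and the
half-open **byte** span `[start, end)` of the block, so any selection can
later be re-extracted verbatim.  Byte offsets (not character offsets)
define spans and files are treated as ASCII/UTF-8; this is what makes
subset extraction bit-exact.

Units are normalized at parse time: cell axes are stored in Å (the
stream prints nm; conversion is an exact ×10), angles in degrees,
detector shifts in mm as printed after `predict_refine/det_shift`, and
resolutions as the Å figure of the `… nm^-1 or X A` lines.  Optional
fields that are absent or unparseable are *missing*, never zero, and
never abort the scan; only structural defects (missing magic line, a
block opened but never closed) raise, the latter naming the byte offset
where the block began.  Unknown lines inside a chunk are preserved in
the spans but ignored, for forward compatibility.

## The parameter table

`.dat` is a plain whitespace-separated text table with one header line;
the writer always emits tabs.  Column types are `integer`, `real`,
`categorical`, `text` or `flag`, assigned by an XML configuration or
inferred (all-numeric → real, else categorical).  Missing values use
fixed sentinels — NaN (real), −1 (integer), `none` (categorical),
`-` (text), false (flag) — so the file stays rectangular and a
read→write→read cycle is a fixed point.  Floats are written with
`repr`, i.e. the shortest digit string that round-trips exactly.

Table generation (`extract.build_table`) emits one row per crystal and
one row per unindexed frame (crystal columns at their sentinels), with
frame fields repeated on every crystal row of a multi-crystal frame.
Unindexed rows exist so hit-rate histograms and the third "no centering"
category are first-class; `indexed_only=True` suppresses them.  Derived
columns: the triclinic cell volume

    V = abc √(1 − cos²α − cos²β − cos²γ + 2 cosα cosβ cosγ)   [Å³]

(checked in the tests against an explicit lattice-vector triple-product
oracle) and the run number captured from the image filename by a
user-supplied one-group regular expression.  Optional per-event scalars
are harvested from the HDF5/CXI image files; any failure there degrades
to a sentinel plus a logged warning, never a lost row.

## Filter semantics

* `Between(field, lo, hi)` is **half-open** `lo ≤ v < hi`.  Consequence:
  `Between = GreaterEqual ∧ LessThan`, and two adjacent ranges drawn on
  a histogram never double-count a row.
* Missing numerics (NaN / −1) fail *every* range filter: an unindexed
  frame is never "in range".  Missing categoricals are selectable only
  through the explicit `none` value of an `in` filter.
* An empty group evaluates all-true (neutral element): a fresh session
  selects the whole data set.  This holds for empty OR groups too —
  an empty OR is an absent constraint, not an unsatisfiable one.
* Multiple `between` leaves on the same field may coexist in
  hand-written filter files; they are combined by their parent group
  like any other leaves.  `set_range_filter` implements the plot-drawn
  range: it replaces the managed `Between` directly under the root
  group or appends one.

Filter trees serialize to a small XML dialect (`and`, `or`, `between`,
`lessthan`, `greaterequal`, `in`, `flag`, and the six comparison leaf
tags); parse∘serialize is the identity on trees.

## Comparison mode

Merging G tables of the same frames assigns each distinct
`(filename, event)` key — optionally matched on basename only — a
contiguous comparison ID 0..F−1 in order of first appearance, and tags
each row with its source group.  Classes may be *partial* (a frame
absent from some groups) and *multi-row* (multi-crystal frames).  The
six class-wise filters are defined for all of these:

* `min`/`max` select exactly one row per class — the extremal finite
  value, ties broken to the lowest group then lowest row index; classes
  with no finite value select nothing.
* `all_between[lo,hi)` qualifies a class iff **every** group contributes
  at least one in-range row (a group missing the class fails it);
  `any_between` iff at least one row is in range.  Both select **all
  rows** of qualifying classes.  The all-rows reading makes the
  selection size exactly G × (qualifying patterns) whenever every group
  has one row per pattern — the row/pattern arithmetic the suite
  verifies on synthetic fixtures.
* `all_same` qualifies a class iff all rows carry an identical value,
  where missing equals missing, and real values may be compared with an
  optional absolute tolerance (default 0 — exact equality of the parsed
  text-table values, which is well defined since `.dat` serialization is
  exact).  `any_different` is its exact class-level complement, so the
  two masks partition every merged table.

`pair_values` (behind the comparison scatter / 2D histogram) emits one
(x, y) pair per class with a non-missing value in both groups,
multi-crystal classes contributing their first row per group (min/max
reduction available).  The persistent merged format is an extended
`.dat` with `comp_id`/`comp_group` columns and `#group i name` header
comments — diffable text rather than a binary container.

## Plot data

All five plot types are computed as data, never pixels.  Two populations
are always computed over **shared bin edges derived from the full set's
finite range** (not the selection's), so an overlay of opaque selection
on semi-transparent full set aligns by construction; display modes
merely choose which population is "displayed".  Binning follows the
numpy convention: equal-width bins, last bin right-closed, so rebinning
a histogram conserves its total count.  Aggregated plots report the
per-bin mean (or median) with the population standard deviation as
spread, empty bins carrying NaN; a split field (e.g. the comparison
group) yields one series per split value.  Pixel maps reduce a
parameter over integer grid positions by mean, median or count.

## Synthetic study conditions

The generator (`streamsieve.synth`) emulates the statistical structure
the diagnostics operate on, with counts realized exactly (rounded
fractions via a seeded permutation) and byte-identical output per seed:

* **Cell mixture**: by default 75% C-centered orthorhombic
  (61.5, 122.2, 160.5 Å, 90° angles — a membrane-protein-scale cell) and
  25% P monoclinic (40, 50, 60 Å, β = 105°), independent Gaussians per
  axis (sd 0.3–0.7 Å) and angle (sd 0.1–0.15°).  Independence per
  parameter is sufficient for histogram/selection tests; no covariance
  structure is claimed.
* **Detector shifts**: correctly indexed crystals draw from Gaussian
  clusters — default one cluster at (−0.3, 0.4) mm, sd 0.03 mm, the
  wrong-beam-center signature; misindexed crystals draw uniform shifts
  on ±1.5 mm and broad uniform cells (axes ±25%, angles 70–110°), so
  they fail any tight cell selection.
* Defaults: 100 frames, 60% indexed, 10% of indexed frames carry a
  second crystal, 0% misindexed; filenames `run<NNNN>_<i>.cxi //event`
  (100 events/file, 500 frames/run) so run-number extraction and
  time-ordering are exercisable.
* Peak and reflection tables contain plausible dummy rows only: the
  format is exercised, not the diffraction physics.  Passing tests
  therefore demonstrate correctness of parsing, querying, accounting
  and extraction — not robustness to the full messiness of real
  detector output (malformed encodings, interleaved MPI writes,
  gigabyte-scale streams).

The comparison fixture generator produces G tables over the same frame
keys with controlled per-group value-missingness, whole-row absence and
multi-crystal duplication, so class-wise expectations are computable
exactly by enumeration.

## Problem sizes and numerical choices

The acceptance experiment uses 5000 frames (all indexed, 40% correct /
60% misindexed), large enough that the correct cluster (≈1500 crystals
after the C-cell selection) dominates any 0.1 mm background bin by two
orders of magnitude while the whole run takes seconds.  The 2D shift
histogram uses 0.1 mm bins whose *centers* lie on the 0.1 mm grid
(edges at ±0.05 mm offsets) — the natural grid for reading off a beam
center correction, and it avoids splitting a cluster across an edge.
The correct-cell selection spans ±5 sd per cell parameter around the
generating distribution, the tight-but-safe window a user would draw on
the six cell histograms.

Oracle suites run 1000 random filter trees (tables ≤ 80 rows, depth
≤ 4) and 500 random comparison fixtures (G ≤ 4, F < 50) against
independent per-row/per-class brute-force evaluators.  Sorting is
stable with missing values last in either direction (realized as a
missing-first lexsort key, value second).  The random export limit uses
`numpy.random.default_rng(seed)` and returns its sample in sort order.

## Limitations

* Reflection and peak tables are indexed as byte spans but not parsed
  into numeric arrays; geometry files are carried, not interpreted.
* The `.lst` writer deduplicates to one line per frame (its purpose is
  indexing input); a per-crystal list is not offered.
* Stream subset export writes one crystal per chunk, repeating frame
  text for multi-crystal frames — deliberate, so individual crystals
  are selectable and sortable, but not the single-chunk convention
  other tools may expect for multi-crystal frames.
* Tables are in-memory (pandas); no out-of-core path.
* `all_same` on reals compares parsed values exactly by default; use
  the tolerance when comparing quantities printed with few decimals.
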