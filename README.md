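# streamsieve

Index, query, plot and export CrystFEL stream files — a headless data
engine for serial-crystallography diagnostics.

## The problem

Serial femtosecond crystallography (SFX) collects one snapshot diffraction
pattern per crystal, hundreds of thousands of frames per experiment.
Indexing software (CrystFEL's `indexamajig`) writes its results to a large
text *stream file*: one "chunk" per frame, each with the image
filename/event, the peak list, and zero or more "crystal" blocks holding
the refined unit cell, lattice centering, predicted detector shift,
diffraction resolution limit and integrated reflections.  Practically
every processing decision — is the beam center right? did the cell drift?
which integration radii are best? which frames should be merged? — starts
with querying and plotting these per-frame parameters.

`streamsieve` turns streams into a typed parameter table (one row per
crystal, one row per unindexed frame) that is simultaneously an *index
into the stream's bytes*, then provides:

* a **Boolean filter tree** (AND/OR groups over `between` / `less than` /
  `greater or equal` / `in-set` / flag leaves) that evaluates to a row
  mask — the "current selection";
* **comparison mode**: merge tables of the same frames processed under
  different conditions, link equivalent frames by a comparison ID, and
  filter class-wise with `min`, `max`, `all_between`, `any_between`,
  `all_same`, `any_different`;
* the five diagnostic **plot data** computations (histogram, 2D
  histogram, scatter, pixel map, aggregated statistic) with
  full-set/selection overlay semantics, computed headlessly;
* **export** of any selection — sorted, limited (first-N or random-N),
  partitioned by any parameter — as a `.dat` table, a `.lst` frame list
  (`file.cxi //event`), or a bit-exact extracted **stream subset** that
  downstream merging programs accept.

The stream subset writer uses the recorded byte spans: each selected
crystal's chunk is copied verbatim with the other crystal blocks removed,
so re-scanning the subset reproduces every parameter value exactly.

A synthetic stream generator with known ground truth
(`streamsieve.synth`) drives the test suite; no external data are needed.

## Worked example: finding a wrong beam center

When the detector geometry used for indexing has a wrong beam center,
prediction refinement leaves every *correctly indexed* crystal with
nearly the same predicted detector shift, while misindexed crystals
scatter broadly.  Selecting the expected unit cell and histogramming the
shifts in 2D exposes the needed correction as the densest bin.

```sh
# 1000 synthetic frames; 60% indexed; correct crystals' shifts cluster
# at (-0.3, 0.4) mm, misindexed crystals scatter uniformly
streamsieve synth --frames 1000 --indexed 0.6 --multi 0.1 \
    --misindexed 0.3 --seed 1 --out demo.stream --truth truth.dat
streamsieve gen --out demo.dat --run-regex 'run(\d+)' demo.stream
```

    wrote demo.stream (1000 frames, 660 crystals)
    wrote demo.dat (1060 rows)

1060 rows = 660 crystals + 400 unindexed frames.  Select the expected
cell with a filter file `correct_cell.xml`:

```xml
<and>
  <between field="a" min="60.0" max="63.0"/>
  <between field="b" min="119.7" max="124.7"/>
  <between field="c" min="157.0" max="164.0"/>
  <in field="centering" values="C"/>
</and>
```

```sh
streamsieve plot hist2d --in demo.dat --x det_shift_x --y det_shift_y \
    --bins 31 --mode selection_only --filter correct_cell.xml --dump shift.tsv
```

The densest bin of `shift.tsv` is centered at x = −0.289 mm,
y = 0.387 mm (count 255) — the injected (−0.3, 0.4) mm offset recovered
to within half a bin width, i.e. the correction to apply to the beam
center.  Export the 100 highest-resolution correctly indexed crystals as
a stream for merging:

```sh
streamsieve export --in demo.dat --filter correct_cell.xml \
    --sort resolution_limit_A:asc --limit 100 --format stream --out best100.stream
```

    wrote best100.stream (100 rows)

The same operations are available as a library (`streamsieve.scan_stream`,
`build_table`, `evaluate`, `hist2d_data`, `write_stream_subset`, ...); the
CLI is a thin wrapper.

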