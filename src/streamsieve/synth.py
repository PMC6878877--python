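"""Synthetic CrystFEL-format streams with known ground truth.

Real serial-crystallography streams come from indexing hundreds of
thousands of frames; for testing the indexing-diagnostics pipeline we
instead *generate* streams whose statistical structure is controlled:

* a mixture of lattice/centering classes, each with Gaussian unit-cell
  parameter distributions (independent per axis/angle — enough for
  histogram and clustering diagnostics, no covariance model is claimed);
* correctly indexed crystals whose predicted detector shifts fall in
  tight Gaussian clusters (the signature of a wrong beam center), while
  misindexed crystals draw broad uniform shifts and broad uniform cells;
* a controlled fraction of unindexed frames (``indexed_by = none``) and
  of multi-crystal frames.

Counts are deterministic given the seed (rounded fractions realized by a
seeded permutation), and the emitted stream text is byte-identical for
the same spec and seed.  Peak and reflection tables contain plausible
dummy rows only — the format is exercised, not the physics.

Filenames follow ``run<NNNN>_<i>.cxi`` with ``//`` events so run-number
extraction and time ordering are exercisable downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dat_table import FieldSpec, ParameterTable

__all__ = [
    "CellModel",
    "ShiftCluster",
    "StreamSynthSpec",
    "generate_stream",
    "generate_comparison_fixture",
]


@dataclass(frozen=True)
class CellModel:
    """One centering class: Gaussian cell-parameter distribution."""

    lattice_type: str
    centering: str
    unique_axis: str
    mean: tuple[float, float, float, float, float, float]  # a,b,c (A), angles (deg)
    sd: tuple[float, float, float, float, float, float]
    weight: float


@dataclass(frozen=True)
class ShiftCluster:
    """Gaussian cluster of predicted detector shifts (mm)."""

    x: float
    y: float
    sd: float
    weight: float


#: A membrane-protein-like C-centered orthorhombic cell plus a minority
#: P lattice, the two-centering situation the diagnostics care about.
DEFAULT_CELLS = (
    CellModel(
        "orthorhombic", "C", "*",
        (61.5, 122.2, 160.5, 90.0, 90.0, 90.0),
        (0.3, 0.5, 0.7, 0.1, 0.1, 0.1),
        0.75,
    ),
    CellModel(
        "monoclinic", "P", "b",
        (40.0, 50.0, 60.0, 90.0, 105.0, 90.0),
        (0.3, 0.3, 0.3, 0.1, 0.15, 0.1),
        0.25,
    ),
)

#: One tight shift cluster at the beam-center offset of the worked
#: wrong-beam-center scenario: (-0.3, 0.4) mm, sd 0.03 mm.
DEFAULT_SHIFT_CLUSTERS = (ShiftCluster(-0.3, 0.4, 0.03, 1.0),)


@dataclass
class StreamSynthSpec:
    """Study conditions for one synthetic stream."""

    n_frames: int = 100
    indexed_fraction: float = 0.6
    multi_crystal_fraction: float = 0.1   # of indexed frames, get a 2nd crystal
    misindexed_fraction: float = 0.0      # of crystals: broad cells + uniform shifts
    cells: Sequence[CellModel] = DEFAULT_CELLS
    shift_clusters: Sequence[ShiftCluster] = DEFAULT_SHIFT_CLUSTERS
    misindexed_shift_range: float = 1.5   # mm, uniform on [-r, r] per axis
    resolution_mean_A: float = 2.5
    resolution_sd_A: float = 0.4
    photon_energy_eV: float = 9300.0
    events_per_file: int = 100
    frames_per_run: int = 500
    run_start: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("indexed_fraction", "multi_crystal_fraction", "misindexed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(c.weight for c in self.cells) - 1.0) > 1e-9:
            raise ValueError("cell model weights must sum to 1")
        if abs(sum(c.weight for c in self.shift_clusters) - 1.0) > 1e-9:
            raise ValueError("shift cluster weights must sum to 1")
        if any(min(c.sd) < 0 for c in self.cells) or any(
            c.sd < 0 for c in self.shift_clusters
        ):
            raise ValueError("standard deviations must be >= 0")


_HEADER = """CrystFEL stream format 2.3
Generated by CrystFEL 0.7.0 (synthetic)
indexamajig -i files.lst -o synthetic.stream --peaks=cxi
----- Begin geometry file -----
; synthetic placeholder geometry (not parsed)
clen = 0.120
photon_energy = {energy:.1f}
----- End geometry file -----
"""

_TRUTH_FIELDS = [
    FieldSpec("frame", "integer"),
    FieldSpec("filename", "text"),
    FieldSpec("event", "integer"),
    FieldSpec("run", "integer"),
    FieldSpec("crystal_index", "integer"),
    FieldSpec("correct", "integer"),          # 1 = correct indexing
    FieldSpec("cell_model", "categorical"),   # centering letter
    FieldSpec("shift_cluster", "integer"),    # -1 for misindexed
    FieldSpec("a", "real", units="A"),
    FieldSpec("b", "real", units="A"),
    FieldSpec("c", "real", units="A"),
    FieldSpec("alpha", "real", units="deg"),
    FieldSpec("beta", "real", units="deg"),
    FieldSpec("gamma", "real", units="deg"),
    FieldSpec("det_shift_x", "real", units="mm"),
    FieldSpec("det_shift_y", "real", units="mm"),
    FieldSpec("resolution_limit_A", "real", units="A"),
]


def _exact_subset(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean mask with exactly round(fraction*n) True, seeded choice."""
    k = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    if k:
        mask[rng.permutation(n)[:k]] = True
    return mask


def generate_stream(
    spec: StreamSynthSpec, out_path: str | Path
) -> tuple[Path, ParameterTable]:
    """Write a synthetic stream; return its path and the truth table.

    The truth table has one row per generated crystal, in stream order,
    recording the sampled parameters, the cell model (centering) and the
    shift-cluster membership (-1 marks a misindexed crystal).
    """
    out_path = Path(out_path)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames

    indexed = _exact_subset(rng, n, spec.indexed_fraction)
    idx_frames = np.nonzero(indexed)[0]
    multi = np.zeros(n, dtype=bool)
    if len(idx_frames):
        multi_sel = _exact_subset(rng, len(idx_frames), spec.multi_crystal_fraction)
        multi[idx_frames[multi_sel]] = True
    crystals_per_frame = np.where(indexed, np.where(multi, 2, 1), 0)
    total_crystals = int(crystals_per_frame.sum())
    misindexed = _exact_subset(rng, total_crystals, spec.misindexed_fraction)

    cell_weights = np.array([c.weight for c in spec.cells])
    cluster_weights = np.array([c.weight for c in spec.shift_clusters])

    truth_rows: list[dict] = []
    buf = io.StringIO()
    buf.write(_HEADER.format(energy=spec.photon_energy_eV))

    crystal_counter = 0
    for frame in range(n):
        run = spec.run_start + frame // spec.frames_per_run
        file_idx = frame // spec.events_per_file
        event = frame % spec.events_per_file
        filename = f"run{run:04d}_{file_idx}.cxi"
        num_peaks = int(rng.poisson(80)) + 3
        peak_res = max(0.8, rng.normal(spec.resolution_mean_A + 0.5, 0.3))

        buf.write("----- Begin chunk -----\n")
        buf.write(f"Image filename: {filename}\n")
        buf.write(f"Event: //{event}\n")
        buf.write(f"Image serial number: {frame + 1}\n")
        buf.write("hit = 1\n")
        buf.write(
            "indexed_by = mosflm-latt-nocell\n" if indexed[frame] else "indexed_by = none\n"
        )
        buf.write(f"photon_energy_eV = {spec.photon_energy_eV:.6f}\n")
        buf.write(f"num_peaks = {num_peaks}\n")
        buf.write(
            f"peak_resolution = {10.0 / peak_res:.6f} nm^-1 or {peak_res:.3f} A\n"
        )
        buf.write("Peaks from peak search\n")
        buf.write("  fs/px   ss/px (1/d)/nm   Intensity  Panel\n")
        buf.write(" 100.50  200.50     1.25      500.00  q0a0\n")
        buf.write(" 150.25  300.75     2.10      300.00  q1a1\n")
        buf.write("End of peak list\n")

        for _ in range(int(crystals_per_frame[frame])):
            is_mis = bool(misindexed[crystal_counter])
            model_i = int(rng.choice(len(spec.cells), p=cell_weights))
            model = spec.cells[model_i]
            if is_mis:
                mean = np.asarray(model.mean)
                axes = rng.uniform(0.75 * mean[:3], 1.25 * mean[:3])
                angles = rng.uniform(70.0, 110.0, size=3)
                cell = np.concatenate([axes, angles])
                sx = rng.uniform(-spec.misindexed_shift_range, spec.misindexed_shift_range)
                sy = rng.uniform(-spec.misindexed_shift_range, spec.misindexed_shift_range)
                cluster_i = -1
            else:
                cell = rng.normal(np.asarray(model.mean), np.asarray(model.sd))
                cluster_i = int(rng.choice(len(spec.shift_clusters), p=cluster_weights))
                cl = spec.shift_clusters[cluster_i]
                sx = rng.normal(cl.x, cl.sd)
                sy = rng.normal(cl.y, cl.sd)
            res = max(0.8, rng.normal(spec.resolution_mean_A, spec.resolution_sd_A))
            n_refl = int(rng.poisson(900)) + 10
            n_sat = int(rng.poisson(0.5))
            n_impl = int(rng.poisson(1.0))

            buf.write("--- Begin crystal\n")
            buf.write(
                "Cell parameters {:.5f} {:.5f} {:.5f} nm, {:.5f} {:.5f} {:.5f} deg\n".format(
                    cell[0] / 10.0, cell[1] / 10.0, cell[2] / 10.0,
                    cell[3], cell[4], cell[5],
                )
            )
            buf.write("astar = +0.1626016 +0.0000000 +0.0000000 nm^-1\n")
            buf.write("bstar = +0.0000000 +0.0816993 +0.0000000 nm^-1\n")
            buf.write("cstar = +0.0000000 +0.0000000 +0.0623053 nm^-1\n")
            buf.write(f"lattice_type = {model.lattice_type}\n")
            buf.write(f"centering = {model.centering}\n")
            buf.write(f"unique_axis = {model.unique_axis}\n")
            buf.write("profile_radius = 0.00123 nm^-1\n")
            buf.write(
                f"predict_refine/det_shift x = {sx:.6f} y = {sy:.6f} mm\n"
            )
            buf.write(
                f"diffraction_resolution_limit = {10.0 / res:.6f} nm^-1 or {res:.3f} A\n"
            )
            buf.write(f"num_reflections = {n_refl}\n")
            buf.write(f"num_saturated_reflections = {n_sat}\n")
            buf.write(f"num_implausible_reflections = {n_impl}\n")
            buf.write("Reflections measured after indexing\n")
            buf.write("   h    k    l          I   sigma(I)       peak background  fs/px  ss/px panel\n")
            buf.write("   1    2    3     100.00      10.00     110.00      5.00  100.0  200.0 q0a0\n")
            buf.write("End of reflections\n")
            buf.write("--- End crystal\n")

            truth_rows.append(
                dict(
                    frame=frame, filename=filename, event=event, run=run,
                    crystal_index=crystal_counter,
                    correct=0 if is_mis else 1,
                    cell_model=model.centering,
                    shift_cluster=cluster_i,
                    a=cell[0], b=cell[1], c=cell[2],
                    alpha=cell[3], beta=cell[4], gamma=cell[5],
                    det_shift_x=sx, det_shift_y=sy,
                    resolution_limit_A=res,
                )
            )
            crystal_counter += 1
        buf.write("----- End chunk -----\n")

    out_path.write_text(buf.getvalue(), encoding="utf-8")

    names = [f.name for f in _TRUTH_FIELDS]
    if truth_rows:
        df = pd.DataFrame(truth_rows, columns=names)
    else:
        df = pd.DataFrame({f.name: pd.Series(dtype=float) for f in _TRUTH_FIELDS})
    for f in _TRUTH_FIELDS:
        if f.dtype == "integer":
            df[f.name] = df[f.name].astype(np.int64)
        elif f.dtype == "real":
            df[f.name] = df[f.name].astype(np.float64)
        else:
            df[f.name] = df[f.name].astype(object)
    truth = ParameterTable(df, _TRUTH_FIELDS, provenance=[str(out_path)] * len(df))
    return out_path, truth


def generate_comparison_fixture(
    n_groups: int = 2,
    n_frames: int = 3,
    missing_prob: float = 0.2,
    absent_prob: float = 0.0,
    multi_crystal_prob: float = 0.0,
    base_value: float = 1000.0,
    jitter: float = 10.0,
    seed: int = 0,
) -> tuple[list[ParameterTable], pd.DataFrame]:
    """Parameter tables of the same frames "processed" several ways.

    Emulates a multi-way re-indexing comparison: every group covers the
    same frame keys, but per group a frame's value may be missing (NaN,
    probability ``missing_prob``), its row may be absent entirely
    (``absent_prob``), or duplicated as a second crystal
    (``multi_crystal_prob``).  Returns the tables plus a tidy truth frame
    (one record per generated row) from which class-wise expectations can
    be computed exactly.
    """
    if n_groups < 2:
        raise ValueError("need at least two groups")
    rng = np.random.default_rng(seed)
    fields = [
        FieldSpec("filename", "text"),
        FieldSpec("event", "integer"),
        FieldSpec("volume", "real", units="A^3"),
        FieldSpec("resolution_limit_A", "real", units="A"),
        FieldSpec("centering", "categorical"),
        FieldSpec("flag", "flag"),
    ]
    frame_values = base_value + rng.normal(0.0, jitter, size=n_frames)
    tables: list[ParameterTable] = []
    truth_records: list[dict] = []
    for g in range(n_groups):
        rows: list[dict] = []
        for f in range(n_frames):
            if rng.random() < absent_prob:
                continue
            n_cryst = 2 if rng.random() < multi_crystal_prob else 1
            for k in range(n_cryst):
                if rng.random() < missing_prob:
                    value = float("nan")
                else:
                    value = float(frame_values[f] + rng.normal(0.0, jitter / 2))
                row = dict(
                    filename=f"frame_{f // 10}.cxi",
                    event=f % 10,
                    volume=value,
                    resolution_limit_A=float(
                        np.round(max(0.8, 2.5 + rng.normal(0, 0.2)), 2)
                    ),
                    centering="C",
                    flag=False,
                )
                rows.append(row)
                truth_records.append(dict(group=g, frame=f, crystal=k, **row))
        df = pd.DataFrame(rows, columns=[fs.name for fs in fields])
        if rows:
            df["event"] = df["event"].astype(np.int64)
            df["flag"] = df["flag"].astype(bool)
        else:
            df = pd.DataFrame(
                {
                    "filename": pd.Series(dtype=object),
                    "event": pd.Series(dtype=np.int64),
                    "volume": pd.Series(dtype=float),
                    "resolution_limit_A": pd.Series(dtype=float),
                    "centering": pd.Series(dtype=object),
                    "flag": pd.Series(dtype=bool),
                }
            )
        tables.append(ParameterTable(df, fields, provenance=[f"group{g}"] * len(df)))
    truth = pd.DataFrame(truth_records)
    return tables, truth
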