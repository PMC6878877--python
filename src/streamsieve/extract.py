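"""Build a parameter table from stream files (the ``gen`` step).

One row per crystal; frames that failed indexing get one row with crystal
fields at their missing sentinels, so hit-rate style histograms and the
"no centering" category exist.  Frame-level fields are repeated on every
crystal row of a multi-crystal frame, mirroring the stream-export
convention.  Byte-span columns make the table an index back into the
stream file, enabling bit-exact subset extraction later.

Optionally harvests per-event scalar datasets from the HDF5/CXI image
files (timestamps, pulse energies, ...) into extra columns.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dat_table import ConfigSpec, FieldSpec, ParameterTable, concat_tables
from .stream_io import scan_stream

__all__ = [
    "ExtractionSpec",
    "build_table",
    "cell_volume",
    "extract_hdf5_scalar",
    "run_number_from_path",
    "default_config",
    "CRYSTAL_FIELDS",
]

logger = logging.getLogger(__name__)

#: Canonical column specs of a generated table, in order.
_BASE_FIELDS = [
    FieldSpec("source", "text"),
    FieldSpec("chunk_start", "integer"),
    FieldSpec("chunk_end", "integer"),
    FieldSpec("peaks_start", "integer"),
    FieldSpec("peaks_end", "integer"),
    FieldSpec("filename", "text"),
    FieldSpec("event", "integer"),
    FieldSpec("serial", "integer"),
    FieldSpec("indexed_by", "categorical"),
    FieldSpec("num_peaks", "integer"),
    FieldSpec("peak_resolution_A", "real", units="A"),
    FieldSpec("crystal_start", "integer"),
    FieldSpec("crystal_end", "integer"),
    FieldSpec("refl_start", "integer"),
    FieldSpec("refl_end", "integer"),
    FieldSpec("a", "real", units="A"),
    FieldSpec("b", "real", units="A"),
    FieldSpec("c", "real", units="A"),
    FieldSpec("alpha", "real", units="deg"),
    FieldSpec("beta", "real", units="deg"),
    FieldSpec("gamma", "real", units="deg"),
    FieldSpec("lattice_type", "categorical"),
    FieldSpec("centering", "categorical"),
    FieldSpec("unique_axis", "categorical"),
    FieldSpec("det_shift_x", "real", units="mm"),
    FieldSpec("det_shift_y", "real", units="mm"),
    FieldSpec("resolution_limit_A", "real", units="A"),
    FieldSpec("num_reflections", "integer"),
    FieldSpec("num_saturated_reflections", "integer"),
    FieldSpec("num_implausible_reflections", "integer"),
    FieldSpec("volume", "real", units="A^3"),
    FieldSpec("run", "integer"),
    FieldSpec("flag", "flag"),
]

#: Columns that describe the crystal (missing-sentinel on unindexed rows).
CRYSTAL_FIELDS = (
    "crystal_start", "crystal_end", "refl_start", "refl_end",
    "a", "b", "c", "alpha", "beta", "gamma",
    "lattice_type", "centering", "unique_axis",
    "det_shift_x", "det_shift_y", "resolution_limit_A",
    "num_reflections", "num_saturated_reflections",
    "num_implausible_reflections", "volume",
)


def default_config() -> ConfigSpec:
    """Typings of the canonical generated columns, for re-reading ``.dat``."""
    return ConfigSpec(fields={f.name: f for f in _BASE_FIELDS})


@dataclass
class ExtractionSpec:
    """What to extract: streams, optional HDF5 scalars, run-number rule."""

    stream_paths: Sequence[str]
    hdf5_fields: Sequence[str] = ()
    run_pattern: Optional[str] = None
    config: Optional[ConfigSpec] = None
    indexed_only: bool = False

    def __post_init__(self) -> None:
        if self.run_pattern is not None:
            if re.compile(self.run_pattern).groups != 1:
                raise ValueError("run_pattern must have exactly one capture group")


def cell_volume(a: float, b: float, c: float,
                alpha: float, beta: float, gamma: float) -> float:
    """Triclinic unit-cell volume in cubic Angstrom.

    V = abc * sqrt(1 - cos^2(alpha) - cos^2(beta) - cos^2(gamma)
                   + 2 cos(alpha) cos(beta) cos(gamma))

    Symmetric under any simultaneous permutation of (a, alpha), (b, beta),
    (c, gamma).  Raises for geometrically impossible cells.
    """
    if min(a, b, c) <= 0:
        raise ValueError("cell axes must be positive")
    if not all(0 < x < 180 for x in (alpha, beta, gamma)):
        raise ValueError("cell angles must lie in (0, 180) degrees")
    ca, cb, cg = (math.cos(math.radians(x)) for x in (alpha, beta, gamma))
    disc = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if disc <= 0:
        raise ValueError(f"impossible cell: discriminant {disc} <= 0")
    return a * b * c * math.sqrt(disc)


def _cell_volume_array(a, b, c, alpha, beta, gamma) -> np.ndarray:
    ca, cb, cg = (np.cos(np.radians(x)) for x in (alpha, beta, gamma))
    disc = 1.0 - ca**2 - cb**2 - cg**2 + 2.0 * ca * cb * cg
    with np.errstate(invalid="ignore"):
        vol = a * b * c * np.sqrt(np.where(disc > 0, disc, np.nan))
    return vol


def run_number_from_path(path: str, pattern: Optional[str]) -> int:
    """Extract the run number embedded in a file name; -1 when absent."""
    if pattern is None:
        return -1
    m = re.search(pattern, str(path))
    if m is None:
        return -1
    try:
        return int(m.group(1))
    except (ValueError, IndexError):
        return -1


def extract_hdf5_scalar(
    file_path: str | Path, dataset: str, event: Optional[int] = None
) -> Optional[float]:
    """Read one scalar from an HDF5/CXI file, per event when given.

    Scalar dataset -> its value; 1-D dataset with an event index -> that
    element.  Any failure (missing file or dataset, out-of-range event,
    wrong shape) logs a warning and returns None so table building never
    aborts on one bad frame.
    """
    import h5py

    try:
        with h5py.File(file_path, "r") as fh:
            if dataset not in fh:
                logger.warning("%s: dataset %s absent", file_path, dataset)
                return None
            ds = fh[dataset]
            if ds.shape == ():
                return float(ds[()])
            if ds.ndim == 1 and event is not None:
                if not (0 <= event < ds.shape[0]):
                    logger.warning(
                        "%s: event %d out of bounds for %s (len %d)",
                        file_path, event, dataset, ds.shape[0],
                    )
                    return None
                return float(ds[event])
            logger.warning(
                "%s: dataset %s has shape %s, need scalar or 1-D with event",
                file_path, dataset, ds.shape,
            )
    except OSError as exc:
        logger.warning("%s: %s", file_path, exc)
    return None


_MISSING = {
    "real": float("nan"),
    "integer": -1,
    "categorical": "none",
    "text": "-",
    "flag": False,
}


def _hdf5_column_name(dataset: str) -> str:
    return dataset.strip("/").replace("/", "_")


def build_table(spec: ExtractionSpec) -> ParameterTable:
    """Scan the streams of *spec* into one typed parameter table."""
    per_stream = [_build_one(spec, p) for p in spec.stream_paths]
    if len(per_stream) == 1:
        return per_stream[0]
    return concat_tables(per_stream)


def _build_one(spec: ExtractionSpec, stream_path: str) -> ParameterTable:
    chunks, _header = scan_stream(stream_path)
    fields = list(_BASE_FIELDS) + [
        FieldSpec(_hdf5_column_name(d), "real") for d in spec.hdf5_fields
    ]
    rows: dict[str, list] = {f.name: [] for f in fields}

    def put(name: str, value, dtype: str) -> None:
        rows[name].append(_MISSING[dtype] if value is None else value)

    stream_dir = Path(stream_path).parent
    for chunk in chunks:
        crystals = chunk.crystals
        if not crystals:
            if spec.indexed_only:
                continue
            crystals = [None]
        run = run_number_from_path(chunk.filename or "", spec.run_pattern)
        for cryst in crystals:
            put("source", stream_path, "text")
            put("chunk_start", chunk.chunk_span.start, "integer")
            put("chunk_end", chunk.chunk_span.end, "integer")
            put("peaks_start", chunk.peaks_span.start if chunk.peaks_span else None, "integer")
            put("peaks_end", chunk.peaks_span.end if chunk.peaks_span else None, "integer")
            put("filename", chunk.filename, "text")
            put("event", chunk.event, "integer")
            put("serial", chunk.serial, "integer")
            put("indexed_by", chunk.indexed_by, "categorical")
            put("num_peaks", chunk.num_peaks, "integer")
            put("peak_resolution_A", chunk.peak_resolution_A, "real")
            if cryst is None:
                for name in CRYSTAL_FIELDS:
                    dtype = next(f.dtype for f in _BASE_FIELDS if f.name == name)
                    put(name, None, dtype)
            else:
                put("crystal_start", cryst.crystal_span.start, "integer")
                put("crystal_end", cryst.crystal_span.end, "integer")
                put("refl_start", cryst.reflections_span.start if cryst.reflections_span else None, "integer")
                put("refl_end", cryst.reflections_span.end if cryst.reflections_span else None, "integer")
                put("a", cryst.a, "real")
                put("b", cryst.b, "real")
                put("c", cryst.c, "real")
                put("alpha", cryst.alpha, "real")
                put("beta", cryst.beta, "real")
                put("gamma", cryst.gamma, "real")
                put("lattice_type", cryst.lattice_type, "categorical")
                put("centering", cryst.centering, "categorical")
                put("unique_axis", cryst.unique_axis, "categorical")
                put("det_shift_x", cryst.det_shift_x, "real")
                put("det_shift_y", cryst.det_shift_y, "real")
                put("resolution_limit_A", cryst.resolution_limit_A, "real")
                put("num_reflections", cryst.num_reflections, "integer")
                put("num_saturated_reflections", cryst.num_saturated_reflections, "integer")
                put("num_implausible_reflections", cryst.num_implausible_reflections, "integer")
                put("volume", None, "real")  # filled vectorized below
            put("run", run if run >= 0 else None, "integer")
            put("flag", False, "flag")
            for dataset in spec.hdf5_fields:
                value = None
                if chunk.filename:
                    img = Path(chunk.filename)
                    if not img.is_absolute() and not img.exists():
                        img = stream_dir / img
                    if img.exists():
                        value = extract_hdf5_scalar(img, dataset, chunk.event)
                    else:
                        logger.warning("image file %s not found", chunk.filename)
                put(_hdf5_column_name(dataset), value, "real")

    df = pd.DataFrame(
        {f.name: np.asarray(rows[f.name], dtype=_PANDAS[f.dtype]) for f in fields},
        columns=[f.name for f in fields],
    )
    df["volume"] = _cell_volume_array(
        df["a"].to_numpy(), df["b"].to_numpy(), df["c"].to_numpy(),
        df["alpha"].to_numpy(), df["beta"].to_numpy(), df["gamma"].to_numpy(),
    )
    return ParameterTable(df, fields, provenance=[stream_path] * len(df))


_PANDAS = {
    "integer": np.int64,
    "real": np.float64,
    "categorical": object,
    "text": object,
    "flag": bool,
}
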