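from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from streamsieve.dat_table import FieldSpec, ParameterTable
from streamsieve.extract import ExtractionSpec, build_table
from streamsieve.synth import StreamSynthSpec, generate_stream


@pytest.fixture(scope="session")
def mixed_stream(tmp_path_factory):
    """A small stream with unindexed, single- and multi-crystal frames."""
    out = tmp_path_factory.mktemp("streams") / "mixed.stream"
    spec = StreamSynthSpec(
        n_frames=40,
        indexed_fraction=0.6,
        multi_crystal_fraction=0.25,
        misindexed_fraction=0.2,
        seed=7,
    )
    path, truth = generate_stream(spec, out)
    return path, truth, spec


@pytest.fixture(scope="session")
def mixed_table(mixed_stream):
    path, _truth, _spec = mixed_stream
    return build_table(ExtractionSpec([str(path)], run_pattern=r"run(\d+)"))


def make_random_table(rng: np.random.Generator, n_rows: int) -> ParameterTable:
    """Random typed table: two reals, one integer, one categorical, flag.

    Numeric columns carry their missing sentinels with ~15% probability.
    """
    fields = [
        FieldSpec("x", "real"),
        FieldSpec("y", "real"),
        FieldSpec("k", "integer"),
        FieldSpec("cat", "categorical"),
        FieldSpec("flag", "flag"),
    ]
    x = rng.uniform(0, 10, n_rows)
    x[rng.random(n_rows) < 0.15] = np.nan
    y = rng.normal(5, 3, n_rows)
    y[rng.random(n_rows) < 0.15] = np.nan
    k = rng.integers(0, 10, n_rows)
    k[rng.random(n_rows) < 0.15] = -1
    cat = rng.choice(np.array(["C", "P", "I", "none"], dtype=object), n_rows)
    flag = rng.random(n_rows) < 0.2
    df = pd.DataFrame(
        {"x": x, "y": y, "k": k.astype(np.int64), "cat": cat, "flag": flag}
    )
    return ParameterTable(df, fields)
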