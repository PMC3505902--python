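"""Shared fixtures: a small synthetic library run through the pipeline once."""

from __future__ import annotations

import pandas as pd
import pytest

import abcc2pred as a


@pytest.fixture(scope="session")
def library() -> a.SyntheticLibrary:
    """Small seeded library with the default dirty-record complement."""
    return a.generate_library(a.SimulationConfig(n_compounds=150, seed=11))


@pytest.fixture(scope="session")
def curated(library):
    ds, report = a.run_curation(list(library.records))
    return ds, report


@pytest.fixture(scope="session")
def labeled(curated) -> a.Dataset:
    ds, _ = curated
    return a.label_by_pcc(ds, a.LabelRule(-0.25))


@pytest.fixture(scope="session")
def zmatrix(labeled):
    matrix = a.compute_matrix(labeled.records)
    zm, params = a.zscore(matrix)
    return zm, params


@pytest.fixture(scope="session")
def labels_series(labeled) -> pd.Series:
    return pd.Series(labeled.labels, index=labeled.ids)
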