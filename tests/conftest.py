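import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nichevar.resource_data import ExperimentDesign, SampleRecord

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def design_2x2() -> ExperimentDesign:
    """Eight tanks, two per treatment cell."""
    factors = {}
    for i, (c, p) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)] * 2):
        factors[f"T{i + 1}"] = (c, p)
    return ExperimentDesign(factors)


@pytest.fixture
def simple_records() -> list[SampleRecord]:
    """One tank, two fish, two sessions; totals: A=4 (3 chironomid,
    1 ostracod), B=2 ostracod."""
    return [
        SampleRecord("T1", "A", "s1", "chironomid", 2),
        SampleRecord("T1", "A", "s2", "chironomid", 1),
        SampleRecord("T1", "A", "s2", "ostracod", 1),
        SampleRecord("T1", "B", "s1", "ostracod", 2),
    ]


def _toy_compositions() -> pd.DataFrame:
    """13 unbalanced samples of 5-part compositions with group effects.

    Deterministic (fixed generator seed); shared by the tests that
    compare against frozen reference values from vegan (adonis2
    by="terms", betadisper type="centroid", simper), computed once on
    this exact table.
    """
    rng = np.random.default_rng(42)
    n = 16
    comp = np.repeat([0, 0, 1, 1], 4)
    pred = np.tile([0, 0, 1, 1], 4)
    keep = np.ones(n, bool)
    keep[[1, 6, 11]] = False
    x = rng.dirichlet([2, 2, 2, 2, 2], size=n) + 0.08 * np.column_stack(
        [comp, -comp, pred, -pred, comp * pred]
    )
    x = np.clip(x, 1e-6, None)
    x = x / x.sum(1, keepdims=True)
    frame = pd.DataFrame(
        x[keep], columns=list("abcde"),
        index=[f"s{i}" for i in range(keep.sum())],
    )
    frame.attrs["comp"] = comp[keep]
    frame.attrs["pred"] = pred[keep]
    return frame


@pytest.fixture(scope="session")
def toy_compositions() -> pd.DataFrame:
    return _toy_compositions()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_count_matrix(
    rng: np.random.Generator,
    n_ind_range=(3, 10),
    n_cat_range=(2, 14),
    mean_count: float = 2.0,
) -> np.ndarray:
    """Random valid count matrix: no zero rows or columns."""
    while True:
        n = int(rng.integers(*n_ind_range, endpoint=True))
        k = int(rng.integers(*n_cat_range, endpoint=True))
        m = rng.poisson(mean_count, size=(n, k)).astype(float)
        if (m.sum(axis=1) > 0).all() and (m.sum(axis=0) > 0).all():
            return m
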