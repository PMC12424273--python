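"""Monte Carlo null model for the specialisation index.

The null hypothesis is a population of stochastic generalists: every
individual samples resources independently in proportion to their use
by the population as a whole. Each replicate redraws every individual's
counts as a multinomial of its observed size with the pooled population
proportions, so sampling effort per individual is preserved exactly.
The observed 1 - WIC/TNW is compared one-sidedly against the replicate
distribution; significance indicates more among-individual diet or
habitat heterogeneity than finite multinomial sampling alone produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from nichevar.niche import DegenerateNicheError, decompose
from nichevar.resource_data import ResourceUseMatrix, ValidationError

__all__ = ["NullResult", "resample_population", "monte_carlo_test"]

# replicates whose index is undefined (single-category draw) are redrawn;
# give up after this many multiples of n_reps
_REDRAW_CAP = 20


@dataclass(frozen=True)
class NullResult:
    """Observed index, null replicate indices, and the one-sided p-value."""

    observed_index: float
    null_indices: np.ndarray
    p_value: float
    n_reps: int
    seed: int | None

    @property
    def significant(self) -> bool:
        return self.p_value <= 0.05


def _as_counts(matrix) -> np.ndarray:
    counts = (
        matrix.counts if isinstance(matrix, ResourceUseMatrix)
        else np.asarray(matrix, dtype=float)
    )
    if (counts.sum(axis=1) == 0).any():
        raise ValidationError("zero row sum; filter empty individuals first")
    # never-used categories carry q = 0 and no information: drop them
    return counts[:, counts.sum(axis=0) > 0]


def _draw(counts: np.ndarray, q: np.ndarray, n: int, rng) -> np.ndarray:
    """n replicate matrices, each row multinomial(row_sum, q): (n, i, j)."""
    sizes = counts.sum(axis=1).astype(int)
    reps = np.empty((n, *counts.shape), dtype=np.int64)
    for i, s in enumerate(sizes):
        reps[:, i, :] = rng.multinomial(s, q, size=n)
    return reps


def _indices(reps: np.ndarray) -> np.ndarray:
    """1 - WIC/TNW for a stack of count matrices; NaN where TNW = 0."""
    reps = reps.astype(float)
    row = reps.sum(axis=2)                      # (n, i)
    total = row.sum(axis=1)                     # (n,)
    p_ij = reps / row[:, :, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        h_rows = -np.where(p_ij > 0, p_ij * np.log(p_ij), 0.0).sum(axis=2)
    wic = (row / total[:, None] * h_rows).sum(axis=1)
    q = reps.sum(axis=1) / total[:, None]       # (n, j)
    with np.errstate(divide="ignore", invalid="ignore"):
        tnw = -np.where(q > 0, q * np.log(q), 0.0).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(tnw > 0, 1.0 - wic / tnw, np.nan)


def resample_population(matrix, rng: np.random.Generator) -> ResourceUseMatrix:
    """One stochastic-generalist resample of a population.

    Each individual's row is redrawn as a multinomial of its observed
    row sum with the pooled population proportions ``q``; row sums are
    preserved exactly.
    """
    counts = _as_counts(matrix)
    q = counts.sum(axis=0) / counts.sum()
    new = _draw(counts, q, 1, rng)[0].astype(float)
    if isinstance(matrix, ResourceUseMatrix):
        kept = matrix.counts.sum(axis=0) > 0
        categories = [c for c, k in zip(matrix.categories, kept) if k]
        return ResourceUseMatrix(
            new, list(matrix.individuals), categories,
            matrix.tank_id, matrix.niche_kind,
        )
    return ResourceUseMatrix(
        new,
        [f"ind{i}" for i in range(new.shape[0])],
        [f"cat{j}" for j in range(new.shape[1])],
        tank_id="resampled",
    )


def monte_carlo_test(
    matrix, n_reps: int = 999, seed: int | np.random.Generator | None = None
) -> NullResult:
    """One-sided Monte Carlo test of 1 - WIC/TNW against the generalist null.

    ``p = (1 + #{null >= observed}) / (n_reps + 1)`` (add-one
    convention, so p is never 0). Replicates with an undefined index
    (all items in one category) are redrawn up to a cap; persistent
    degeneracy raises.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    counts = _as_counts(matrix)
    observed = decompose(counts).is_index
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    q = counts.sum(axis=0) / counts.sum()
    null = _indices(_draw(counts, q, n_reps, rng))
    tries = 0
    while np.isnan(null).any():
        tries += 1
        if tries > _REDRAW_CAP:
            raise DegenerateNicheError(
                "persistent degenerate null replicates (TNW = 0); the "
                "population is too concentrated for the Monte Carlo null"
            )
        bad = np.flatnonzero(np.isnan(null))
        warnings.warn(
            f"redrawing {bad.size} degenerate null replicate(s)",
            stacklevel=2,
        )
        null[bad] = _indices(_draw(counts, q, bad.size, rng))
    p = (1.0 + (null >= observed).sum()) / (n_reps + 1.0)
    return NullResult(
        observed_index=observed,
        null_indices=null,
        p_value=float(p),
        n_reps=n_reps,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )
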