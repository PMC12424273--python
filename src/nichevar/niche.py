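"""Shannon decomposition of total niche width and the 1 - WIC/TNW index.

The total niche width (TNW) of a population is the Shannon entropy of
its pooled resource-use proportions. It partitions additively into a
within-individual component (WIC) — the count-weighted average Shannon
breadth of the individuals — and a between-individual component
(BIC = TNW - WIC), the mutual information between individual identity
and resource category. The specialisation index 1 - WIC/TNW is 0 when
all individuals are identical generalists and 1 when they use fully
disjoint category sets.

Notation, with ``n_ij`` the count of individual *i* in category *j* and
``N`` the grand total:

* ``p_ij = n_ij / n_i.`` — proportion of individual *i*'s use in *j*;
* ``p_i. = n_i. / N``   — individual *i*'s share of the population total;
* ``q_j  = n_.j / N``   — population proportion of category *j*;
* ``gamma_ij = n_ij / n_.j`` — individual *i*'s share of the population's
  use of *j*.

Then ``WIC = sum_i p_i. * H(p_i,:)``, ``TNW = H(q)``, and
``BIC = H(p_.) - sum_j q_j * H(gamma_:,j)``, all in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nichevar.resource_data import ResourceUseMatrix, ValidationError

__all__ = [
    "DegenerateNicheError",
    "ProportionSet",
    "NicheComponents",
    "shannon_entropy",
    "proportions",
    "decompose",
    "is_index",
]


class DegenerateNicheError(ValueError):
    """The index 1 - WIC/TNW is undefined (single-category population)."""


@dataclass(frozen=True)
class ProportionSet:
    """The four proportion arrays underlying the decomposition."""

    p_ij: np.ndarray
    p_i_dot: np.ndarray
    q_j: np.ndarray
    gamma_ij: np.ndarray


@dataclass(frozen=True)
class NicheComponents:
    """WIC, BIC and TNW in nats, plus the 1 - WIC/TNW index."""

    wic: float
    bic: float
    tnw: float
    is_index: float
    n_individuals: int = 0
    n_categories: int = 0


def _entropy(p: np.ndarray, axis: int | None = None) -> np.ndarray | float:
    # -sum p ln p with 0 ln 0 := 0
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    return -terms.sum(axis=axis)


def shannon_entropy(p, atol: float = 1e-9) -> float:
    """Shannon entropy (nats) of a probability vector.

    Entries must be non-negative and sum to 1 within ``atol``;
    ``0 * ln 0`` is taken as 0.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValidationError("negative entry in proportion vector")
    if abs(p.sum() - 1.0) > atol:
        raise ValidationError(
            f"proportions sum to {p.sum():.12g}, not 1 (tolerance {atol})"
        )
    return float(_entropy(p))


def proportions(matrix: ResourceUseMatrix | np.ndarray) -> ProportionSet:
    """Compute all four proportion arrays from a count matrix.

    Requires every row and column to have a positive sum; callers with
    raw matrices should use ``drop_empty_individuals`` / ``filter_tanks``
    first.
    """
    counts = (
        matrix.counts if isinstance(matrix, ResourceUseMatrix)
        else np.asarray(matrix, dtype=float)
    )
    if counts.ndim != 2 or counts.shape[0] < 1:
        raise ValidationError("need a 2-D count matrix with at least one row")
    if (counts < 0).any():
        raise ValidationError("negative count")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValidationError(
            "zero row or column sum; filter empty individuals/categories first"
        )
    total = counts.sum()
    return ProportionSet(
        p_ij=counts / row[:, None],
        p_i_dot=row / total,
        q_j=col / total,
        gamma_ij=counts / col[None, :],
    )


def decompose(matrix: ResourceUseMatrix | np.ndarray) -> NicheComponents:
    """Partition a population's niche width into WIC + BIC = TNW.

    WIC weights each individual's Shannon breadth by its share of the
    population's total use, so heavily sampled individuals contribute
    more. BIC is computed from the individual-identity side of the
    mutual information, ``H(p_.) - sum_j q_j H(gamma_:,j)``; additivity
    with TNW - WIC is exact up to floating point and is enforced as an
    invariant in the test suite rather than by construction.

    Raises :class:`DegenerateNicheError` when TNW = 0 (every item in a
    single category), where the index is undefined.
    """
    pr = proportions(matrix)
    wic = float(pr.p_i_dot @ _entropy(pr.p_ij, axis=1))
    tnw = float(_entropy(pr.q_j))
    bic = float(_entropy(pr.p_i_dot) - pr.q_j @ _entropy(pr.gamma_ij, axis=0))
    if tnw == 0.0:
        raise DegenerateNicheError(
            "TNW = 0 (single resource category): 1 - WIC/TNW is undefined"
        )
    index = 1.0 - wic / tnw
    n, k = pr.p_ij.shape
    return NicheComponents(
        wic=wic, bic=bic, tnw=tnw, is_index=index,
        n_individuals=n, n_categories=k,
    )


def is_index(components: NicheComponents) -> float:
    """The specialisation index 1 - WIC/TNW of a decomposition."""
    if components.tnw <= 0:
        raise DegenerateNicheError("TNW = 0: 1 - WIC/TNW is undefined")
    return 1.0 - components.wic / components.tnw
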