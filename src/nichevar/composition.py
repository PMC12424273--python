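"""Tank-level composition statistics on Bray-Curtis dissimilarities.

Treatment effects on *where the population niche sits* (as opposed to
how it is partitioned among individuals) are assessed on the tank mean
compositions: Bray-Curtis dissimilarities among tanks, a two-way
PERMANOVA with interaction (sequential sums of squares on the
Gower-centred inner-product matrix, significance by free permutation of
tank labels), a betadisper-style test of homogeneity of multivariate
dispersion, SIMPER decomposition of between-group dissimilarity into
per-category contributions, and non-metric multidimensional scaling for
visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis, pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from nichevar.resource_data import ExperimentDesign, ValidationError

__all__ = [
    "bray_curtis",
    "pairwise_bray_curtis",
    "permanova",
    "permanova_two_way",
    "DispersionResult",
    "dispersion_homogeneity",
    "simper",
    "OrdinationResult",
    "stress1",
    "nmds",
]


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors differ in length")
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("negative abundance")
    if x.sum() + y.sum() == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(braycurtis(x, y))


def pairwise_bray_curtis(compositions: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Bray-Curtis distance matrix among rows (labelled)."""
    comps = compositions.astype(float)
    if (comps.sum(axis=1) == 0).any():
        raise ValidationError("all-zero composition row")
    dist = squareform(pdist(comps.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(dist, index=comps.index, columns=comps.index)


def _check_distance_matrix(dist: pd.DataFrame) -> np.ndarray:
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValidationError("distance matrix must have a zero diagonal")
    return d


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # projection onto col(x); pinv handles rank-deficient dummy codings
    return x @ np.linalg.pinv(x)


def _dummy(values: np.ndarray) -> np.ndarray:
    levels = pd.unique(values)
    return (values[:, None] == levels[None, :]).astype(float)


def _term_columns(term: str, factors: pd.DataFrame) -> np.ndarray:
    """Full dummy coding for a factor or an `a:b` interaction term."""
    parts = term.split(":")
    cols = _dummy(factors[parts[0]].to_numpy())
    for p in parts[1:]:
        d = _dummy(factors[p].to_numpy())
        cols = np.einsum("ij,ik->ijk", cols, d).reshape(len(factors), -1)
    return cols


def permanova(
    dist: pd.DataFrame,
    factors: pd.DataFrame,
    terms: Sequence[str],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Sequential (Type I) PERMANOVA on a distance matrix.

    Squared dissimilarities are partitioned among model terms via the
    Gower-centred inner-product matrix G: the sum of squares of a term
    is tr((H_m - H_{m-1}) G) for the hat matrices H of the nested
    sequence of design matrices, entered in the order given. Pseudo-F
    per term uses the residual mean square of the full model, and
    significance comes from free permutation of the sample labels
    (add-one convention). R-squared is SS_term / SS_total.

    ``factors`` rows must align with ``dist``; ``terms`` entries are
    column names or ``"a:b"`` interactions. With ``exhaustive=True``
    (small n only) every permutation is enumerated and p is the exact
    proportion of permutations with F >= F_observed (the identity
    permutation always counts, so p > 0).
    """
    d = _check_distance_matrix(dist)
    n = d.shape[0]
    if isinstance(dist, pd.DataFrame):
        if list(factors.index) != list(dist.index):
            factors = factors.loc[dist.index]
    if len(factors) != n:
        raise ValidationError("factors do not cover all samples")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    g = _gower_center(d)
    ss_total = float(np.trace(g))
    if ss_total <= 1e-12:
        raise ValidationError("constant distance matrix: nothing to partition")

    # nested hat matrices: intercept, then cumulative terms
    x = np.ones((n, 1))
    hats = [_hat(x)]
    dfs: list[int] = []
    for term in terms:
        x = np.hstack([x, _term_columns(term, factors)])
        h = _hat(x)
        dfs.append(int(round(np.trace(h) - np.trace(hats[-1]))))
        hats.append(h)
    h_full = hats[-1]
    df_resid = n - int(round(np.trace(h_full)))
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")
    # per-term projection differences; residual projector
    diffs = [hats[i + 1] - hats[i] for i in range(len(terms))]
    resid_proj = np.eye(n) - h_full

    def term_ss(gmat: np.ndarray) -> np.ndarray:
        return np.array([float(np.sum(dh * gmat)) for dh in diffs])

    # residual SS can be a tiny negative number for perfectly separated
    # groups; clamp so the pseudo-F degenerates to +inf, not -inf
    ss_eps = 1e-12 * ss_total

    def f_stats(ss_terms: np.ndarray, ssr: float) -> np.ndarray:
        msr = (0.0 if ssr < ss_eps else ssr) / df_resid
        with np.errstate(divide="ignore", invalid="ignore"):
            return (ss_terms / np.array(dfs)) / msr

    ss = term_ss(g)
    ss_resid = float(np.sum(resid_proj * g))
    ms_resid = max(ss_resid, 0.0) / df_resid
    f_obs = f_stats(ss, ss_resid)

    def perm_f(perm) -> np.ndarray:
        gp = g[np.ix_(perm, perm)]
        return f_stats(term_ss(gp), float(np.sum(resid_proj * gp)))

    # F comparisons tolerate rounding so equivalent relabellings tie
    finite = np.abs(f_obs[np.isfinite(f_obs)])
    ftol = 1e-9 * max(1.0, float(finite.max()) if finite.size else 1.0)
    if exhaustive:
        from itertools import permutations as _perms

        if n > 9:
            raise ValidationError("exhaustive enumeration limited to n <= 9")
        exceed = np.zeros(len(terms))
        total = 0
        for perm in _perms(range(n)):
            exceed += perm_f(np.asarray(perm)) >= f_obs - ftol
            total += 1
        pvals = exceed / total
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        exceed = np.zeros(len(terms))
        for _ in range(n_perm):
            exceed += perm_f(rng.permutation(n)) >= f_obs - ftol
        pvals = (1.0 + exceed) / (n_perm + 1.0)

    rows = list(zip(terms, dfs, ss, ss / ss_total, f_obs, pvals))
    table = pd.DataFrame(
        rows, columns=["term", "df", "ss", "r2", "pseudo_f", "p"]
    ).set_index("term")
    table.loc["residual"] = [df_resid, ss_resid, ss_resid / ss_total, np.nan, np.nan]
    table.loc["total"] = [n - 1, ss_total, 1.0, np.nan, np.nan]
    table["df"] = table["df"].astype(int)
    return table


def permanova_two_way(
    dist: pd.DataFrame,
    design: ExperimentDesign | pd.DataFrame,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    interaction: bool = True,
) -> pd.DataFrame:
    """Two-way PERMANOVA: competition, predation, their interaction.

    Terms are entered sequentially in that order (configurable only by
    reordering the design columns through :func:`permanova` directly).
    """
    if isinstance(design, ExperimentDesign):
        frame = design.to_frame().set_index("tank_id")
    else:
        frame = design
    labels = list(dist.index) if isinstance(dist, pd.DataFrame) else None
    if labels is not None:
        missing = [t for t in labels if t not in frame.index]
        if missing:
            raise ValidationError(f"tanks missing from design: {missing}")
        frame = frame.loc[labels]
    terms = ["competition", "predation"]
    if interaction:
        terms.append("competition:predation")
    return permanova(dist, frame, terms, n_perm=n_perm, seed=seed)


@dataclass
class DispersionResult:
    """Distances to group centroids and the homogeneity test."""

    distances: pd.Series
    group_means: pd.Series
    f: float
    p: float
    n_perm: int


def dispersion_homogeneity(
    dist: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> DispersionResult:
    """Betadisper-style test of homogeneity of multivariate dispersion.

    Samples are embedded by principal coordinates of the distance
    matrix, keeping axes with negative eigenvalues separately; the
    squared distance of a sample to its group centroid is the real-axis
    contribution minus the imaginary-axis contribution, floored at 0.
    Group differences in mean distance-to-centroid are tested with a
    one-way F whose significance comes from permuting the distances
    across groups.
    """
    d = _check_distance_matrix(dist)
    labels = (
        list(dist.index) if isinstance(dist, pd.DataFrame)
        else [str(i) for i in range(d.shape[0])]
    )
    grp = pd.Series(groups).loc[labels] if not isinstance(groups, pd.Series) else groups.loc[labels]
    counts = grp.value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least two groups")
    if (counts < 2).any():
        small = sorted(counts.index[counts < 2])
        raise ValidationError(f"group(s) with fewer than 2 members: {small}")

    g = _gower_center(d)
    eigval, eigvec = np.linalg.eigh(g)
    tol = 1e-8 * max(1.0, float(np.abs(eigval).max()))
    pos = eigval > tol
    neg = eigval < -tol
    coords_pos = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords_neg = eigvec[:, neg] * np.sqrt(-eigval[neg])

    dists = np.empty(d.shape[0])
    for level in counts.index:
        members = np.asarray(grp == level)
        cp = coords_pos[members].mean(axis=0)
        cn = coords_neg[members].mean(axis=0)
        sq = ((coords_pos[members] - cp) ** 2).sum(axis=1)
        sq -= ((coords_neg[members] - cn) ** 2).sum(axis=1)
        dists[members] = np.sqrt(np.maximum(sq, 0.0))

    codes = pd.factorize(grp)[0]

    def anova_f(z: np.ndarray) -> float:
        grand = z.mean()
        ss_b = sum(
            (z[codes == c]).size * (z[codes == c].mean() - grand) ** 2
            for c in range(len(counts))
        )
        ss_w = sum(
            ((z[codes == c] - z[codes == c].mean()) ** 2).sum()
            for c in range(len(counts))
        )
        df_b = len(counts) - 1
        df_w = z.size - len(counts)
        if ss_w <= 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    f_obs = anova_f(dists)
    ftol = 1e-9 * max(1.0, abs(f_obs)) if np.isfinite(f_obs) else 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = sum(
        anova_f(dists[rng.permutation(dists.size)]) >= f_obs - ftol
        for _ in range(n_perm)
    )
    p = (1.0 + exceed) / (n_perm + 1.0)
    series = pd.Series(dists, index=labels, name="dist_to_centroid")
    return DispersionResult(
        distances=series,
        group_means=series.groupby(grp).mean(),
        f=float(f_obs),
        p=float(p),
        n_perm=n_perm,
    )


def simper(
    compositions: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """SIMPER: per-category contributions to between-group dissimilarity.

    For two groups, the contribution of category j is the average over
    all between-group sample pairs (a, b) of |x_aj - x_bj| / sum_k(x_ak
    + x_bk); contributions sum exactly to the mean between-group
    Bray-Curtis dissimilarity. Significance of each contribution is a
    one-sided permutation test on group labels (add-one convention):
    small p flags categories contributing more than expected were the
    groups exchangeable.
    """
    comps = compositions.astype(float)
    grp = pd.Series(groups)
    grp = grp.loc[comps.index]
    levels = sorted(pd.unique(grp))
    if len(levels) != 2:
        raise ValidationError(f"SIMPER needs exactly two groups, got {levels}")
    mask = np.asarray(grp == levels[0])
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValidationError("a group has no members")
    x = comps.to_numpy()

    def contributions(m: np.ndarray) -> np.ndarray:
        a, b = x[m], x[~m]
        denom = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :]   # (na, nb)
        num = np.abs(a[:, None, :] - b[None, :, :])               # (na, nb, k)
        return (num / denom[:, :, None]).mean(axis=(0, 1))

    obs = contributions(mask)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = np.zeros_like(obs)
    for _ in range(n_perm):
        exceed += contributions(rng.permutation(mask)) >= obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)

    table = pd.DataFrame(
        {
            "contribution": obs,
            "contribution_pct": 100.0 * obs / obs.sum(),
            f"mean_{levels[0]}": x[mask].mean(axis=0),
            f"mean_{levels[1]}": x[~mask].mean(axis=0),
            "p": pvals,
        },
        index=comps.columns,
    )
    table.attrs["mean_between_group_bc"] = float(obs.sum())
    table.attrs["groups"] = levels
    return table.sort_values("contribution", ascending=False)


@dataclass
class OrdinationResult:
    """NMDS configuration with its Kruskal stress-1."""

    coordinates: pd.DataFrame
    stress: float
    n_starts: int
    seed: int | None
    converged: bool


def stress1(dist: pd.DataFrame, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    Disparities are the isotonic (monotone non-decreasing) regression of
    the configuration distances on the dissimilarities, ties averaged;
    stress-1 = sqrt(sum (d - dhat)^2 / sum d^2) over the upper triangle.
    """
    d = _check_distance_matrix(dist)
    diss = squareform(d, checks=False)
    conf = pdist(np.asarray(coordinates, dtype=float))
    disparities = IsotonicRegression(increasing=True).fit_transform(diss, conf)
    denom = float((conf**2).sum())
    if denom == 0:
        raise ValidationError("degenerate configuration (all points coincide)")
    return float(np.sqrt(((conf - disparities) ** 2).sum() / denom))


def _pcoa_coords(d: np.ndarray, k: int) -> np.ndarray:
    eigval, eigvec = np.linalg.eigh(_gower_center(d))
    order = np.argsort(eigval)[::-1][:k]
    lam = np.clip(eigval[order], 0.0, None)
    return eigvec[:, order] * np.sqrt(lam)


def nmds(
    dist: pd.DataFrame,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | np.random.Generator | None = None,
) -> OrdinationResult:
    """Non-metric multidimensional scaling, best of several starts.

    Runs nonmetric SMACOF from one principal-coordinate start plus
    ``n_starts`` random starts and returns the configuration with the
    lowest Kruskal stress-1 (evaluated by :func:`stress1`, so the
    selection criterion is independent of the optimiser's internal
    stress). If no start converges within ``max_iter`` the best-effort
    configuration is returned flagged ``converged=False``.
    """
    d = _check_distance_matrix(dist)
    n = d.shape[0]
    if n < k + 2:
        raise ValidationError(f"need at least k + 2 = {k + 2} samples")
    labels = (
        list(dist.index) if isinstance(dist, pd.DataFrame)
        else [str(i) for i in range(n)]
    )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    inits = [_pcoa_coords(d, k)]
    scale = max(d.max(), 1e-12)
    inits += [rng.normal(scale=scale, size=(n, k)) for _ in range(n_starts)]

    best = None
    best_stress = np.inf
    best_converged = False
    for init in inits:
        coords, _, n_iter = smacof(
            d, metric=False, n_components=k, init=init, n_init=1,
            max_iter=max_iter, eps=tol, normalized_stress=True,
            return_n_iter=True,
        )
        if not np.isfinite(coords).all() or pdist(coords).sum() == 0:
            continue
        s = stress1(d, coords)
        if s < best_stress:
            best, best_stress = coords, s
            best_converged = n_iter < max_iter
    if best is None:
        raise ValidationError("NMDS failed from every start")
    return OrdinationResult(
        coordinates=pd.DataFrame(
            best, index=labels, columns=[f"nmds{i + 1}" for i in range(k)]
        ),
        stress=best_stress,
        n_starts=len(inits),
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        converged=best_converged,
    )
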