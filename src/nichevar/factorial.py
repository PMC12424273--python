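"""2x2 factorial inference on per-tank niche responses.

Per-tank scalar responses (the specialisation index, WIC, BIC, TNW) are
modelled as ordinary least squares on competition, predation and their
interaction under sum-to-zero factor coding. Because tank attrition
leaves the design unbalanced, the interaction is tested with Type III
sums of squares; when it is not significant, main effects are reported
from Type II sums of squares (which respect marginality and are more
powerful in that case). Effect sizes are partial eta squared, and
pairwise differences among the four treatment cells are tested with
Tukey HSD (Tukey-Kramer standard errors for unequal cell sizes) plus a
compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from nichevar.resource_data import (
    TREATMENT_LABELS,
    ExperimentDesign,
    ValidationError,
)

__all__ = [
    "FactorialFit",
    "fit_2x2",
    "anova_report",
    "partial_eta_squared",
    "tukey_pairwise",
    "residual_diagnostics",
    "compact_letter_display",
]

TERMS = ("competition", "predation", "competition:predation")


@dataclass
class FactorialFit:
    """An OLS fit of a 2x2 factorial model with both SS types."""

    response: str
    transform: str
    y: np.ndarray
    tanks: list[str]
    cells: pd.Series            # treatment label per tank
    params: np.ndarray          # intercept, comp, pred, interaction (sum-to-zero)
    residuals: np.ndarray
    ss_type2: dict[str, float]
    ss_type3: dict[str, float]
    ss_resid: float
    df_resid: int

    @property
    def ss_total(self) -> float:
        return float(((self.y - self.y.mean()) ** 2).sum())

    @property
    def residual_degenerate(self) -> bool:
        """True when the model fits exactly (numerically zero residual)."""
        return self.ss_resid <= 1e-12 * max(self.ss_total, 1e-300)

    @property
    def mse(self) -> float:
        if self.df_resid <= 0:
            raise ValidationError("no residual degrees of freedom")
        return self.ss_resid / self.df_resid

    @property
    def cell_means(self) -> pd.Series:
        return pd.Series(self.y, index=self.cells.to_numpy()).groupby(level=0).mean()

    @property
    def cell_counts(self) -> pd.Series:
        return self.cells.value_counts()


def _rss(y: np.ndarray, x: np.ndarray) -> float:
    return float(sm.OLS(y, x).fit().ssr)


def fit_2x2(
    response_by_tank: Mapping[str, float] | pd.Series,
    design: ExperimentDesign,
    transform: str = "none",
    response_name: str = "response",
) -> FactorialFit:
    """Fit the 2x2 competition x predation model to per-tank responses.

    ``transform="log"`` applies a natural log (all responses must be
    strictly positive; the offending tank is named otherwise). Both
    Type III (each term dropped from the full model) and Type II
    (main effects adjusted for the other main effect only) sums of
    squares are computed from nested-model residual sums of squares
    under sum-to-zero coding.
    """
    y_series = pd.Series(response_by_tank, dtype=float)
    tanks = [str(t) for t in y_series.index]
    missing = [t for t in tanks if t not in design.factors]
    if missing:
        raise ValidationError(f"tanks missing from design: {missing}")
    y = y_series.to_numpy()
    if transform == "log":
        bad = [t for t, v in zip(tanks, y) if v <= 0]
        if bad:
            raise ValidationError(
                f"log transform requires positive response; offending tank(s): {bad}"
            )
        y = np.log(y)
    elif transform != "none":
        raise ValidationError(f"unknown transform {transform!r}")

    comp = np.array([design.competition(t) for t in tanks])
    pred = np.array([design.predation(t) for t in tanks])
    cells = pd.Series(
        [TREATMENT_LABELS[(c, p)] for c, p in zip(comp, pred)], index=tanks
    )
    if cells.nunique() < 4:
        present = sorted(cells.unique())
        raise ValidationError(
            f"empty design cell(s): only {present} observed; "
            "the interaction model is not estimable"
        )

    a = 2.0 * comp - 1.0      # sum-to-zero codes
    b = 2.0 * pred - 1.0
    one = np.ones_like(a)
    x_full = np.column_stack([one, a, b, a * b])
    fit = sm.OLS(y, x_full).fit()
    rss_full = float(fit.ssr)

    def cols(*idx: int) -> np.ndarray:
        return x_full[:, list(idx)]

    ss_type3 = {
        "competition": _rss(y, cols(0, 2, 3)) - rss_full,
        "predation": _rss(y, cols(0, 1, 3)) - rss_full,
        "competition:predation": _rss(y, cols(0, 1, 2)) - rss_full,
    }
    rss_ab = _rss(y, cols(0, 1, 2))
    ss_type2 = {
        "competition": _rss(y, cols(0, 2)) - rss_ab,
        "predation": _rss(y, cols(0, 1)) - rss_ab,
        "competition:predation": ss_type3["competition:predation"],
    }
    return FactorialFit(
        response=response_name,
        transform=transform,
        y=y,
        tanks=tanks,
        cells=cells,
        params=np.asarray(fit.params),
        residuals=np.asarray(fit.resid),
        ss_type2={k: max(v, 0.0) for k, v in ss_type2.items()},
        ss_type3={k: max(v, 0.0) for k, v in ss_type3.items()},
        ss_resid=rss_full,
        df_resid=len(y) - 4,
    )


def anova_report(
    fit: FactorialFit, interaction_first: bool = True, alpha: float = 0.05
) -> pd.DataFrame:
    """Term table implementing the interaction-gated SS choice.

    The interaction is always judged from Type III sums of squares.
    With ``interaction_first`` (the default), main effects are reported
    from Type II sums of squares when the interaction is not
    significant at ``alpha``, and from Type III otherwise. Each row
    carries df, SS, F, p, the SS type used, and partial eta squared.
    """
    if fit.df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")
    if fit.residual_degenerate:
        raise ValidationError("zero residual variance: F is undefined")
    mse = fit.mse

    def row(term: str, ss_type: str) -> dict:
        ss = (fit.ss_type3 if ss_type == "III" else fit.ss_type2)[term]
        f = ss / mse
        return {
            "term": term,
            "df": 1,
            "ss": ss,
            "ss_type": ss_type,
            "f": f,
            "p": float(stats.f.sf(f, 1, fit.df_resid)),
            "partial_eta_sq": ss / (ss + fit.ss_resid),
        }

    inter = row("competition:predation", "III")
    if interaction_first and inter["p"] >= alpha:
        main_type = "II"
    else:
        main_type = "III"
    rows = [row("competition", main_type), row("predation", main_type), inter]
    table = pd.DataFrame(rows).set_index("term")
    table.loc["residual"] = {
        "df": fit.df_resid, "ss": fit.ss_resid, "ss_type": "",
        "f": np.nan, "p": np.nan, "partial_eta_sq": np.nan,
    }
    table["df"] = table["df"].astype(int)
    return table


def partial_eta_squared(fit: FactorialFit, term: str, ss_type: str = "II") -> float:
    """Partial eta squared SS_term / (SS_term + SS_residual)."""
    ss_map = fit.ss_type3 if ss_type == "III" else fit.ss_type2
    if term not in ss_map:
        raise ValidationError(f"unknown term {term!r}; terms: {list(ss_map)}")
    denom = ss_map[term] + fit.ss_resid
    if denom == 0:
        raise ValidationError("SS_term + SS_residual = 0: effect size undefined")
    return ss_map[term] / denom


def compact_letter_display(
    levels: list[str], significant_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Levels sharing a letter are not significantly different; every
    significant pair ends up with no letter in common.
    """
    groups: list[set[str]] = [set(levels)]
    for i, j in significant_pairs:
        new: list[set[str]] = []
        for g in groups:
            if i in g and j in g:
                new.extend([g - {i}, g - {j}])
            else:
                new.append(g)
        # absorb subsets and duplicates
        groups = []
        for g in sorted(new, key=len, reverse=True):
            if g and not any(g <= h for h in groups):
                groups.append(g)
    groups.sort(key=lambda g: min(levels.index(l) for l in g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {
        lvl: "".join(alphabet[k] for k, g in enumerate(groups) if lvl in g)
        for lvl in levels
    }


def tukey_pairwise(fit: FactorialFit, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD comparisons among the four treatment cells.

    The 2x2 model with interaction is exactly the 4-cell means model,
    so its residual mean square and df are reused. Unequal cell sizes
    use the Tukey-Kramer standard error; adjusted p-values come from
    the studentized range distribution with 4 groups. A compact letter
    display at ``alpha`` is attached via ``.attrs["letters"]``.
    """
    if fit.df_resid <= 0:
        raise ValidationError("no residual degrees of freedom")
    if fit.residual_degenerate:
        raise ValidationError("zero residual variance: Tukey HSD undefined")
    mse = fit.mse
    means = fit.cell_means
    counts = fit.cell_counts
    order = [lab for lab in TREATMENT_LABELS.values() if lab in means.index]
    rows = []
    sig: set[tuple[str, str]] = set()
    for g1, g2 in combinations(order, 2):
        diff = means[g1] - means[g2]
        se_q = np.sqrt(mse / 2.0 * (1.0 / counts[g1] + 1.0 / counts[g2]))
        q = abs(diff) / se_q
        p_adj = float(stats.studentized_range.sf(q, len(order), fit.df_resid))
        if p_adj <= alpha:
            sig.add((g1, g2))
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "estimate": diff,
                "se": np.sqrt(mse * (1.0 / counts[g1] + 1.0 / counts[g2])),
                "q": q,
                "p_adj": min(p_adj, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["letters"] = compact_letter_display(order, sig)
    table.attrs["alpha"] = alpha
    return table


def residual_diagnostics(fit: FactorialFit) -> dict:
    """Numeric stand-in for a visual residual check; purely advisory.

    Flags raised: ``skewness`` when |skewness| > 1, ``heteroscedastic``
    when the max/min cell variance ratio exceeds 4, ``degenerate`` when
    the residuals are (numerically) constant.
    """
    r = fit.residuals
    flags: list[str] = []
    if np.allclose(r, r[0], atol=1e-12):
        return {
            "skewness": 0.0, "excess_kurtosis": 0.0,
            "variance_ratio": np.nan, "flags": ["degenerate"],
        }
    skew = float(stats.skew(r))
    kurt = float(stats.kurtosis(r))
    cell_vars = pd.Series(r, index=fit.cells.to_numpy()).groupby(level=0).var(ddof=1)
    cell_vars = cell_vars.dropna()
    vmin = float(cell_vars.min()) if len(cell_vars) else np.nan
    ratio = float(cell_vars.max() / vmin) if vmin and vmin > 0 else np.inf
    if abs(skew) > 1:
        flags.append("skewness")
    if ratio > 4:
        flags.append("heteroscedastic")
    return {
        "skewness": skew,
        "excess_kurtosis": kurt,
        "variance_ratio": ratio,
        "flags": flags,
    }
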