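"""Resource-use records, count matrices, and the filtering/aggregation rules.

The central object is the :class:`ResourceUseMatrix`: an individuals x
resource-categories table of non-negative integer counts for one
population (tank), for one niche kind (``"diet"`` or ``"habitat"``).
Diet counts are stomach-content item counts summed over repeated
gastric-lavage sessions; habitat use is encoded as one count per
sighting, so the same machinery serves both niche axes.

Populations enter the downstream statistics only after two filters:
individuals only ever sampled with empty stomachs are dropped, and a
tank is retained only if it has at least ``min_individuals`` individuals
each carrying at least ``min_measures`` total niche measures (items or
observations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "SampleRecord",
    "ExperimentDesign",
    "ResourceUseMatrix",
    "read_records",
    "apply_taxonomy",
    "read_taxonomy",
    "build_matrix",
    "build_tank_matrices",
    "drop_empty_individuals",
    "filter_tanks",
    "tank_mean_composition",
    "TREATMENT_LABELS",
]


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """A record violates an invariant (negative count, unmapped taxon...)."""


#: canonical treatment labels for the 2x2 competition x predation design,
#: keyed by (competition flag, predation flag)
TREATMENT_LABELS: dict[tuple[int, int], str] = {
    (0, 0): "control",
    (0, 1): "predation",
    (1, 0): "competition",
    (1, 1): "predation+competition",
}

DEFAULT_COLUMNS = {
    "tank_id": "tank_id",
    "individual_id": "individual_id",
    "session": "session",
    "category": "category",
    "count": "count",
}


@dataclass(frozen=True, order=True)
class SampleRecord:
    """One (tank, individual, session, category) count.

    ``count`` is the number of diet items of that category found in that
    session's stomach sample, or 1 for a habitat sighting.
    """

    tank_id: str
    individual_id: str
    session: str
    category: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValidationError(f"negative count for {self}")
        if not self.category:
            raise ValidationError("empty resource category")


@dataclass(frozen=True)
class ExperimentDesign:
    """Tank -> (competition, predation) map for the 2x2 factorial design."""

    factors: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for tank, flags in self.factors.items():
            if tuple(flags) not in TREATMENT_LABELS:
                raise ValidationError(
                    f"tank {tank!r}: flags {flags!r} are not a 2x2 cell"
                )

    @property
    def tanks(self) -> list[str]:
        return list(self.factors)

    def competition(self, tank_id: str) -> int:
        return self.factors[tank_id][0]

    def predation(self, tank_id: str) -> int:
        return self.factors[tank_id][1]

    def treatment(self, tank_id: str) -> str:
        return TREATMENT_LABELS[tuple(self.factors[tank_id])]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tank_id": t,
                "competition": c,
                "predation": p,
                "treatment": TREATMENT_LABELS[(c, p)],
            }
            for t, (c, p) in self.factors.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExperimentDesign":
        for col in ("tank_id", "competition", "predation"):
            if col not in frame.columns:
                raise SchemaError(f"design table is missing column {col!r}")
        dup = frame["tank_id"].duplicated()
        if dup.any():
            raise ValidationError(
                f"duplicate tanks in design: {sorted(frame.loc[dup, 'tank_id'])}"
            )
        return cls(
            {
                str(r.tank_id): (int(r.competition), int(r.predation))
                for r in frame.itertuples()
            }
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "ExperimentDesign":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class ResourceUseMatrix:
    """Individuals x resource categories count matrix for one tank."""

    counts: np.ndarray
    individuals: list[str]
    categories: list[str]
    tank_id: str
    niche_kind: str = "diet"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.individuals), len(self.categories)):
            raise ValidationError("matrix shape does not match its labels")
        if (self.counts < 0).any():
            raise ValidationError("negative cell in resource-use matrix")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.individuals, name="individual_id"),
            columns=self.categories,
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, tank_id: str, niche_kind: str = "diet"
    ) -> "ResourceUseMatrix":
        return cls(
            counts=frame.to_numpy(dtype=float),
            individuals=[str(i) for i in frame.index],
            categories=[str(c) for c in frame.columns],
            tank_id=tank_id,
            niche_kind=niche_kind,
        )


def _records_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.tank_id, r.individual_id, r.session, r.category, r.count)
            for r in records
        ],
        columns=["tank_id", "individual_id", "session", "category", "count"],
    )


def read_records(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[SampleRecord]:
    """Read long-format sample records from a CSV file.

    Parameters
    ----------
    path
        CSV with a header row naming the five required fields.
    columns
        Optional mapping from canonical field names (``tank_id``,
        ``individual_id``, ``session``, ``category``, ``count``) to the
        column names actually present in the file.

    Duplicate (tank, individual, session, category) rows are summed.
    Negative or non-integer counts raise :class:`ValidationError` naming
    the offending row.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    table = pd.read_csv(path, dtype=str)
    missing = [src for src in colmap.values() if src not in table.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {missing}; "
            f"present: {list(table.columns)}"
        )
    table = table.rename(columns={v: k for k, v in colmap.items()})
    counts = pd.to_numeric(table["count"], errors="coerce")
    bad = counts.isna() | (counts != counts.round()) | (counts < 0)
    if bad.any():
        # +2: header line plus 1-based numbering
        rows = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise ValidationError(
            f"{path}: non-integer or negative count at row(s) {rows}"
        )
    table["count"] = counts.astype(int)
    grouped = (
        table.groupby(
            ["tank_id", "individual_id", "session", "category"], sort=True
        )["count"]
        .sum()
        .reset_index()
    )
    return [
        SampleRecord(
            str(r.tank_id), str(r.individual_id), str(r.session),
            str(r.category), int(r.count),
        )
        for r in grouped.itertuples()
    ]


def read_taxonomy(path: str | Path) -> dict[str, str]:
    """Read a two-column (raw_taxon, category) CSV into a taxonomy map."""
    table = pd.read_csv(path, dtype=str)
    if table.shape[1] < 2:
        raise SchemaError(f"{path}: taxonomy map needs two columns")
    raw, agg = table.columns[:2]
    dup = table[raw].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: raw taxa mapped twice: {sorted(table.loc[dup, raw])}"
        )
    return dict(zip(table[raw].astype(str), table[agg].astype(str)))


def apply_taxonomy(
    records: Sequence[SampleRecord],
    taxonomy_map: Mapping[str, str],
    strict: bool = True,
    other_label: str = "other",
) -> list[SampleRecord]:
    """Aggregate raw prey taxa into the analysis categories.

    Rare or partially digestible taxa are pooled into higher taxonomic
    groups (e.g. chydorid subfamilies into a single *Chydorus* spp.
    category) so that more items can be identified and included. Counts
    merging into one label are summed; total count is conserved.

    With ``strict=True`` an unmapped taxon raises
    :class:`ValidationError` listing every unmapped label; otherwise
    unmapped taxa are pooled into ``other_label``.
    """
    unmapped = sorted({r.category for r in records} - set(taxonomy_map))
    if unmapped and strict:
        raise ValidationError(f"unmapped taxa: {unmapped}")
    merged: dict[tuple[str, str, str, str], int] = {}
    for r in records:
        label = taxonomy_map.get(r.category, other_label)
        key = (r.tank_id, r.individual_id, r.session, label)
        merged[key] = merged.get(key, 0) + r.count
    return [
        SampleRecord(*key, count) for key, count in sorted(merged.items())
    ]


def build_matrix(
    records: Sequence[SampleRecord],
    tank_id: str,
    niche_kind: str = "diet",
) -> ResourceUseMatrix:
    """Sum one tank's records over sessions into a count matrix.

    Individual proportions are computed downstream from counts
    aggregated across all of an individual's sampling sessions; this op
    performs that aggregation. Individuals whose total is zero (only
    empty stomachs) are retained here and removed by
    :func:`drop_empty_individuals`. Category order is lexicographic for
    reproducible serialisation.
    """
    sub = [r for r in records if r.tank_id == tank_id]
    if not sub:
        raise ValidationError(f"no records for tank {tank_id!r}")
    frame = _records_frame(sub)
    wide = (
        frame.pivot_table(
            index="individual_id", columns="category", values="count",
            aggfunc="sum", fill_value=0,
        )
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    return ResourceUseMatrix.from_frame(wide, tank_id=tank_id, niche_kind=niche_kind)


def build_tank_matrices(
    records: Sequence[SampleRecord], niche_kind: str = "diet"
) -> dict[str, ResourceUseMatrix]:
    """Build one matrix per tank present in ``records``."""
    tanks = sorted({r.tank_id for r in records})
    return {t: build_matrix(records, t, niche_kind) for t in tanks}


def drop_empty_individuals(
    matrix: ResourceUseMatrix,
) -> tuple[ResourceUseMatrix, int]:
    """Remove individuals only ever sampled with empty stomachs.

    Rows with zero total are dropped and counted; columns that become
    all-zero are dropped too (a category no retained individual used
    carries no information). May return an empty matrix.
    """
    keep_rows = matrix.row_sums > 0
    n_dropped = int((~keep_rows).sum())
    counts = matrix.counts[keep_rows]
    individuals = [i for i, k in zip(matrix.individuals, keep_rows) if k]
    keep_cols = counts.sum(axis=0) > 0 if counts.size else np.zeros(
        matrix.n_categories, dtype=bool
    )
    counts = counts[:, keep_cols]
    categories = [c for c, k in zip(matrix.categories, keep_cols) if k]
    return (
        ResourceUseMatrix(
            counts, individuals, categories, matrix.tank_id, matrix.niche_kind
        ),
        n_dropped,
    )


def filter_tanks(
    matrices: Mapping[str, ResourceUseMatrix],
    min_individuals: int = 3,
    min_measures: int = 3,
) -> tuple[dict[str, ResourceUseMatrix], list[dict]]:
    """Apply the tank-retention rule and log exclusions.

    A tank is retained iff at least ``min_individuals`` of its
    individuals each carry at least ``min_measures`` niche measures
    (total diet items or habitat observations, i.e. the row sum).
    Individuals below the per-individual threshold are removed from
    retained tanks, as are categories that become all-zero.

    Returns the retained matrices and an exclusion log: one dict per
    excluded tank with ``tank_id``, ``reason`` and ``n_qualifying``.
    """
    retained: dict[str, ResourceUseMatrix] = {}
    log: list[dict] = []
    for tank_id, m in matrices.items():
        qualifying = m.row_sums >= min_measures
        n_ok = int(qualifying.sum())
        if n_ok < min_individuals:
            log.append(
                {
                    "tank_id": tank_id,
                    "niche_kind": m.niche_kind,
                    "reason": (
                        f"only {n_ok} individual(s) with >= {min_measures} "
                        f"niche measures (need {min_individuals})"
                    ),
                    "n_qualifying": n_ok,
                }
            )
            continue
        counts = m.counts[qualifying]
        individuals = [i for i, k in zip(m.individuals, qualifying) if k]
        keep_cols = counts.sum(axis=0) > 0
        retained[tank_id] = ResourceUseMatrix(
            counts[:, keep_cols],
            individuals,
            [c for c, k in zip(m.categories, keep_cols) if k],
            tank_id,
            m.niche_kind,
        )
    return retained, log


def tank_mean_composition(matrix: ResourceUseMatrix) -> pd.Series:
    """Mean of individual resource-use proportions for one tank.

    Each individual's counts are first converted to proportions, then
    averaged across individuals with equal weight, so an individual
    sampled more heavily does not dominate the tank's composition. The
    result sums to 1.
    """
    if matrix.n_individuals == 0 or matrix.total == 0:
        raise ValidationError(
            f"tank {matrix.tank_id!r}: cannot average an empty matrix"
        )
    sums = matrix.row_sums
    if (sums == 0).any():
        raise ValidationError(
            f"tank {matrix.tank_id!r}: zero-sum individual; run "
            "drop_empty_individuals first"
        )
    props = matrix.counts / sums[:, None]
    return pd.Series(props.mean(axis=0), index=matrix.categories)
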