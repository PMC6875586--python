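"""Expert-elicitation campaign data and agreement analytics.

Two experts score each (species, niche axis) unit into one of four ordered
categories — excellent, good, moderate, poor — or opt out with
"cannot_evaluate". A random dual subsample is scored by both experts
(without either knowing which units overlap); the paired scores are
cross-tabulated into a confusion matrix whose trace counts exact
agreements:

    % agreement = 100 * identical assessments / total paired assessments

and, restricted to pairs in which either expert used a given category,

    % agreement(c) = 100 * diag(c) / (row_total(c) + col_total(c) - diag(c)).

The published dual-assessment confusion matrix ships as a packaged CSV
fixture (rows = expert 2, columns = expert 1) so the agreement statistics
are reproducible without the original score file.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "CANNOT_EVALUATE",
    "Allocation",
    "ConfusionMatrix",
    "allocate_species",
    "assessment_units",
    "confusion_matrix",
    "percent_agreement",
    "category_agreement",
    "score_distribution",
    "pairs_from_matrix",
    "matrix_from_pairs",
    "published_confusion_matrix",
    "validate_scores",
]

CATEGORIES = ("excellent", "good", "moderate", "poor")
CANNOT_EVALUATE = "cannot_evaluate"
VALID_CATEGORIES = CATEGORIES + (CANNOT_EVALUATE,)


def assessment_units(n_species: int, n_axes: int = 7, n_methods: int = 1) -> int:
    """Number of assessment units: species x niche axes (x methods when
    each modelling method would be scored separately instead of one
    averaged curve)."""
    if min(n_species, n_axes, n_methods) < 1:
        raise ValueError("counts must be positive")
    return n_species * n_axes * n_methods


@dataclass(frozen=True)
class Allocation:
    """Assignment of species to experts, with a hidden dual subsample."""

    experts: tuple[str, str]
    tasks: dict[str, tuple[str, ...]]  # expert -> full (sorted) task list
    dual_set: frozenset[str]

    def expert_of(self, species: str) -> tuple[str, ...]:
        return tuple(e for e, lst in self.tasks.items() if species in lst)


def allocate_species(species, experts, dual_frac: float = 0.05,
                     seed: int = 0) -> Allocation:
    """Randomly split species between two experts with a dual subsample.

    The dual subsample of size ceil(dual_frac * n) is drawn uniformly and
    assessed by both experts; the rest is partitioned as evenly as
    possible. Each expert's task list is sorted, so dual-set membership is
    not identifiable from it. Deterministic per seed.
    """
    species = list(species)
    if len(species) < 2:
        raise ValueError("need at least 2 species to allocate")
    if len(set(species)) != len(species):
        raise ValueError("species labels must be unique")
    ea, eb = experts
    if not 0.0 <= dual_frac <= 1.0:
        raise ValueError("dual_frac must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_dual = math.ceil(dual_frac * len(species))
    order = rng.permutation(len(species))
    dual = [species[i] for i in order[:n_dual]]
    rest = [species[i] for i in order[n_dual:]]
    half = (len(rest) + 1) // 2
    tasks = {
        ea: tuple(sorted(rest[:half] + dual)),
        eb: tuple(sorted(rest[half:] + dual)),
    }
    return Allocation(experts=(ea, eb), tasks=tasks, dual_set=frozenset(dual))


def validate_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Validate a score table: required columns, closed category set
    (case-insensitive on read, canonical lower-case on return), one record
    per (species, axis, expert). Offending row numbers are reported."""
    required = ["species", "axis", "expert", "category"]
    missing = [c for c in required if c not in scores.columns]
    if missing:
        raise ValueError(f"score table lacks columns {missing}")
    out = scores[required].copy()
    out["category"] = out["category"].astype(str).str.strip().str.lower()
    bad = ~out["category"].isin(VALID_CATEGORIES)
    if bad.any():
        rows = [int(i) for i in out.index[bad][:10]]
        vals = sorted(out.loc[bad, "category"].unique())
        raise ValueError(f"unknown categories {vals} at rows {rows}")
    dup = out.duplicated(subset=["species", "axis", "expert"])
    if dup.any():
        rows = [int(i) for i in out.index[dup][:10]]
        raise ValueError(f"duplicate (species, axis, expert) records at rows {rows}")
    return out


@dataclass
class ConfusionMatrix:
    """k x k cross-tabulation of paired scores (rows = expert B / second
    expert, columns = expert A / first expert) with marginals."""

    counts: pd.DataFrame  # index/columns = CATEGORIES

    def __post_init__(self) -> None:
        c = self.counts.reindex(index=list(CATEGORIES),
                                columns=list(CATEGORIES)).fillna(0)
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        c = c.astype(int)
        c.index.name = "expert_b"
        c.columns.name = "expert_a"
        self.counts = c

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def diagonal_total(self) -> int:
        return int(np.trace(self.counts.to_numpy()))


def confusion_matrix(scores: pd.DataFrame, expert_a: str,
                     expert_b: str) -> ConfusionMatrix:
    """Cross-tabulate the two experts over jointly scored (species, axis)
    units, excluding any pair in which either chose cannot_evaluate.
    Columns follow expert A, rows expert B."""
    s = validate_scores(scores)
    for e in (expert_a, expert_b):
        if e not in set(s["expert"]):
            raise ValueError(f"expert {e!r} not present in score table")
    a = s[s["expert"] == expert_a].set_index(["species", "axis"])["category"]
    b = s[s["expert"] == expert_b].set_index(["species", "axis"])["category"]
    both = a.index.intersection(b.index)
    pairs = pd.DataFrame({"a": a.loc[both], "b": b.loc[both]})
    pairs = pairs[(pairs["a"] != CANNOT_EVALUATE) & (pairs["b"] != CANNOT_EVALUATE)]
    if pairs.empty:
        warnings.warn("no overlapping evaluated pairs; confusion matrix is zero",
                      stacklevel=2)
    tab = pd.crosstab(pairs["b"], pairs["a"])
    return ConfusionMatrix(counts=tab)


def percent_agreement(m: ConfusionMatrix) -> float:
    """Overall % agreement: 100 * trace / grand total (full precision;
    display rounding is the caller's concern)."""
    if m.grand_total == 0:
        raise ValueError("percent agreement undefined for an empty matrix")
    return 100.0 * m.diagonal_total / m.grand_total


def category_agreement(m: ConfusionMatrix, category: str) -> float:
    """% agreement restricted to pairs in which either expert used the
    category: 100 * diag / (row + col - diag)."""
    if category not in CATEGORIES:
        raise KeyError(f"unknown category {category!r}")
    d = int(m.counts.loc[category, category])
    denom = int(m.row_totals[category] + m.col_totals[category] - d)
    if denom == 0:
        raise ValueError(f"no pairs involve category {category!r}")
    return 100.0 * d / denom


def score_distribution(scores: pd.DataFrame, expert: str | None = None,
                       species: list[str] | None = None,
                       include_cannot_evaluate: bool = False) -> pd.Series:
    """Percentage of assessments per category over a selection of records.

    By default cannot_evaluate records are excluded from the denominator
    (toggle with ``include_cannot_evaluate``). Percentages sum to 100
    within floating rounding.
    """
    s = validate_scores(scores)
    if expert is not None:
        s = s[s["expert"] == expert]
    if species is not None:
        s = s[s["species"].isin(species)]
    if not include_cannot_evaluate:
        s = s[s["category"] != CANNOT_EVALUATE]
    if s.empty:
        raise ValueError("empty selection; no evaluated records to tabulate")
    cats = VALID_CATEGORIES if include_cannot_evaluate else CATEGORIES
    counts = s["category"].value_counts().reindex(list(cats)).fillna(0)
    return 100.0 * counts / counts.sum()


def pairs_from_matrix(m: ConfusionMatrix) -> pd.DataFrame:
    """Expand a confusion matrix back into one row per paired score
    (columns ``a``, ``b``); inverse of matrix_from_pairs."""
    rows = []
    for cb in CATEGORIES:
        for ca in CATEGORIES:
            rows.extend([(ca, cb)] * int(m.counts.loc[cb, ca]))
    return pd.DataFrame(rows, columns=["a", "b"])


def matrix_from_pairs(pairs: pd.DataFrame) -> ConfusionMatrix:
    return ConfusionMatrix(counts=pd.crosstab(pairs["b"], pairs["a"]))


def published_confusion_matrix() -> ConfusionMatrix:
    """The packaged dual-assessment confusion matrix fixture (45 vascular
    plant species scored by both experts; 290 evaluated pairs)."""
    with resources.files("nicheval.data").joinpath(
            "dual_assessment_confusion.csv").open() as fh:
        tidy = pd.read_csv(fh)
    tab = tidy.pivot(index="expert2_category", columns="expert1_category",
                     values="count")
    return ConfusionMatrix(counts=tab)
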