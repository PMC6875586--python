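"""Quantitative model-fit assessment: repeated 75/25 hold-out AUC and its
comparison against species prevalence and expert scores.

AUC is computed in the rank-statistic (Mann–Whitney) form: the probability
that a randomly chosen presence receives a higher predicted value than a
randomly chosen absence, with ties counting one half. Because AUC is a
rank statistic it is invariant under the strictly monotone favorability
rescale, so raw and rescaled predictions give identical values.

Prevalence-vs-AUC displays use a square-root transform of prevalence (to
spread rare species across the axis) and degree-1 locally weighted
regression (loess) per assessment-category group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .ensemble import fit_ensemble, predict
from .synthetic import CovariateSpace, species_column

__all__ = [
    "AucResult",
    "rank_auc",
    "auc_holdout",
    "score_auc_table",
    "smoothed_trend",
]


def rank_auc(y_true, scores) -> float:
    """Mann–Whitney AUC: P(score_presence > score_absence) + 0.5 P(tie)."""
    y = np.asarray(y_true)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC requires both presences and absences")
    r = rankdata(s)  # average ranks handle ties with the 0.5 convention
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class AucResult:
    species: str
    method: str
    rep_aucs: np.ndarray
    prevalence: float

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.rep_aucs))

    @property
    def sqrt_prevalence(self) -> float:
        return float(np.sqrt(self.prevalence))


def auc_holdout(plots: pd.DataFrame, species: str, space: CovariateSpace,
                method: str, train_frac: float = 0.75, reps: int = 10,
                seed: int = 0, max_retries: int = 100,
                min_class_count: int = 5) -> AucResult:
    """Repeated random 75/25 hold-out AUC for one species and method.

    Each repetition draws a simple random (unstratified) split, fits the
    method on the training part and scores the test part with the rank
    AUC. Splits leaving either part without both classes are redrawn (up
    to ``max_retries``, logged); seeded, so results are reproducible.
    """
    col = species_column(species)
    y_all = plots[col].to_numpy()
    n = len(plots)
    n_train = int(round(train_frac * n))
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(reps):
        for attempt in range(max_retries):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if (y_all[tr].min() < y_all[tr].max()
                    and y_all[te].min() < y_all[te].max()):
                break
        else:
            raise RuntimeError(
                f"could not draw a usable {train_frac:.0%} split for "
                f"{species!r} in {max_retries} tries; more data needed"
            )
        if attempt > 0:
            warnings.warn(f"{species!r}: redrew a degenerate split "
                          f"{attempt} time(s)", stacklevel=2)
        fit = fit_ensemble(plots.iloc[tr], species, space, methods=(method,),
                           seed=int(rng.integers(2**31 - 1)),
                           min_class_count=min(min_class_count,
                                               int(y_all[tr].sum())))
        p = predict(fit, plots.iloc[te], method)
        aucs.append(rank_auc(y_all[te], p))
    return AucResult(species=species, method=method,
                     rep_aucs=np.asarray(aucs),
                     prevalence=float(y_all.mean()))


def score_auc_table(aucs, scores: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Join expert scores with species-level mean AUC and prevalence.

    ``aucs`` is an iterable of AucResult (possibly several methods per
    species); the species mean AUC averages over its fitted methods.
    Returns one record per (species, axis, expert) score plus the list of
    scored species lacking any AUC (excluded from the join).
    """
    rows = [(a.species, a.method, a.mean_auc, a.prevalence) for a in aucs]
    auc_df = pd.DataFrame(rows, columns=["species", "method", "mean_auc", "prevalence"])
    per_species = (auc_df.groupby("species", as_index=False)
                   .agg(mean_auc=("mean_auc", "mean"),
                        prevalence=("prevalence", "first")))
    missing = sorted(set(scores["species"]) - set(per_species["species"]))
    joined = scores.merge(per_species, on="species", how="inner")
    joined["sqrt_prevalence"] = np.sqrt(joined["prevalence"])
    return joined.reset_index(drop=True), missing


def smoothed_trend(records: pd.DataFrame, group: str = "category",
                   x: str = "sqrt_prevalence", y: str = "mean_auc",
                   frac: float = 0.75, min_group: int = 10) -> dict[str, pd.DataFrame]:
    """Loess curve of mean AUC against sqrt-prevalence per category group.

    Degree-1 locally weighted regression with span ``frac``. Groups with
    fewer than ``min_group`` records are skipped with a warning.
    """
    out: dict[str, pd.DataFrame] = {}
    for cat, grp in records.groupby(group):
        if len(grp) < min_group:
            warnings.warn(f"group {cat!r} has only {len(grp)} records; "
                          "skipped from smoothing", stacklevel=2)
            continue
        fitted = lowess(grp[y].to_numpy(), grp[x].to_numpy(),
                        frac=frac, it=0, return_sorted=True)
        out[str(cat)] = pd.DataFrame({x: fitted[:, 0], y: fitted[:, 1]})
    return out
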