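"""Five-method species niche model ensemble with a uniform prediction contract.

The ensemble mirrors the standard small multi-method SDM toolkit: a
parametric logistic GLM (linear + quadratic terms, pairwise interactions
when data permit), a penalized spline additive logistic model (GAM), an
adaptive hinge-basis fitter (MARS), a single-hidden-layer perceptron (NN)
and a classification random forest (RF). All methods expose the same
``predict`` surface returning probability of presence in [0, 1].

Raw probabilities are comparable across species of different commonness
only after the prevalence-correcting favorability rescale of Real, Barbosa
& Vargas: F = (p / (1 - p)) / (n1/n0 + p / (1 - p)). F is a strictly
monotone bijection of [0, 1] for fixed presence/absence counts, so
rank-based statistics such as AUC are unchanged by it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import SplineTransformer, StandardScaler

from ._mars import MarsClassifier
from .synthetic import CovariateSpace, species_column

__all__ = [
    "METHOD_TAGS",
    "CURVE_METHODS",
    "EnsembleFit",
    "fit_ensemble",
    "predict",
    "favorability_rescale",
    "ensemble_favorability",
    "save_fit",
    "load_fit",
]

METHOD_TAGS = ("GLM", "GAM", "MARS", "NN", "RF")
# RF is excluded from 1D response-curve averages (spiky, locally over-fitted
# curves are uninterpretable to an assessor).
CURVE_METHODS = ("GLM", "GAM", "MARS", "NN")


def favorability_rescale(p, n_presence: int, n_absence: int):
    """Prevalence-correcting favorability transform of raw probabilities.

    F = (p/(1-p)) / (n1/n0 + p/(1-p)). F(0) = 0 and F(1) = 1 (limit
    convention), F is strictly increasing in p, and when p equals the
    training prevalence n1/(n1+n0) the odds ratio is 1 so F = 0.5.
    """
    if n_presence <= 0 or n_absence <= 0:
        raise ValueError("presence and absence counts must be positive")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    ratio = n_presence / n_absence
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = p_arr / (1.0 - p_arr)
        f = np.where(p_arr >= 1.0, 1.0, odds / (ratio + odds))
    if np.isscalar(p) or np.ndim(p) == 0:
        return float(f)
    return f


# ---------------------------------------------------------------------------
# per-method wrappers (uniform predict-probability contract)
# ---------------------------------------------------------------------------

class _GlmModel:
    """Logistic GLM: per-axis linear + quadratic terms; pairwise linear
    interactions when the species has at least ``interaction_floor``
    presences."""

    def __init__(self, include_interactions: bool):
        self.include_interactions = include_interactions
        self.scaler = StandardScaler()
        self.model = LogisticRegression(C=1e4, max_iter=5000)

    def _expand(self, X: np.ndarray) -> np.ndarray:
        cols = [X, X**2]
        if self.include_interactions:
            n = X.shape[1]
            inter = [X[:, i] * X[:, j] for i in range(n) for j in range(i + 1, n)]
            cols.append(np.column_stack(inter))
        return np.column_stack(cols)

    def fit(self, X, y, rng):
        Z = self.scaler.fit_transform(X)
        self.model.fit(self._expand(Z), y)
        return self

    def predict(self, X):
        Z = self.scaler.transform(X)
        return self.model.predict_proba(self._expand(Z))[:, 1]


class _GamModel:
    """Penalized spline additive logistic model; smoothness (the L2 penalty
    on the spline coefficients) chosen by internal cross-validation."""

    def __init__(self, n_knots: int = 6, degree: int = 3):
        self.scaler = StandardScaler()
        self.splines = SplineTransformer(
            n_knots=n_knots, degree=degree, extrapolation="constant"
        )
        self.model = LogisticRegressionCV(
            Cs=np.logspace(-2, 3, 6), cv=3, penalty="l2", max_iter=3000, n_jobs=1
        )

    def fit(self, X, y, rng):
        Z = self.splines.fit_transform(self.scaler.fit_transform(X))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", FutureWarning)
            self.model.fit(Z, y)
        return self

    def predict(self, X):
        Z = self.splines.transform(self.scaler.transform(X))
        return self.model.predict_proba(Z)[:, 1]


class _MarsModel:
    def __init__(self):
        self.model = MarsClassifier()

    def fit(self, X, y, rng):
        self.model.fit(X, y)
        return self

    def predict(self, X):
        return self.model.predict_proba(X)


class _NnModel:
    """Single-hidden-layer perceptron with logistic output, seeded.

    Two stabilisers for presence/absence data: (1) the lbfgs solver lands
    in different local optima per initialisation, which shifts single-axis
    response peaks, so a handful of restarts is averaged; (2) for rare
    species the minority class is upsampled to roughly 1:2 before fitting
    and the predicted probabilities are prior-corrected back to the
    training base rate (p' = p r / (p r + 1 - p) with r the true-to-
    balanced odds ratio), the standard rare-event correction."""

    def __init__(self, hidden: int = 8, n_restarts: int = 9, alpha: float = 0.1):
        self.scaler = StandardScaler()
        self.hidden = hidden
        self.n_restarts = n_restarts
        self.alpha = alpha
        self.nets: list[MLPClassifier] = []
        self._odds_ratio = 1.0

    def fit(self, X, y, rng):
        Z = self.scaler.fit_transform(X)
        y = np.asarray(y)
        pi_true = y.mean()
        pos, neg = np.where(y == 1)[0], np.where(y == 0)[0]
        reps = max(1, int(round(len(neg) / max(len(pos), 1) / 2)))
        idx = np.concatenate([np.tile(pos, reps), neg])
        Zb, yb = Z[idx], y[idx]
        pi_bal = yb.mean()
        self._odds_ratio = ((pi_true / (1 - pi_true))
                            / (pi_bal / (1 - pi_bal)))
        self.nets = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for _ in range(self.n_restarts):
                net = MLPClassifier(
                    hidden_layer_sizes=(self.hidden,),
                    activation="tanh",
                    solver="lbfgs",
                    alpha=self.alpha,
                    max_iter=400,
                    random_state=int(rng.integers(2**31 - 1)),
                )
                net.fit(Zb, yb)
                self.nets.append(net)
        return self

    def predict(self, X):
        Z = self.scaler.transform(X)
        p = np.mean([n.predict_proba(Z)[:, 1] for n in self.nets], axis=0)
        r = self._odds_ratio
        return p * r / (p * r + 1 - p)


class _RfModel:
    def __init__(self, n_estimators: int = 300):
        self.n_estimators = n_estimators
        self.model: RandomForestClassifier | None = None

    def fit(self, X, y, rng):
        seed = int(rng.integers(2**31 - 1))
        self.model = RandomForestClassifier(
            n_estimators=self.n_estimators,
            min_samples_leaf=3,
            random_state=seed,
            n_jobs=1,
        )
        self.model.fit(X, y)
        return self

    def predict(self, X):
        return self.model.predict_proba(X)[:, 1]


_FACTORIES = {
    "GLM": lambda n_presence: _GlmModel(include_interactions=n_presence >= 100),
    "GAM": lambda n_presence: _GamModel(),
    "MARS": lambda n_presence: _MarsModel(),
    "NN": lambda n_presence: _NnModel(),
    "RF": lambda n_presence: _RfModel(),
}


@dataclass
class EnsembleFit:
    """The fitted ensemble for one species plus its training metadata."""

    species: str
    space: CovariateSpace
    models: dict = field(repr=False)
    failed: dict
    n_presence: int
    n_absence: int
    covariate_mins: pd.Series = field(repr=False)
    covariate_maxs: pd.Series = field(repr=False)
    covariate_medians: pd.Series = field(repr=False)
    training_plots: pd.DataFrame = field(repr=False)
    seed: int = 0

    @property
    def prevalence(self) -> float:
        return self.n_presence / (self.n_presence + self.n_absence)

    @property
    def fitted_methods(self) -> tuple[str, ...]:
        return tuple(t for t in METHOD_TAGS if t in self.models)

    def _matrix(self, covariates) -> np.ndarray:
        if isinstance(covariates, pd.DataFrame):
            return covariates[list(self.space.names)].to_numpy(dtype=float)
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[1] != len(self.space.names):
            raise ValueError("covariate rows must have 7 values")
        return X


def fit_ensemble(plots: pd.DataFrame, species: str, space: CovariateSpace,
                 methods=METHOD_TAGS, seed: int = 0,
                 min_class_count: int = 20) -> EnsembleFit:
    """Fit the requested methods to one species' presence/absence data.

    Requires at least ``min_class_count`` presences and absences. A method
    that fails numerically is recorded in ``failed`` and the ensemble
    continues with the rest; stochastic methods draw their seeds from the
    ensemble seed so refits are identical.
    """
    bad = [m for m in methods if m not in METHOD_TAGS]
    if bad:
        raise ValueError(f"unknown method tags {bad}; valid tags are {list(METHOD_TAGS)}")
    col = species_column(species)
    if col not in plots.columns:
        raise KeyError(f"plot table has no presence column {col!r}")
    missing = plots[list(space.names)].isna().any().any()
    if missing:
        raise ValueError("plot table contains missing covariate values")
    y = plots[col].to_numpy()
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("presence column must be strictly binary")
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 < min_class_count or n0 < min_class_count:
        raise ValueError(
            f"species {species!r} has {n1} presences / {n0} absences; "
            f"need at least {min_class_count} of each to fit"
        )
    X = plots[list(space.names)].to_numpy(dtype=float)
    ss = np.random.SeedSequence(seed)
    streams = {tag: np.random.default_rng(s)
               for tag, s in zip(METHOD_TAGS, ss.spawn(len(METHOD_TAGS)))}
    models, failed = {}, {}
    for tag in methods:
        try:
            models[tag] = _FACTORIES[tag](n1).fit(X, y, streams[tag])
        except Exception as exc:  # degrade gracefully, record the failure
            failed[tag] = f"{type(exc).__name__}: {exc}"
    if not models:
        raise RuntimeError(f"all requested methods failed to fit: {failed}")
    cov = plots[list(space.names)]
    return EnsembleFit(
        species=species,
        space=space,
        models=models,
        failed=failed,
        n_presence=n1,
        n_absence=n0,
        covariate_mins=cov.min(),
        covariate_maxs=cov.max(),
        covariate_medians=cov.median(),
        training_plots=plots.copy(),
        seed=seed,
    )


def predict(fit: EnsembleFit, covariates, method: str) -> np.ndarray:
    """Raw probability of presence from one fitted method, clipped to [0, 1]."""
    if method not in fit.models:
        raise KeyError(
            f"method {method!r} not fitted for {fit.species!r}; "
            f"available: {list(fit.models)}"
        )
    X = fit._matrix(covariates)
    return np.clip(fit.models[method].predict(X), 0.0, 1.0)


def ensemble_favorability(fit: EnsembleFit, covariates,
                          methods: tuple[str, ...] | None = None) -> np.ndarray:
    """Per-method favorability rescale, then unweighted average.

    Rescaling is applied per method before averaging (recorded choice);
    ``methods`` defaults to every successfully fitted method.
    """
    tags = fit.fitted_methods if methods is None else tuple(methods)
    tags = tuple(t for t in tags if t in fit.models)
    if not tags:
        raise ValueError("no fitted methods to average over")
    vals = [favorability_rescale(predict(fit, covariates, t),
                                 fit.n_presence, fit.n_absence) for t in tags]
    return np.mean(vals, axis=0)


# ---------------------------------------------------------------------------
# persistence: versioned on-disk bundle (metadata JSON + per-method artifact)
# ---------------------------------------------------------------------------

_BUNDLE_VERSION = 1


def save_fit(fit: EnsembleFit, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "bundle_version": _BUNDLE_VERSION,
        "species": fit.species,
        "methods": list(fit.models),
        "failed": fit.failed,
        "n_presence": fit.n_presence,
        "n_absence": fit.n_absence,
        "prevalence": fit.prevalence,
        "seed": fit.seed,
        "covariate_medians": fit.covariate_medians.to_dict(),
        "covariate_mins": fit.covariate_mins.to_dict(),
        "covariate_maxs": fit.covariate_maxs.to_dict(),
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    joblib.dump(fit.space, out / "space.joblib")
    fit.training_plots.to_csv(out / "training_plots.csv", index=False)
    for tag, model in fit.models.items():
        joblib.dump(model, out / f"method_{tag}.joblib")
    return out


def load_fit(in_dir) -> EnsembleFit:
    src = Path(in_dir)
    meta = json.loads((src / "metadata.json").read_text())
    if meta.get("bundle_version") != _BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {meta.get('bundle_version')}")
    space = joblib.load(src / "space.joblib")
    plots = pd.read_csv(src / "training_plots.csv")
    models = {tag: joblib.load(src / f"method_{tag}.joblib")
              for tag in meta["methods"]}
    cov = plots[list(space.names)]
    return EnsembleFit(
        species=meta["species"],
        space=space,
        models=models,
        failed=meta.get("failed", {}),
        n_presence=meta["n_presence"],
        n_absence=meta["n_absence"],
        covariate_mins=cov.min(),
        covariate_maxs=cov.max(),
        covariate_medians=cov.median(),
        training_plots=plots,
        seed=meta.get("seed", 0),
    )
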