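"""Hold-out AUC machinery, score/AUC joins and loess trends."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from nicheval.ensemble import favorability_rescale
from nicheval.synthetic import generate_plots, make_null_species, sample_occurrences
from nicheval.validation import (
    AucResult,
    auc_holdout,
    rank_auc,
    score_auc_table,
    smoothed_trend,
)


class TestRankAuc:
    def test_matches_trapezoidal_roc_integration_exhaustively(self, rng):
        # independent oracle: sklearn's ROC-curve trapezoid area must equal
        # the Mann-Whitney rank statistic on every random small instance,
        # including heavy ties
        for trial in range(200):
            n = int(rng.integers(4, 20))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = rng.integers(0, 4, n) / 3.0  # few levels -> many ties
            assert rank_auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_perfect_separation_gives_one(self):
        y = np.array([0, 0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        assert rank_auc(y, s) == 1.0

    def test_all_tied_scores_give_half(self):
        y = np.array([0, 1, 0, 1])
        s = np.ones(4)
        assert rank_auc(y, s) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_auc(np.ones(5), np.arange(5))


class TestAucHoldout:
    def test_separable_species_scores_one(self, space):
        # truth is a hard threshold on one covariate: any flexible method
        # separates train and test almost perfectly
        plots = generate_plots(space, 3000, seed=11)
        plots["sp_step"] = (plots["substrate_ph"] > 6.5).astype(int)
        res = auc_holdout(plots, "step", space, "RF", reps=3, seed=12)
        assert res.mean_auc > 0.999

    def test_null_species_auc_near_half(self, space):
        plots = generate_plots(space, 4000, seed=13)
        sp = make_null_species(prob=0.2)
        plots = sample_occurrences(sp, plots, space, seed=14)
        res = auc_holdout(plots, "null_species", space, "GLM", seed=15)
        assert 0.45 <= res.mean_auc <= 0.55

    def test_reps_and_determinism(self, space, plots):
        a = auc_holdout(plots, "rare_unimodal", space, "GLM", reps=4, seed=3)
        b = auc_holdout(plots, "rare_unimodal", space, "GLM", reps=4, seed=3)
        assert len(a.rep_aucs) == 4
        np.testing.assert_array_equal(a.rep_aucs, b.rep_aucs)
        assert a.mean_auc == pytest.approx(np.mean(a.rep_aucs))
        assert a.sqrt_prevalence == pytest.approx(np.sqrt(a.prevalence))

    def test_holdout_not_better_than_in_sample_on_average(self, space):
        # optimism non-negativity: averaged over repetitions, the hold-out
        # AUC does not exceed the in-sample AUC of a fit to all data
        from nicheval.ensemble import fit_ensemble, predict

        plots = generate_plots(space, 1200, seed=21)
        rng = np.random.default_rng(22)
        gaps = []
        for rep in range(20):
            Z = (plots["substrate_ph"] - 5.75) / 1.5
            p = 0.08 + 0.5 * np.exp(-0.5 * (Z / 0.4) ** 2)
            col = f"sp_r{rep}"
            plots[col] = (rng.random(len(plots)) < p).astype(int)
            fit = fit_ensemble(plots, f"r{rep}", space, methods=("GLM",),
                               seed=rep)
            in_auc = rank_auc(plots[col], predict(fit, plots, "GLM"))
            out_auc = auc_holdout(plots, f"r{rep}", space, "GLM", reps=3,
                                  seed=100 + rep).mean_auc
            gaps.append(in_auc - out_auc)
            plots = plots.drop(columns=col)
        assert np.mean(gaps) >= 0

    def test_impossible_split_raises(self, space):
        plots = generate_plots(space, 40, seed=31)
        presence = np.zeros(40, dtype=int)
        presence[0] = 1  # a single presence cannot appear in both halves
        plots["sp_one"] = presence
        with pytest.raises(RuntimeError, match="split"):
            auc_holdout(plots, "one", space, "GLM", reps=2, seed=32,
                        max_retries=5)


def _fake_aucs(mapping):
    return [AucResult(species=s, method=m, rep_aucs=np.array([v]), prevalence=pv)
            for s, (m, v, pv) in mapping.items()]


class TestScoreAucTable:
    def test_disjoint_keys_yield_empty_join_and_full_exclusion(self):
        aucs = _fake_aucs({"a": ("GLM", 0.9, 0.1)})
        scores = pd.DataFrame({"species": ["b"], "axis": ["ph"],
                               "expert": ["E1"], "category": ["good"]})
        joined, missing = score_auc_table(aucs, scores)
        assert joined.empty
        assert missing == ["b"]

    def test_one_species_seven_axes_share_one_mean(self):
        aucs = _fake_aucs({"a": ("GLM", 0.88, 0.2)})
        scores = pd.DataFrame({
            "species": ["a"] * 7,
            "axis": [f"ax{i}" for i in range(7)],
            "expert": ["E1"] * 7,
            "category": ["good"] * 7,
        })
        joined, missing = score_auc_table(aucs, scores)
        assert len(joined) == 7
        assert missing == []
        assert joined["mean_auc"].nunique() == 1
        assert joined["mean_auc"].iloc[0] == pytest.approx(0.88)

    def test_mean_auc_averages_over_methods(self):
        aucs = [AucResult("a", "GLM", np.array([0.8]), 0.1),
                AucResult("a", "RF", np.array([0.9]), 0.1)]
        scores = pd.DataFrame({"species": ["a"], "axis": ["ph"],
                               "expert": ["E1"], "category": ["good"]})
        joined, _ = score_auc_table(aucs, scores)
        assert joined["mean_auc"].iloc[0] == pytest.approx(0.85)

    def test_category_built_from_noisy_auc_orders_trends(self, rng):
        # construction oracle: categories assigned by thresholding a noisy
        # copy of AUC must come out ordered in the smoothed per-category
        # trends
        n = 400
        prev = rng.uniform(0.01, 0.5, n)
        auc = rng.uniform(0.6, 1.0, n)
        noisy = np.clip(auc + rng.normal(0, 0.02, n), 0, 1)
        cat = pd.cut(noisy, [0, 0.7, 0.8, 0.9, 1.0],
                     labels=["poor", "moderate", "good", "excellent"])
        records = pd.DataFrame({"category": cat.astype(str),
                                "mean_auc": auc,
                                "sqrt_prevalence": np.sqrt(prev)})
        trends = smoothed_trend(records)
        means = {c: t["mean_auc"].mean() for c, t in trends.items()}
        assert means["poor"] < means["moderate"] < means["good"] < means["excellent"]


class TestSmoothedTrend:
    def test_constant_records_give_flat_line(self):
        records = pd.DataFrame({"category": ["good"] * 20,
                                "mean_auc": [0.83] * 20,
                                "sqrt_prevalence": np.linspace(0.1, 0.7, 20)})
        trends = smoothed_trend(records)
        np.testing.assert_allclose(trends["good"]["mean_auc"], 0.83)

    def test_linear_trend_recovered_within_five_percent(self, rng):
        x = np.linspace(0.1, 0.7, 60)
        y = 0.6 + 0.4 * x + rng.normal(0, 1e-4, 60)
        records = pd.DataFrame({"category": ["good"] * 60,
                                "mean_auc": y, "sqrt_prevalence": x})
        t = smoothed_trend(records)["good"]
        slope = np.polyfit(t["sqrt_prevalence"], t["mean_auc"], 1)[0]
        assert abs(slope - 0.4) / 0.4 < 0.05

    def test_undersized_group_skipped_with_warning(self):
        records = pd.DataFrame({"category": ["good"] * 12 + ["poor"] * 3,
                                "mean_auc": 0.8,
                                "sqrt_prevalence": np.linspace(0.1, 0.8, 15)})
        with pytest.warns(UserWarning, match="poor"):
            trends = smoothed_trend(records)
        assert set(trends) == {"good"}


class TestAucFavorabilityInvariance:
    def test_auc_identical_after_rescale(self, rng):
        y = rng.integers(0, 2, 500)
        y[0], y[1] = 0, 1
        p = rng.random(500)
        f = favorability_rescale(p, 50, 450)
        assert rank_auc(y, p) == pytest.approx(rank_auc(y, f), abs=1e-12)
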