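"""End-to-end reproducible synthetic campaign: simulate -> fit -> response
artefacts -> hold-out AUC -> (optional) expert-agreement report.

A campaign is driven by a flat key-value config carrying one master seed;
every stochastic stage derives its own seed deterministically from the
master seed and a stage tag, so single stages can be re-run in isolation
and the whole campaign is byte-reproducible.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .elicitation import (CATEGORIES, category_agreement, confusion_matrix,
                          percent_agreement)
from .ensemble import METHOD_TAGS, fit_ensemble
from .response import niche_surface, response_curve
from .synthetic import (CovariateSpace, calibrate_prevalence, default_space,
                        generate_plots, make_bimodal, make_common_unimodal,
                        make_rare_unimodal, sample_occurrences)
from .validation import auc_holdout

__all__ = ["CampaignConfig", "stage_seed", "run_campaign",
           "load_config", "save_config", "ARCHETYPES"]

logger = logging.getLogger("nicheval")

ARCHETYPES = {
    "common_unimodal": make_common_unimodal,
    "rare_unimodal": make_rare_unimodal,
    "bimodal_mire": make_bimodal,
}

DEFAULT_PREVALENCE = {
    "common_unimodal": 0.25,
    "rare_unimodal": 0.05,
    "bimodal_mire": 0.04,
}


def stage_seed(master: int, *tags: str) -> int:
    """Deterministic per-stage seed: master seed combined with a CRC of the
    stage tag path via a SeedSequence; always below 2**31."""
    crc = zlib.crc32("/".join(tags).encode())
    return int(np.random.SeedSequence([master, crc]).generate_state(1)[0] % (2**31))


@dataclass
class CampaignConfig:
    """Configuration of the default synthetic campaign.

    Species are archetype names; target prevalences are applied by exact
    calibration of each species' peak probability over the simulated plot
    table before occurrences are sampled.
    """

    n_plots: int = 5000
    seed: int = 1
    species: tuple[str, ...] = ("common_unimodal", "rare_unimodal", "bimodal_mire")
    methods: tuple[str, ...] = METHOD_TAGS
    prevalence: dict = field(default_factory=lambda: dict(DEFAULT_PREVALENCE))
    n_points_1d: int = 100
    n_grid_2d: int = 50
    auc_reps: int = 10
    surface_axes: tuple[str, str] = ("precipitation", "substrate_ph")
    scores_csv: str = ""
    out_dir: str = "results/campaign"


def save_config(cfg: CampaignConfig, path) -> None:
    pairs = {
        "n_plots": str(cfg.n_plots),
        "seed": str(cfg.seed),
        "species": ", ".join(cfg.species),
        "methods": ", ".join(cfg.methods),
        "n_points_1d": str(cfg.n_points_1d),
        "n_grid_2d": str(cfg.n_grid_2d),
        "auc_reps": str(cfg.auc_reps),
        "surface_axes": ", ".join(cfg.surface_axes),
        "scores_csv": cfg.scores_csv,
        "out_dir": cfg.out_dir,
    }
    for name, p in sorted(cfg.prevalence.items()):
        pairs[f"prevalence.{name}"] = f"{p:.12g}"
    nio.write_keyvalues(pairs, path)


def load_config(path) -> CampaignConfig:
    kv = nio.read_keyvalues(path)
    prev = {k.split(".", 1)[1]: float(v) for k, v in kv.items()
            if k.startswith("prevalence.")}
    return CampaignConfig(
        n_plots=int(kv.get("n_plots", 5000)),
        seed=int(kv.get("seed", 1)),
        species=tuple(s.strip() for s in kv.get("species", "").split(",") if s.strip())
        or CampaignConfig.species,
        methods=tuple(m.strip() for m in kv.get("methods", "").split(",") if m.strip())
        or METHOD_TAGS,
        prevalence=prev or dict(DEFAULT_PREVALENCE),
        n_points_1d=int(kv.get("n_points_1d", 100)),
        n_grid_2d=int(kv.get("n_grid_2d", 50)),
        auc_reps=int(kv.get("auc_reps", 10)),
        surface_axes=tuple(a.strip() for a in kv.get(
            "surface_axes", "precipitation, substrate_ph").split(",")),
        scores_csv=kv.get("scores_csv", ""),
        out_dir=kv.get("out_dir", "results/campaign"),
    )


def simulate_campaign_plots(cfg: CampaignConfig, space: CovariateSpace | None = None):
    """Simulate the campaign plot table with all configured species."""
    space = space or default_space()
    plots = generate_plots(space, cfg.n_plots, stage_seed(cfg.seed, "plots"))
    truths = {}
    for name in cfg.species:
        sp = ARCHETYPES[name](space)
        if name in cfg.prevalence:
            sp = calibrate_prevalence(sp, plots, space, cfg.prevalence[name])
        plots = sample_occurrences(sp, plots, space,
                                   stage_seed(cfg.seed, "occurrences", name))
        truths[name] = sp
    return space, plots, truths


def run_campaign(cfg: CampaignConfig, make_figures: bool = False) -> dict:
    """Execute the full campaign and write all artefacts under
    ``cfg.out_dir``. Returns the summary report (also written as JSON)."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(cfg).items()},
                    "stages": {}}

    def _stage(name):
        logger.info("stage %s", name)
        report["stages"][name] = {"started": time.time() - t0}

    _stage("simulate")
    space, plots, truths = simulate_campaign_plots(cfg)
    nio.save_plots(plots, out / "plots.csv")
    for name, sp in truths.items():
        nio.save_species(sp, out / f"species_{name}.kv")
    report["stages"]["simulate"]["n_plots"] = len(plots)

    _stage("fit")
    fits = {}
    for name in cfg.species:
        fits[name] = fit_ensemble(plots, name, space, methods=cfg.methods,
                                  seed=stage_seed(cfg.seed, "fit", name))
        logger.info("fitted %s: methods=%s failed=%s", name,
                    fits[name].fitted_methods, fits[name].failed)

    _stage("curves")
    curve_rows = []
    for name, fit in fits.items():
        for axis in space.names:
            rc = response_curve(fit, axis, background="median",
                                n_points=cfg.n_points_1d)
            for method, vals in rc.per_method.items():
                for g, v in zip(rc.grid, vals):
                    curve_rows.append((name, axis, method, g, v, rc.background))
            for g, v in zip(rc.grid, rc.average):
                curve_rows.append((name, axis, "average", g, v, rc.background))
    curves_df = pd.DataFrame(curve_rows, columns=[
        "species", "axis", "method", "value", "favorability", "background"])
    nio.save_plots(curves_df, out / "response_curves.csv")
    report["stages"]["curves"]["n_curves"] = int(
        curves_df.groupby(["species", "axis"]).ngroups)

    _stage("surfaces")
    surf_rows = []
    for name, fit in fits.items():
        for background in ("median", "observed"):
            ns = niche_surface(fit, cfg.surface_axes, background=background,
                               n_grid=cfg.n_grid_2d)
            for (x, y), v in zip(ns.points, ns.prediction):
                surf_rows.append((name, *cfg.surface_axes, background, x, y, v))
    surf_df = pd.DataFrame(surf_rows, columns=[
        "species", "axis_x", "axis_y", "background", "x", "y", "favorability"])
    nio.save_plots(surf_df, out / "niche_surfaces.csv")
    report["stages"]["surfaces"]["n_surfaces"] = int(
        surf_df.groupby(["species"]).ngroups)

    _stage("auc")
    auc_rows = []
    for name in cfg.species:
        for method in cfg.methods:
            res = auc_holdout(plots, name, space, method, reps=cfg.auc_reps,
                              seed=stage_seed(cfg.seed, "auc", name, method))
            for rep, a in enumerate(res.rep_aucs, start=1):
                auc_rows.append((name, method, rep, a, res.mean_auc,
                                 res.prevalence))
    auc_df = pd.DataFrame(auc_rows, columns=[
        "species", "method", "rep", "auc", "mean_auc", "prevalence"])
    nio.save_plots(auc_df, out / "holdout_auc.csv")
    report["stages"]["auc"]["n_results"] = int(
        auc_df.groupby(["species", "method"]).ngroups)
    report["stages"]["auc"]["mean_auc_by_species"] = {
        k: round(float(v), 6)
        for k, v in auc_df.groupby("species")["auc"].mean().items()}

    if cfg.scores_csv:
        _stage("agreement")
        scores = nio.load_scores(cfg.scores_csv)
        experts = sorted(scores["expert"].unique())[:2]
        m = confusion_matrix(scores, experts[0], experts[1])
        overall = percent_agreement(m)
        per_cat = {}
        for c in CATEGORIES:
            try:
                per_cat[c] = category_agreement(m, c)
            except ValueError:
                per_cat[c] = None
        report["stages"]["agreement"] = {
            "experts": experts,
            "grand_total": m.grand_total,
            "identical": m.diagonal_total,
            "overall_pct": overall,
            "overall_pct_display": round(overall),
            "per_category_pct": {k: (None if v is None else round(v, 6))
                                 for k, v in per_cat.items()},
            "per_category_pct_display": {k: (None if v is None else round(v))
                                         for k, v in per_cat.items()},
        }
        m.counts.to_csv(out / "confusion_matrix.csv")

    if make_figures:
        _stage("figures")
        _render_figures(fits, cfg, out)

    report["runtime_s"] = round(time.time() - t0, 3)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _render_figures(fits, cfg: CampaignConfig, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    for name, fit in fits.items():
        fig, axes = plt.subplots(2, 4, figsize=(16, 7))
        for ax, axis in zip(axes.ravel(), fit.space.names):
            rc = response_curve(fit, axis, n_points=cfg.n_points_1d)
            for m, vals in rc.per_method.items():
                if m == "RF":
                    continue
                ax.plot(rc.grid, vals, lw=0.8, alpha=0.6, label=m)
            ax.plot(rc.grid, rc.average, lw=2.2, color="saddlebrown", label="average")
            ax.set_title(axis, fontsize=9)
            ax.set_ylim(0, 1)
        axes.ravel()[-1].axis("off")
        axes.ravel()[0].legend(fontsize=7)
        fig.suptitle(f"{name}: rescaled response curves (median background)")
        fig.tight_layout()
        fig.savefig(figdir / f"curves_{name}.png", dpi=110)
        plt.close(fig)

        fig, axs = plt.subplots(1, 2, figsize=(11, 4.5), sharex=True, sharey=True)
        for ax, background in zip(axs, ("observed", "median")):
            ns = niche_surface(fit, cfg.surface_axes, background=background,
                               n_grid=cfg.n_grid_2d)
            sc = ax.scatter(ns.points[:, 0], ns.points[:, 1], c=ns.prediction,
                            s=6, cmap="viridis", vmin=0, vmax=1)
            if not ns.occurrence_envelope.degenerate:
                v = np.vstack([ns.occurrence_envelope.vertices,
                               ns.occurrence_envelope.vertices[:1]])
                ax.plot(v[:, 0], v[:, 1], color="red", lw=1.5)
            if not ns.training_polygon.degenerate:
                v = np.vstack([ns.training_polygon.vertices,
                               ns.training_polygon.vertices[:1]])
                ax.plot(v[:, 0], v[:, 1], color="gray", lw=1.0, ls="--")
            ax.set_title(f"{background} background", fontsize=9)
            ax.set_xlabel(cfg.surface_axes[0])
        axs[0].set_ylabel(cfg.surface_axes[1])
        fig.colorbar(sc, ax=axs, label="favorability")
        fig.suptitle(f"{name}: bivariate niche surface")
        fig.savefig(figdir / f"surface_{name}.png", dpi=110)
        plt.close(fig)
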