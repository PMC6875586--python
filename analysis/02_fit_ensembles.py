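"""Fit the five-method ensemble to each simulated species.

Reads the plot table written by 01_simulate.py, fits GLM / GAM / MARS /
NN / RF per species, reports training prevalence and in-sample AUC per
method, and persists each fitted bundle under results/campaign/fits/.
"""

from pathlib import Path

from nicheval import io as nio
from nicheval.campaign import CampaignConfig, stage_seed
from nicheval.ensemble import fit_ensemble, predict, save_fit
from nicheval.synthetic import default_space, species_column
from nicheval.validation import rank_auc

OUT = Path("results/campaign")


def main() -> None:
    cfg = CampaignConfig(seed=1)
    space = default_space()
    plots = nio.load_plots(OUT / "plots.csv", space)
    for name in cfg.species:
        fit = fit_ensemble(plots, name, space,
                           seed=stage_seed(cfg.seed, "fit", name))
        save_fit(fit, OUT / "fits" / name)
        y = plots[species_column(name)]
        aucs = {m: rank_auc(y, predict(fit, plots, m))
                for m in fit.fitted_methods}
        print(f"{name}: prevalence {fit.prevalence:.4f}; in-sample AUC "
              + ", ".join(f"{m}={a:.3f}" for m, a in aucs.items()))
        if fit.failed:
            print(f"  failed methods: {fit.failed}")


if __name__ == "__main__":
    main()
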