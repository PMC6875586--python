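"""Quantitative fit assessment: repeated 75/25 hold-out AUC.

For each species and method, splits the plot table into random 75% train /
25% test sets ten times, fits on the training part, scores the test part
with the rank (Mann-Whitney) AUC, and averages. Writes the per-repetition
table and prints the species x method means with square-root prevalence.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nicheval import io as nio
from nicheval.campaign import CampaignConfig, stage_seed
from nicheval.synthetic import default_space
from nicheval.validation import auc_holdout

OUT = Path("results/campaign")


def main() -> None:
    cfg = CampaignConfig(seed=1)
    space = default_space()
    plots = nio.load_plots(OUT / "plots.csv", space)
    rows = []
    for name in cfg.species:
        means = {}
        for method in cfg.methods:
            res = auc_holdout(plots, name, space, method, reps=cfg.auc_reps,
                              seed=stage_seed(cfg.seed, "auc", name, method))
            means[method] = res.mean_auc
            rows += [(name, method, i + 1, a, res.mean_auc, res.prevalence)
                     for i, a in enumerate(res.rep_aucs)]
        print(f"{name} (sqrt prevalence {np.sqrt(res.prevalence):.3f}): "
              + ", ".join(f"{m}={v:.3f}" for m, v in means.items()))
    pd.DataFrame(rows, columns=["species", "method", "rep", "auc",
                                "mean_auc", "prevalence"]
                 ).to_csv(OUT / "holdout_auc.csv", index=False,
                          float_format="%.10g")
    print(f"wrote {OUT / 'holdout_auc.csv'}")


if __name__ == "__main__":
    main()
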