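#!/usr/bin/env python
"""Cross-domain structure of the variability indices on the synthetic
cohort: (1) the Spearman correlation matrix across the geometric,
information, and fractal-scaling domains; (2) simple standardized
regressions of each dynamical index against %CV; (3) the fully adjusted
TIR models — TIR ~ core covariates (age, sex, diabetes duration, BMI,
carbohydrate intake, therapy) + %CV + one index — with VIF and
Durbin-Watson diagnostics.

Run analysis/02_per_subject_indices.py first.
"""

import sys
from pathlib import Path

import pandas as pd

from glucodyn.pipeline import INDEX_COLUMNS
from glucodyn.stats import spearman_matrix, standardized_regression, tir_models


def main() -> None:
    path = Path("results/cohort_table.csv")
    if not path.exists():
        sys.exit("run analysis/02_per_subject_indices.py first")
    table = pd.read_csv(path)

    rho, _ = spearman_matrix(table, list(INDEX_COLUMNS))
    rho.round(3).to_csv("results/spearman_rho.csv")
    print("Spearman correlations across domains:")
    print(rho.round(2))

    rows = []
    for index in INDEX_COLUMNS:
        rep = standardized_regression(table, index, ["cv_percent"])
        beta, p = rep.terms["cv_percent"]
        rows.append({"index": index, "beta_vs_cv": beta, "r2_adj": rep.r2_adj, "p": p})
    simple = pd.DataFrame(rows)
    simple.to_csv("results/index_vs_cv.csv", index=False, float_format="%.4f")
    print("\nstandardized beta of each index against %CV:")
    print(simple.round(3).to_string(index=False))

    rows = []
    for index in ("sd1", "sd2", "afe", "complexity_index"):
        rep = tir_models(table, index, subjects="patients")
        rows.append({
            "index": index,
            "beta_index": rep.terms[index][0], "p_index": rep.terms[index][1],
            "beta_cv": rep.terms["cv_percent"][0],
            "r2_adj": rep.r2_adj, "max_vif": max(rep.vif.values()),
            "durbin_watson": rep.durbin_watson, "n": rep.n,
        })
    tir = pd.DataFrame(rows)
    tir.to_csv("results/tir_models.csv", index=False, float_format="%.4f")
    print("\nTIR ~ core model + %CV + index (patients only):")
    print(tir.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
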