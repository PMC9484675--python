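#!/usr/bin/env python
"""Descriptive statistics, threshold ANOVA and correlation matrix.

Reads results/measures_filtered.csv and writes:
  results/descriptives.csv   M/SD/Min/Max/Skewness/Kurtosis per measure
  results/anova.json         repeated-measures ANOVA on the four log
                             thresholds with sphericity diagnostics
  results/correlations.csv   Pearson matrix over g score, thresholds,
                             suppression index and timing measures
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from trpsem.models import BIS_VARS, THRESHOLD_VARS, TIMING_VARS, build_model
from trpsem.sem import factor_scores, fit_ml
from trpsem.stats import corr_matrix, describe, describe_table, rm_anova

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()
    m = pd.read_csv(args.out / "measures_filtered.csv")

    desc = describe_table(m, THRESHOLD_VARS + TIMING_VARS)
    desc.to_csv(args.out / "descriptives.csv")
    si = describe(m["si"])

    res = rm_anova(m[THRESHOLD_VARS].to_numpy())
    (args.out / "anova.json").write_text(json.dumps(
        {k: v for k, v in res.__dict__.items() if np.isscalar(v)},
        indent=1, default=float))

    D = m[BIS_VARS].to_numpy()
    D = (D - D.mean(0)) / D.std(0, ddof=1)
    g_fit = fit_ml(build_model("g_cfa"), np.cov(D, rowvar=False, ddof=1),
                   len(m))
    m["g_score"] = factor_scores(g_fit, D)[:, 0]
    corr = corr_matrix(m, ["g_score"] + THRESHOLD_VARS + ["si"] + TIMING_VARS)
    corr.to_csv(args.out / "correlations.csv")

    print("Descriptives (thresholds in log10 ms):")
    print(desc.round(3).to_string())
    print(f"\nSuppression index: M = {si['mean']:.3f}, SD = {si['sd']:.3f}, "
          f"range {si['min']:.3f} to {si['max']:.3f}")
    print(f"\nThreshold ANOVA: F({res.df1:.2f}, {res.df2:.2f}) = "
          f"{res.F:.2f}, p = {res.p_value_gg:.3g} "
          f"(Greenhouse-Geisser eps = {res.epsilon_gg:.3f}, "
          f"Mauchly p = {res.mauchly_p:.3g})")
    print(f"eta^2 = {res.eta_sq:.3f}, partial = {res.eta_sq_partial:.3f}")
    print("\nCorrelations with the g factor score:")
    print(corr.loc["g_score"].drop("g_score").round(2).to_string())


if __name__ == "__main__":
    main()
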