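#!/usr/bin/env python
"""Validation-cohort PRM analytics for the eight-peptide panel.

Quantifies light/heavy ratios from the simulated transition report (with
automatic interference flagging), runs per-peptide Wilcoxon tests, computes
per-peptide ROC curves with DeLong confidence intervals and the combined
logistic-regression ROC, correlates the neurofilament peptide against a
simulated external immunoassay, and reports the Spearman matrix of the
panel. Writes results/prm_ratios.tsv, results/prm_group_stats.tsv and
results/panel_model.json.

Run 01_simulate_cohorts.py first.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from pepmarker._utils import child_seed
from pepmarker.diffstats import spearman_matrix
from pepmarker.io import read_prm_report, read_sample_sheet
from pepmarker.prm import (
    correlate_external, flag_interference, group_stats, quantify_prm,
    roc_combined,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    dataset = ROOT / "results" / "data" / "validation"
    report = read_prm_report(dataset / "prm_report.csv")
    annotations = read_sample_sheet(dataset / "sample_sheet.tsv")
    panel = [e["peptide_id"]
             for e in json.loads((dataset / "panel.json").read_text())["peptides"]]

    flagged = flag_interference(report)
    if flagged:
        print("transitions flagged for matrix interference and excluded "
              f"from both channels: {flagged}")
    result = quantify_prm(report, panel, exclude_transitions=flagged)
    result.ratios.to_csv(ROOT / "results" / "prm_ratios.tsv", sep="\t",
                         index_label="sample_id")

    stats_table = group_stats(result, annotations)
    stats_table.to_csv(ROOT / "results" / "prm_group_stats.tsv", sep="\t")
    print("\nper-peptide Wilcoxon tests (ALS vs Con):")
    for pep in panel:
        row = stats_table.loc[pep]
        print(f"  {pep:10s} {row['direction']:5s} p = {row['p']:.2g}")

    labels = {a.sample_id: (0 if a.group == "Con" else 1) for a in annotations
              if a.group != "QC"}
    model = roc_combined(np.log2(result.ratios), labels,
                         seed=child_seed(args.seed, "roc"))
    print("\nROC analysis:")
    for pep, r in model.per_peptide_auc.items():
        print(f"  {pep:10s} AUC {100 * r.auc:5.1f}% "
              f"({100 * r.ci_low:.1f}-{100 * r.ci_high:.1f}%)")
    c = model.combined_auc
    print(f"  combined   AUC {100 * c.auc:5.1f}% "
          f"({100 * c.ci_low:.1f}-{100 * c.ci_high:.1f}%)  <- all peptides, "
          "in-sample logistic model")

    rng = np.random.default_rng(child_seed(args.seed, "external"))
    nfl = result.ratios["NFL"]
    external = pd.Series(nfl * rng.lognormal(0, 0.1, len(nfl)),
                         index=nfl.index)
    r_ext, p_ext, pairs = correlate_external(nfl, external)
    print(f"\nNFL peptide vs external immunoassay: Spearman r = {r_ext:.3f} "
          f"(n = {len(pairs)})")

    rmat, _ = spearman_matrix(np.log2(result.ratios))
    payload = {
        "panel": panel,
        "per_peptide_auc_percent": {p: round(100 * r.auc, 2)
                                    for p, r in model.per_peptide_auc.items()},
        "combined_auc_percent": round(100 * c.auc, 2),
        "combined_auc_ci_percent": [round(100 * c.ci_low, 2),
                                    round(100 * c.ci_high, 2)],
        "coefficients": model.coefficients.round(4).to_dict(),
        "nfl_external_spearman_r": round(r_ext, 4),
        "panel_spearman_matrix": rmat.round(3).to_dict(),
        "excluded_transitions": {p: list(t) for p, t in flagged.items()},
    }
    out = ROOT / "results" / "panel_model.json"
    out.write_text(json.dumps(payload, indent=1, sort_keys=True))
    print(f"-> {out}")


if __name__ == "__main__":
    main()
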