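#!/usr/bin/env python
"""Generate the synthetic discovery and validation cohorts.

Writes a discovery-cohort dataset (24 Con / 24 ALS / 3 QC, ~4000 peptides,
56 planted effects with >2-fold changes, tryptic-like detection fractions
0.20 vs 0.25, clinical covariates linked to the first planted peptide) and a
validation-cohort PRM transition report for the published eight-peptide
panel (42 Con / 67 ALS), under results/data/.

Usage: python analysis/01_simulate_cohorts.py [--seed 1]
"""

import argparse
import json
from pathlib import Path

from pepmarker._utils import child_seed
from pepmarker.panel_reference import PANEL_PEPTIDES, panel_records
from pepmarker.sim import (
    ClinicalEffect,
    PanelEntry,
    PRMSimConfig,
    SimConfig,
    generate_peptidome,
    generate_proteome,
    make_annotations,
    planted_effect_table,
    simulate_clinical,
    simulate_cohort,
    simulate_prm,
    write_dataset,
)

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    seed = args.seed

    # --- discovery cohort -------------------------------------------------
    n_peptides = 4000
    effects = planted_effect_table(n_peptides, n_effects=56,
                                   seed=child_seed(seed, "effects"))
    cfg = SimConfig(
        n_proteins=120, n_peptides=n_peptides,
        n_per_group={"Con": 24, "ALS": 24}, n_qc=3,
        effect_table=effects,
        tryptic_like_fraction={"Con": 0.20, "ALS": 0.25},
        clinical_effects=(
            ClinicalEffect("alsfrs_r", effects[0].peptide_id, -0.4),
            ClinicalEffect("qalb", effects[0].peptide_id, 0.6),
        ),
    )
    s = child_seed(seed, "discovery")
    proteins = generate_proteome(cfg.n_proteins, s)
    catalog, state = generate_peptidome(proteins, cfg, s)
    matrix, annotations, state = simulate_cohort(catalog, state, cfg, s)
    annotations = simulate_clinical(annotations, matrix, cfg, s)
    outdir = ROOT / "results" / "data" / "discovery"
    paths = write_dataset(outdir, proteins, catalog, matrix, annotations, state)
    print(f"discovery cohort: {len(catalog)} peptides x "
          f"{matrix.data.shape[1]} samples, {len(effects)} planted effects")
    print(f"  -> {outdir}")

    # --- validation cohort (PRM) -----------------------------------------
    directions = {d["peptide_id"]: d["regulation"] for d in PANEL_PEPTIDES}
    panel_ids = [r.peptide_id for r in panel_records()]
    folds = {p: {"ALS": (3.5 if p == "NFL" else 2.0)
                 if directions[p] == "up" else 0.5} for p in panel_ids}
    up = tuple(p for p in panel_ids if directions[p] == "up")
    down = tuple(p for p in panel_ids if directions[p] == "down")
    panel = [PanelEntry(p, p, tuple(f"y{i}" for i in range(10)), 10.0 + 2 * k)
             for k, p in enumerate(panel_ids)]
    vcfg = SimConfig(n_per_group={"Con": 42, "ALS": 67}, n_qc=0)
    vann = make_annotations(vcfg, child_seed(seed, "valann"))
    prm_cfg = PRMSimConfig(
        fold_by_group=folds, abundance_cv=0.6,
        correlation_groups=(up, down), correlation=0.7,
        interference=(("PENK", "y3", 2.0),),
    )
    report = simulate_prm(panel, vann, prm_cfg, child_seed(seed, "prm"))
    val_dir = ROOT / "results" / "data" / "validation"
    val_dir.mkdir(parents=True, exist_ok=True)
    report.to_csv(val_dir / "prm_report.csv", index=False)
    from pepmarker.io import write_sample_sheet

    write_sample_sheet(vann, val_dir / "sample_sheet.tsv")
    (val_dir / "panel.json").write_text(json.dumps(
        {"peptides": [
            {"peptide_id": p, "protein": next(
                d["entry_name"] for d in PANEL_PEPTIDES if d["peptide_id"] == p),
             "transitions": [f"y{i}" for i in range(10)],
             "reference_rt": 10.0 + 2 * k}
            for k, p in enumerate(panel_ids)]},
        indent=1,
    ))
    print(f"validation cohort: {len(panel_ids)}-peptide PRM panel, "
          f"{len(vann)} samples, one injected transition interference (PENK y3)")
    print(f"  -> {val_dir}")


if __name__ == "__main__":
    main()
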