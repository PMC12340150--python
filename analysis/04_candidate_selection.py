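#!/usr/bin/env python
"""Candidate selection: criteria union, exclusion rules, panel assembly.

Runs the five presence-policy criteria on the discovery cohort and unions
the significant peptides with per-criterion provenance; applies the
exclusion rules (freeze-thaw instability over 100%, blacklisted/blood-
derived proteins) on simulated stability results; and reproduces the
published worked example in which the reviewed edit list turns eleven
label-free candidates into the final eight-peptide, seven-protein panel.
Writes results/candidate_union.tsv and results/exclusion_ledger.tsv.

Run 01_simulate_cohorts.py first.
"""

import argparse
from pathlib import Path

import numpy as np

from pepmarker._utils import child_seed, substream
from pepmarker.candidates import (
    SelectionConfig, apply_exclusions, assemble_panel, run_criteria_union,
)
from pepmarker.diffstats import DiffParams
from pepmarker.io import (
    read_peptide_catalog, read_quant_table, read_sample_sheet,
)
from pepmarker.normqc import NormalizationParams, normalize, stability_assess
from pepmarker.panel_reference import LABELFREE_CANDIDATES, PANEL_EDITS
from pepmarker.sim import STANDARD_IDS

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    dataset = ROOT / "results" / "data" / "discovery"
    matrix = read_quant_table(dataset / "quant_matrix.tsv",
                              standard_ids=STANDARD_IDS)
    annotations = read_sample_sheet(dataset / "sample_sheet.tsv")
    catalog = read_peptide_catalog(dataset / "peptide_catalog.tsv")
    norm = normalize(matrix, NormalizationParams("stdpep", STANDARD_IDS))
    labels = {a.sample_id: a.group for a in annotations if a.group != "QC"}
    quality = {p.peptide_id: p.quality for p in catalog}

    selection = SelectionConfig()
    union = run_criteria_union(
        norm, labels, selection,
        DiffParams(seed=child_seed(args.seed, "union")), quality=quality,
    )
    union.to_csv(ROOT / "results" / "candidate_union.tsv", sep="\t")
    by_n = union["n_criteria"].value_counts().sort_index()
    print(f"criteria union: {len(union)} candidates "
          f"({int((union['n_criteria'] == 5).sum())} found by all five "
          f"criteria; counts by #criteria: {by_n.to_dict()})")

    # simulated freeze-thaw stability screen for the candidates: most are
    # stable (recovery ~100 +- 15%), a few percent are grossly unstable
    rng = substream(args.seed, "stability")
    stability = {}
    for pep in union.index:
        if rng.random() < 0.05:
            recovery = float(rng.uniform(210, 320))
        else:
            recovery = float(rng.normal(100, 8))
        stability[pep] = stability_assess(100.0, recovery, 100.0,
                                          condition="5 cycles")
    kept, ledger = apply_exclusions(list(union.index), selection,
                                    stability=stability)
    ledger.to_csv(ROOT / "results" / "exclusion_ledger.tsv", sep="\t",
                  index=False)
    print(f"exclusions: {len(union) - len(kept)} removed "
          f"({(ledger['rule'] == 'freeze_thaw_instability').sum()} unstable "
          f"after freeze-thaw); {len(kept)} candidates remain")

    panel, edit_log = assemble_panel([p for p, _ in LABELFREE_CANDIDATES],
                                     PANEL_EDITS)
    protein_of = dict(LABELFREE_CANDIDATES)
    protein_of["MAP1B_EA"] = "MAP1B"
    print("published worked example: 11 label-free candidates "
          f"-> {len(panel)} panel peptides from "
          f"{len({protein_of[p] for p in panel})} proteins: {', '.join(panel)}")


if __name__ == "__main__":
    main()
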