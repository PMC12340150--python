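"""Published reference data for the validated ALS CSF peptide panel.

Eight endogenous peptides from seven proteins, validated by targeted PRM in
ALS versus control CSF, with their parent-protein accessions, 1-based
inclusive coordinates and regulation direction. Also the eleven label-free
PRM candidates and the reviewed edit sequence that turned them into the
final eight-peptide panel.

The full parent-protein sequences are not redistributed here; use
:func:`synthetic_parent` to build a synthetic stand-in protein that embeds a
panel peptide at its printed coordinates for coordinate-validation exercises.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from ._utils import substream
from .candidates import PanelEdit
from .io import PeptideRecord, ProteinRecord, parse_modified_sequence

_MOD_MASS = {"trimethylation": 42.05, "acetylation": 42.01, "guanidination": 42.02}


def _record(peptide_id: str, accession: str, entry: str, gene: str,
            modified_sequence: str, start: int, end: int,
            regulation: str) -> dict:
    plain, mods = parse_modified_sequence(modified_sequence)
    return dict(
        peptide_id=peptide_id, accession=accession, entry_name=entry, gene=gene,
        sequence=plain,
        modifications=tuple((pos, name, _MOD_MASS.get(name, float("nan")))
                            for pos, name in mods),
        start=start, end=end, regulation=regulation,
    )


#: the validated panel: peptide id, accession, entry name, gene, sequence
#: (inline modifications), 1-based start/end, regulation direction in ALS
PANEL_PEPTIDES: tuple[dict, ...] = (
    _record("NFL", "P07196", "NFL", "NEFL",
            "SFPSYYTSHVQEEQIEVEETIEAAKAEEA", 438, 466, "up"),
    _record("MAP1B_KE", "P46821", "MAP1B", "MAP1B",
            "KEPKKEIKKLPKDAKKSSTPLS", 726, 747, "up"),
    _record("MAP1B_EA", "P46821", "MAP1B", "MAP1B",
            "EAKKPAALKPKVPKKEESVKKDSVA", 748, 772, "up"),
    _record("MYL1", "P05976", "MYL1", "MYL1",
            "APKKDVKK(trimethylation)PVAAAAAAPAPAPAPAPAPAPAKPKEE", 2, 36, "up"),
    _record("APOC1_SE", "P02654", "APOC1", "APOC1",
            "SETFQKVKEKLKIDS", 69, 83, "up"),
    _record("CADM3", "Q8N126", "CADM3", "CADM3",
            "TLNVNDPSPVPSSSSTY", 313, 329, "down"),
    _record("SCG1", "P05060", "SCG1", "CHGB",
            "EPRAYFMSDTREE", 425, 437, "down"),
    _record("PENK", "P01210", "PENK", "PENK",
            "DGTSTLRENSKPEESHLL", 79, 96, "down"),
)

#: the eleven peptides significant in the label-free PRM screen, with parent
#: protein entry names
LABELFREE_CANDIDATES: tuple[tuple[str, str], ...] = (
    ("NFL", "NFL"),
    ("NFM_DT", "NFM"),
    ("NFM_SP", "NFM"),
    ("CO3_SN", "CO3"),
    ("MYL1", "MYL1"),
    ("APOC1_SE", "APOC1"),
    ("APOC1_TP", "APOC1"),
    ("CADM3", "CADM3"),
    ("SCG1", "SCG1"),
    ("PENK", "PENK"),
    ("MAP1B_KE", "MAP1B"),
)

#: the reviewed edit sequence from the eleven label-free candidates to the
#: final validated panel
PANEL_EDITS: tuple[PanelEdit, ...] = (
    PanelEdit("remove", "NFM_DT", "neurofilaments represented by NFL only",
              "NFM"),
    PanelEdit("remove", "NFM_SP", "neurofilaments represented by NFL only",
              "NFM"),
    PanelEdit("remove", "CO3_SN", "unstable in CSF after freeze-thaw", "CO3"),
    PanelEdit("add", "MAP1B_EA", "second MAP1B peptide to increase protein "
              "coverage", "MAP1B"),
    PanelEdit("remove", "APOC1_TP", "failed the dilution stability test",
              "APOC1"),
)


def panel_records() -> list[PeptideRecord]:
    """The eight panel peptides as :class:`PeptideRecord` (flanks unknown)."""
    out = []
    for d in PANEL_PEPTIDES:
        out.append(
            PeptideRecord(
                peptide_id=d["peptide_id"], accession=d["accession"],
                sequence=d["sequence"], start=d["start"], end=d["end"],
                modifications=d["modifications"],
            )
        )
    return out


def synthetic_parent(record: PeptideRecord, seed: int = 0,
                     tail: int = 12) -> tuple[ProteinRecord, PeptideRecord]:
    """Synthetic stand-in parent protein embedding `record` at its coordinates.

    The real protein sequence is not bundled; outside the peptide span the
    sequence is random, so only coordinate/length/substring checks against
    the printed peptide data are meaningful. Returns the protein and a copy
    of the record with its flanking residues read off the synthetic context.
    """
    rng = substream(seed, f"parent:{record.peptide_id}")
    aa = np.array(list("ACDEFGHILMNPQSTVW"))  # no K/R: neutral flanks
    length = record.end + tail
    seq = rng.choice(aa, size=length)
    seq[record.start - 1 : record.end] = list(record.sequence)
    full = "".join(seq)
    protein = ProteinRecord(
        accession=record.accession, sequence=full,
        entry_name=f"{record.accession}_SYNTHETIC",
    )
    flanked = replace(
        record,
        preceding_residue=full[record.start - 2] if record.start > 1 else None,
        following_residue=full[record.end] if record.end < len(full) else None,
    )
    return protein, flanked
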