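"""Candidate-selection cascade: criteria unions, exclusions, peak QC, panel.

The discovery screen is repeated under five presence policies (three with
down-shift imputation, two minimum-count policies without); significant
peptides are unioned with per-criterion provenance. Exclusion rules then
remove freeze-thaw-unstable peptides (recovery deviating by more than a
configured percentage), blacklisted proteins (albumin) and contaminants
(keratins), and blood-derived-tagged candidates, each removal logged in an
exclusion ledger. Targeted peaks are accepted only when the transition
pattern matches the reference (dotp above threshold with enough transitions)
and the peak co-elutes at the expected retention time. The final panel is an
explicit, reviewed edit list applied to the label-free significant set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import log
from .diffstats import (
    DiffParams,
    IMPUTING_POLICIES,
    PRESENCE_POLICIES,
    impute_gaussian,
    permutation_fdr,
    prepare_matrix,
)
from .io import DataError, QuantMatrix
from .normqc import StabilityResult


@dataclass(frozen=True)
class SelectionConfig:
    criteria: tuple[str, ...] = PRESENCE_POLICIES
    stability_exclusion_limit: float = 100.0  # freeze-thaw |recovery-100| bound
    blacklist_proteins: frozenset[str] = frozenset()
    blood_derived_tags: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.stability_exclusion_limit <= 0:
            raise DataError("stability exclusion limit must be positive")
        if not self.criteria:
            raise DataError("no selection criterion configured")
        for c in self.criteria:
            if c not in PRESENCE_POLICIES:
                raise DataError(f"unknown criterion {c!r}")


@dataclass(frozen=True)
class PeakQCRule:
    min_dotp: float = 0.7  # strict >
    min_transitions: int = 10
    rt_tolerance_min: float = 1.0
    coelution_tolerance_min: float = 0.1
    require_coelution: bool = True

    def __post_init__(self):
        if not 0 <= self.min_dotp <= 1:
            raise DataError("min_dotp must be in [0,1]")


# ---------------------------------------------------------------------------
# criteria union
# ---------------------------------------------------------------------------


def run_criteria_union(
    matrix: QuantMatrix,
    labels: Mapping[str, str],
    selection: SelectionConfig,
    diff_params: DiffParams,
    quality: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Union of significant peptides over the configured presence criteria.

    Returns one row per candidate with the criteria that flagged it, its
    direction under each, and a conflict flag when criteria disagree on
    direction.
    """
    if not selection.criteria:
        raise DataError("no selection criterion configured")
    hits: dict[str, dict] = {}
    for criterion in selection.criteria:
        params = DiffParams(
            s0=diff_params.s0, fdr=diff_params.fdr,
            n_permutations=diff_params.n_permutations,
            impute_width=diff_params.impute_width,
            impute_downshift=diff_params.impute_downshift,
            presence_policy=criterion,
            quality_threshold=diff_params.quality_threshold,
            seed=diff_params.seed,
        )
        logged, lab, _ = prepare_matrix(matrix, labels, params, quality=quality)
        if logged.empty:
            continue
        if criterion in IMPUTING_POLICIES:
            complete = impute_gaussian(logged, params)
        else:
            complete = logged.dropna(axis=0)  # no imputation: complete cases only
        if complete.empty:
            continue
        result = permutation_fdr(complete, lab, params)
        sig = result.table[result.table["significant"]]
        for pep, row in sig.iterrows():
            entry = hits.setdefault(
                pep, {"criteria": [], "directions": [], "log2_difference": []}
            )
            entry["criteria"].append(criterion)
            entry["directions"].append(row["direction"])
            entry["log2_difference"].append(float(row["log2_difference"]))
    rows = []
    for pep, entry in hits.items():
        dirs = set(entry["directions"])
        rows.append(
            {
                "peptide_id": pep,
                "criteria": ";".join(entry["criteria"]),
                "n_criteria": len(entry["criteria"]),
                "direction": entry["directions"][0] if len(dirs) == 1 else "conflict",
                "direction_conflict": len(dirs) > 1,
                "mean_log2_difference": float(np.mean(entry["log2_difference"])),
            }
        )
    out = pd.DataFrame(
        rows, columns=["peptide_id", "criteria", "n_criteria", "direction",
                       "direction_conflict", "mean_log2_difference"]
    )
    return out.set_index("peptide_id") if len(out) else out


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------


def apply_exclusions(
    candidates: Sequence[str],
    selection: SelectionConfig,
    stability: Mapping[str, StabilityResult] | None = None,
    protein_of: Mapping[str, str] | None = None,
    tags: Mapping[str, Sequence[str]] | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Remove unstable / blacklisted / blood-derived candidates, with a ledger."""
    stability = stability or {}
    protein_of = protein_of or {}
    tags = tags or {}
    keep: list[str] = []
    ledger_rows: list[dict] = []
    for pep in candidates:
        stab = stability.get(pep)
        if stab is None:
            log.info("apply_exclusions: no stability result for %s; kept", pep)
        elif abs(stab.recovery_percent - 100.0) > selection.stability_exclusion_limit:
            ledger_rows.append(
                {"peptide_id": pep, "rule": "freeze_thaw_instability",
                 "value": f"recovery {stab.recovery_percent:.1f}% "
                          f"(limit +-{selection.stability_exclusion_limit:.0f}%)"}
            )
            continue
        prot = protein_of.get(pep, "")
        if prot in selection.blacklist_proteins:
            ledger_rows.append(
                {"peptide_id": pep, "rule": "blacklisted_protein", "value": prot}
            )
            continue
        pep_tags = set(tags.get(pep, ()))
        hit = pep_tags & set(selection.blood_derived_tags)
        if hit:
            ledger_rows.append(
                {"peptide_id": pep, "rule": "blood_derived", "value": ";".join(sorted(hit))}
            )
            continue
        keep.append(pep)
    ledger = pd.DataFrame(ledger_rows, columns=["peptide_id", "rule", "value"])
    return keep, ledger


# ---------------------------------------------------------------------------
# peak QC
# ---------------------------------------------------------------------------


def dotp(measured: Sequence[float], reference: Sequence[float]) -> float:
    """Normalized spectral contrast dot product in [0, 1]."""
    m = np.asarray(measured, float)
    r = np.asarray(reference, float)
    if m.shape != r.shape or m.size < 2:
        raise DataError("dotp needs two equal-length vectors of >= 2 transitions")
    if (m < 0).any() or (r < 0).any():
        raise DataError("dotp expects non-negative intensities")
    nm, nr = np.sqrt((m**2).sum()), np.sqrt((r**2).sum())
    if nm == 0 or nr == 0:
        raise DataError("dotp undefined for a zero vector")
    return float((m @ r) / (nm * nr))


@dataclass(frozen=True)
class PeakQCResult:
    passed: bool
    dotp: float
    n_transitions: int
    rt_spread_min: float
    rt_offset_min: float
    failures: tuple[str, ...] = ()


def peak_qc(
    transition_areas: Mapping[str, float],
    transition_rt: Mapping[str, float],
    reference_intensities: Mapping[str, float],
    reference_rt: float,
    rule: PeakQCRule = PeakQCRule(),
) -> PeakQCResult:
    """Accept a targeted peak iff the transition pattern and RT match.

    pass iff dotp > min_dotp AND #transitions >= min_transitions AND max
    pairwise apex-RT spread <= co-elution tolerance AND |apex RT - reference
    RT| <= rt_tolerance. Diagnostics list each failed clause.
    """
    names = [t for t in transition_areas if t in reference_intensities]
    if not names:
        raise DataError("no transitions shared with the reference entry")
    failures: list[str] = []
    n = len(names)
    if n >= 2:
        score = dotp(
            [transition_areas[t] for t in names],
            [reference_intensities[t] for t in names],
        )
    else:
        score = float("nan")
    rts = np.array([transition_rt[t] for t in names if t in transition_rt], float)
    spread = float(rts.max() - rts.min()) if rts.size else float("nan")
    apex = float(np.median(rts)) if rts.size else float("nan")
    offset = abs(apex - reference_rt) if rts.size else float("nan")
    if not score > rule.min_dotp:
        failures.append(f"dotp {score:.3f} <= {rule.min_dotp}")
    if n < rule.min_transitions:
        failures.append(f"transitions {n} < {rule.min_transitions}")
    if rule.require_coelution and not spread <= rule.coelution_tolerance_min:
        failures.append(
            f"co-elution spread {spread:.3f} min > {rule.coelution_tolerance_min}"
        )
    if not offset <= rule.rt_tolerance_min:
        failures.append(f"RT offset {offset:.3f} min > {rule.rt_tolerance_min}")
    return PeakQCResult(
        passed=not failures, dotp=score, n_transitions=n,
        rt_spread_min=spread, rt_offset_min=offset, failures=tuple(failures),
    )


# ---------------------------------------------------------------------------
# panel assembly
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelEdit:
    action: str  # "add" | "remove"
    peptide_id: str
    reason: str
    protein: str = ""

    def __post_init__(self):
        if self.action not in ("add", "remove"):
            raise DataError(f"panel edit action must be add/remove, got {self.action!r}")


def assemble_panel(
    candidates: Sequence[str], edits: Sequence[PanelEdit]
) -> tuple[list[str], pd.DataFrame]:
    """Apply an explicit reviewed edit list to the candidate set, in order."""
    panel = list(dict.fromkeys(candidates))
    rows = []
    for e in edits:
        if e.action == "remove":
            if e.peptide_id not in panel:
                raise DataError(f"cannot remove non-member {e.peptide_id!r}")
            panel.remove(e.peptide_id)
        else:
            if e.peptide_id in panel:
                log.warning("assemble_panel: %s already in panel; "
                            "duplicate addition ignored", e.peptide_id)
            else:
                panel.append(e.peptide_id)
        rows.append({"action": e.action, "peptide_id": e.peptide_id,
                     "protein": e.protein, "reason": e.reason})
    return panel, pd.DataFrame(rows, columns=["action", "peptide_id", "protein",
                                              "reason"])
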