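"""Tryptic-like peptide classification and group comparison.

Endogenous peptides released by basic-residue-directed proteolysis resemble
tryptic products: preceded by K/R in the precursor protein and ending in K/R.
Two policies are supported: ``and`` (both flank conditions, the default) and
``or`` (either suffices). Peptides at the protein N-terminus have no
preceding residue and fail the N-side condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .diffstats import wilcoxon_rank_sum
from .io import DataError, PeptideRecord, QuantMatrix

BASIC = ("K", "R")


@dataclass(frozen=True)
class TrypticPolicy:
    mode: str = "and"  # "and": both flank conditions; "or": either

    def __post_init__(self):
        if self.mode not in ("and", "or"):
            raise DataError(f"tryptic mode must be 'and' or 'or', got {self.mode!r}")


def is_tryptic_like(peptide: PeptideRecord, policy: TrypticPolicy = TrypticPolicy()) -> bool:
    n_side = peptide.preceding_residue in BASIC
    c_side = len(peptide.sequence) > 0 and peptide.sequence[-1] in BASIC
    return (n_side and c_side) if policy.mode == "and" else (n_side or c_side)


def tryptic_counts(
    matrix: QuantMatrix,
    catalog: Sequence[PeptideRecord],
    policy: TrypticPolicy = TrypticPolicy(),
) -> pd.DataFrame:
    """Per-sample count and percent of observed tryptic-like peptides.

    A peptide is observed in a sample when its quantification is non-missing.
    Spike-in standards are not counted.
    """
    by_id = {p.peptide_id: p for p in catalog}
    std = set(matrix.standard_ids)
    pep_ids = [p for p in matrix.peptide_ids if p not in std]
    missing = [p for p in pep_ids if p not in by_id]
    if missing:
        raise DataError(
            f"catalog misses quantified peptide id(s): {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    flags = pd.Series(
        {p: is_tryptic_like(by_id[p], policy) for p in pep_ids}
    )
    observed = matrix.data.loc[pep_ids].notna()
    total = observed.sum(axis=0)
    count = observed.mul(flags, axis=0).sum(axis=0)
    percent = 100.0 * count / total.where(total > 0, other=pd.NA)
    return pd.DataFrame(
        {"observed_peptides": total, "tryptic_like_count": count,
         "tryptic_like_percent": percent.astype(float).fillna(0.0)}
    )


def compare_tryptic(
    stats_by_sample: pd.DataFrame, labels: Mapping[str, str]
) -> dict:
    """Two-sided Wilcoxon p for tryptic count and percent between two groups."""
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise DataError(f"need exactly two groups, got {groups}")
    out: dict = {"groups": groups}
    for col in ("tryptic_like_count", "tryptic_like_percent"):
        a = stats_by_sample.loc[
            [s for s in stats_by_sample.index if labels.get(s) == groups[0]], col
        ]
        b = stats_by_sample.loc[
            [s for s in stats_by_sample.index if labels.get(s) == groups[1]], col
        ]
        out[f"{col}_p"] = wilcoxon_rank_sum(a, b)
        out[f"{col}_medians"] = {groups[0]: float(a.median()),
                                 groups[1]: float(b.median())}
    return out
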