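"""Normalization and analytical QC.

Three normalization modes mirror common peptidomics practice:

* ``none``  — raw peak areas;
* ``tic``   — each sample divided by its total observed signal, rescaled by
  the mean total so magnitudes stay comparable;
* ``stdpep`` — each sample divided by a factor estimated from five spiked-in
  non-human standard peptides: the median over standards of
  (standard area in this sample / that standard's geometric-mean area across
  samples). The median is robust to one aberrant standard; the geometric-mean
  reference makes the factor scale-equivariant, so an injected per-sample
  global factor cancels exactly (up to a constant shared by all samples).

QC metrics (percent CV on the linear scale, identification counts, dynamic
range) and the targeted-assay acceptance rules (recovery within a percent
band, dilution linearity) follow the conventions of targeted MS validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DataError, QuantMatrix, SampleAnnotation


@dataclass(frozen=True)
class NormalizationParams:
    method: str = "stdpep"  # none | tic | stdpep
    standard_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.method not in ("none", "tic", "stdpep"):
            raise DataError(f"unknown normalization method {self.method!r}")
        if self.method == "stdpep" and not self.standard_ids:
            raise DataError("stdpep normalization requires standard ids")


def normalize(matrix: QuantMatrix, params: NormalizationParams) -> QuantMatrix:
    """Normalize a raw matrix; preserves missingness and identities."""
    if matrix.normalization_state != "raw":
        raise DataError(
            f"normalize expects a raw matrix, got {matrix.normalization_state!r}"
        )
    if params.method == "none":
        return matrix.with_data(matrix.data.copy(), "raw")
    data = matrix.data
    if params.method == "tic":
        totals = data.sum(axis=0, skipna=True)
        if (totals <= 0).any() or data.isna().all(axis=0).any():
            bad = data.columns[data.isna().all(axis=0) | (totals <= 0)].tolist()
            raise DataError(f"TIC normalization: all-missing sample(s) {bad}")
        scaled = data.div(totals, axis=1) * totals.mean()
        return matrix.with_data(scaled, "tic")
    # stdpep
    std_ids = [s for s in params.standard_ids if s in data.index]
    if not std_ids:
        raise DataError("none of the standard ids are present in the matrix")
    std = data.loc[std_ids]
    # per-standard geometric mean across samples: under the multiplicative
    # noise model this makes an injected per-sample factor cancel exactly
    # (up to one constant common to all samples)
    ref = np.exp(np.log(std).mean(axis=1, skipna=True))
    ratios = std.div(ref, axis=0)
    factors = ratios.median(axis=0, skipna=True)
    all_missing = std.isna().all(axis=0)
    if all_missing.any():
        bad = std.columns[all_missing].tolist()
        raise DataError(f"stdpep normalization: all standards missing in {bad}")
    scaled = data.div(factors, axis=1)
    return matrix.with_data(scaled, "stdpep")


def compute_cv(values: Sequence[float]) -> float:
    """Percent CV = 100 * sample SD / mean, on the given (linear) scale."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise DataError(f"CV needs >= 2 non-missing values, got {arr.size}")
    mean = arr.mean()
    if mean <= 0:
        raise DataError(f"CV needs positive mean, got {mean}")
    return float(100.0 * arr.std(ddof=1) / mean)


def _cv_rows(df: pd.DataFrame) -> pd.Series:
    """Per-row percent CV over columns; NaN where <2 values or mean<=0."""
    n = df.notna().sum(axis=1)
    mean = df.mean(axis=1, skipna=True)
    sd = df.std(axis=1, ddof=1, skipna=True)
    cv = 100.0 * sd / mean
    cv[(n < 2) | (mean <= 0)] = np.nan
    return cv


def qc_summary(
    matrix: QuantMatrix,
    annotations: Sequence[SampleAnnotation],
) -> dict:
    """QC report: ID counts, per-peptide CVs in QC replicates, standard CVs."""
    qc_samples = [a.sample_id for a in annotations if a.group == "QC"]
    study_samples = [a.sample_id for a in annotations if a.group != "QC"]
    if not qc_samples:
        raise DataError("no QC samples flagged in annotations")
    data = matrix.data
    std_ids = [s for s in matrix.standard_ids if s in data.index]
    endo = data.drop(index=std_ids)

    id_counts = endo.notna().sum(axis=0)
    report: dict = {
        "normalization": matrix.normalization_state,
        "id_counts": id_counts.to_dict(),
        "id_count_cv_percent": compute_cv(id_counts.to_numpy(float)),
    }
    qc = endo[qc_samples]
    complete = qc.dropna(axis=0)
    pep_cv = _cv_rows(complete) if len(complete) else pd.Series(dtype=float)
    report["qc_peptide_cv_median_percent"] = (
        float(pep_cv.median()) if len(pep_cv) else float("nan")
    )
    report["n_peptides_in_all_qc"] = int(len(complete))
    if std_ids:
        report["standard_cv_qc_percent"] = (
            _cv_rows(data.loc[std_ids, qc_samples]).to_dict()
        )
        if study_samples:
            report["standard_cv_study_percent"] = (
                _cv_rows(data.loc[std_ids, study_samples]).to_dict()
            )
    return report


def dynamic_range(matrix: QuantMatrix) -> tuple[float, pd.DataFrame]:
    """log10(max/min) of per-peptide mean abundances + rank-abundance curve."""
    means = matrix.data.mean(axis=1, skipna=True)
    means = means[means > 0]
    if len(means) < 2:
        raise DataError("dynamic range needs >= 2 peptides with positive mean")
    orders = float(np.log10(means.max() / means.min()))
    curve = (
        means.sort_values(ascending=False)
        .rename("mean_abundance")
        .rename_axis("peptide_id")
        .reset_index()
    )
    curve["rank"] = np.arange(1, len(curve) + 1)
    curve["log10_mean"] = np.log10(curve["mean_abundance"])
    return orders, curve[["rank", "peptide_id", "mean_abundance", "log10_mean"]]


@dataclass(frozen=True)
class StabilityResult:
    condition: str
    recovery_percent: float
    limit_percent: float
    passed: bool


def stability_assess(
    reference_value: float, treated_value: float, limit_percent: float = 30.0,
    condition: str = "",
) -> StabilityResult:
    """Recovery = 100 * treated/reference; pass iff |recovery-100| < limit."""
    if reference_value <= 0:
        raise DataError(f"reference must be positive, got {reference_value}")
    recovery = 100.0 * treated_value / reference_value
    passed = abs(recovery - 100.0) < limit_percent  # strict at the bound
    return StabilityResult(condition, float(recovery), float(limit_percent), passed)


def dilution_linearity(
    series: Sequence[tuple[float, float]], limit_percent: float = 20.0
) -> tuple[float, bool, pd.DataFrame]:
    """Deviation of back-calculated values from the undiluted point.

    `series` holds (dilution factor, measured value); factor 1 = undiluted.
    deviation_i = 100 * |measured_i * factor_i - undiluted| / undiluted;
    pass iff every deviation < limit (strict).
    """
    factors = np.array([f for f, _ in series], float)
    values = np.array([v for _, v in series], float)
    if (factors < 1).any():
        raise DataError("dilution factors must be >= 1")
    if not np.isclose(factors, 1.0).any():
        raise DataError("series must include the undiluted point (factor 1)")
    undiluted = float(values[np.isclose(factors, 1.0)][0])
    if undiluted <= 0:
        raise DataError("undiluted measurement must be positive")
    deviation = 100.0 * np.abs(values * factors - undiluted) / undiluted
    table = pd.DataFrame(
        {"dilution_factor": factors, "measured": values,
         "deviation_percent": deviation}
    )
    mask = ~np.isclose(factors, 1.0)
    max_dev = float(deviation[mask].max()) if mask.any() else 0.0
    return max_dev, bool(max_dev < limit_percent), table
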