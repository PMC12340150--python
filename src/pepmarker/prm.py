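"""Validation-cohort analytics for a targeted PRM panel.

Each panel peptide is co-measured with its stable-isotope-labeled standard
("heavy" channel); the quantity reported per sample is the light-to-heavy
ratio of summed transition areas. Transitions flagged for matrix
interference are excluded symmetrically from both channels. Downstream:
nonparametric group statistics, per-peptide ROC with DeLong confidence
intervals, a combined logistic-regression panel classifier, and correlation
against an external assay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import log, substream
from .diffstats import kruskal_dunn, spearman_matrix, wilcoxon_rank_sum
from .io import DataError, SampleAnnotation


@dataclass
class PRMResult:
    ratios: pd.DataFrame  # samples x peptides, L/H ratio, NaN = missing
    missing_reason: pd.DataFrame  # samples x peptides, "" when present
    excluded_transitions: dict[str, tuple[str, ...]] = field(default_factory=dict)


def flag_interference(
    report: pd.DataFrame,
    threshold_mads: float = 5.0,
    min_ratio_deviation: float = 1.5,
) -> dict[str, tuple[str, ...]]:
    """Propose transitions with matrix interference, per peptide.

    For each peptide the per-transition log light/heavy ratio is summarized
    across samples (median); a transition is flagged when its summary
    deviates from the peptide's overall median by more than `threshold_mads`
    times the MAD of transition summaries AND by at least a factor of
    `min_ratio_deviation` (the floor stops clean but very precise assays
    from being flagged on tiny fluctuations). Requires >= 4 transitions.
    """
    out: dict[str, tuple[str, ...]] = {}
    floor = np.log(min_ratio_deviation)
    wide = _lh_by_transition(report)
    for pep, grp in wide.groupby(level="peptide_id"):
        med = grp.groupby(level="transition").median()
        if len(med) < 4:
            continue
        center = med.median()
        mad = float(np.median(np.abs(med - center)))
        dev = np.abs(med - center)
        bad = med.index[(dev > max(threshold_mads * mad, 1e-12)) & (dev > floor)]
        if len(bad):
            out[pep] = tuple(sorted(bad))
    return out


def _lh_by_transition(report: pd.DataFrame) -> pd.Series:
    """log L/H per (peptide, transition, sample) where both channels exist."""
    pivot = report.pivot_table(
        index=["peptide_id", "transition", "sample_id"],
        columns="channel", values="area", aggfunc="sum",
    )
    if "light" not in pivot or "heavy" not in pivot:
        return pd.Series(dtype=float)
    both = pivot.dropna()
    return np.log((both["light"] / both["heavy"]).astype(float))


def quantify_prm(
    report: pd.DataFrame,
    panel: Sequence[str],
    exclude_transitions: Mapping[str, Sequence[str]] | None = None,
) -> PRMResult:
    """Per sample x peptide L/H ratio from summed retained transition areas.

    A peptide with heavy signal but no light transitions in a sample is
    missing with reason "no peak" (endogenous peptide below limit). A peptide
    present in the light channel but lacking its heavy standard is an assay
    failure and raises.
    """
    exclude = {p: set(t) for p, t in (exclude_transitions or {}).items()}
    samples = sorted(report["sample_id"].unique())
    panel = list(panel)
    ratios = pd.DataFrame(np.nan, index=samples, columns=panel)
    reasons = pd.DataFrame("", index=samples, columns=panel)
    grouped = report.groupby(["peptide_id", "sample_id"])
    seen = set()
    for (pep, smp), grp in grouped:
        if pep not in set(panel):
            continue
        seen.add((pep, smp))
        drop = exclude.get(pep, set())
        grp = grp[~grp["transition"].isin(drop)]  # symmetric: both channels
        light = grp.loc[grp["channel"] == "light", "area"]
        heavy = grp.loc[grp["channel"] == "heavy", "area"]
        if heavy.empty or heavy.sum() <= 0:
            if not light.empty:
                raise DataError(
                    f"heavy channel absent for peptide {pep!r} in sample "
                    f"{smp!r}: assay failure"
                )
            reasons.loc[smp, pep] = "no data"
            continue
        if light.empty or light.sum() <= 0:
            reasons.loc[smp, pep] = "no peak"
            continue
        ratios.loc[smp, pep] = float(light.sum() / heavy.sum())
    for pep in panel:
        for smp in samples:
            if (pep, smp) not in seen and reasons.loc[smp, pep] == "":
                reasons.loc[smp, pep] = "no data"
    return PRMResult(
        ratios=ratios, missing_reason=reasons,
        excluded_transitions={p: tuple(sorted(t)) for p, t in exclude.items()},
    )


# ---------------------------------------------------------------------------
# group statistics
# ---------------------------------------------------------------------------


def group_stats(
    result: PRMResult, annotations: Sequence[SampleAnnotation],
    groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-peptide rank tests across the annotated groups.

    Two groups: two-sided Wilcoxon rank-sum. More: Kruskal-Wallis omnibus +
    Dunn pairwise (Holm-adjusted); the table then carries the omnibus p and a
    dict of pairwise adjusted p. Missing ratios are excluded pairwise with
    counts reported; a peptide absent in a whole group is reported, not run.
    """
    by_group: dict[str, list[str]] = {}
    for a in annotations:
        if groups is not None and a.group not in groups:
            continue
        if a.group == "QC":
            continue
        by_group.setdefault(a.group, []).append(a.sample_id)
    if len(by_group) < 2:
        raise DataError(f"need >= 2 groups, got {sorted(by_group)}")
    rows = []
    for pep in result.ratios.columns:
        vals = {
            g: result.ratios.loc[[s for s in ss if s in result.ratios.index], pep]
            .dropna()
            for g, ss in by_group.items()
        }
        counts = {g: int(v.size) for g, v in vals.items()}
        empty = [g for g, v in vals.items() if v.size < 2]
        row: dict = {"peptide_id": pep, "n_per_group": counts}
        if empty:
            row.update(p=np.nan, direction="untested",
                       note=f"group(s) {empty} have <2 present values")
            rows.append(row)
            continue
        medians = {g: float(v.median()) for g, v in vals.items()}
        names = sorted(vals)
        if "Con" in names:
            others = [g for g in names if g != "Con"]
            pooled_other = float(np.median(np.concatenate(
                [vals[g].to_numpy() for g in others])))
            direction = "up" if pooled_other > medians["Con"] else "down"
        else:
            direction = "up" if medians[names[0]] < medians[names[-1]] else "down"
        if len(vals) == 2:
            g1, g2 = names
            row["p"] = wilcoxon_rank_sum(vals[g1], vals[g2])
        else:
            omnibus, pairs = kruskal_dunn({g: vals[g].to_numpy() for g in names})
            row["p"] = omnibus
            row["pairwise_p_adjusted"] = {
                f"{r.group_1}|{r.group_2}": float(r.p_adjusted)
                for r in pairs.itertuples()
            }
        row["direction"] = direction
        row["medians"] = medians
        rows.append(row)
    return pd.DataFrame(rows).set_index("peptide_id")


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def _auc_mann_whitney(values: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank/Mann-Whitney identity with tie averaging."""
    pos = values[labels == 1]
    neg = values[labels == 0]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    u = r_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _delong_variance(values: np.ndarray, labels: np.ndarray) -> float:
    """DeLong variance of the AUC estimator (single-classifier case)."""
    pos = values[labels == 1]
    neg = values[labels == 0]
    m, n = pos.size, neg.size
    # placement values via mid-ranks (handles ties)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v01 = (all_ranks[:m] - pos_ranks) / n  # per-positive placements
    v10 = 1.0 - (all_ranks[m:] - neg_ranks) / m  # per-negative placements
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return float(s01 / m + s10 / n)


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    orientation: int  # +1: larger value -> positive class; -1: flipped
    n_positive: int
    n_negative: int


def roc_single(
    values: Sequence[float], labels: Sequence[int], ci: float = 0.95
) -> ROCResult:
    """Rank-based AUC with a DeLong confidence interval.

    Orientation is chosen so the reported AUC >= 0.5; the sign is recorded.
    Missing values are dropped pairwise.
    """
    v = np.asarray(values, float)
    y = np.asarray(labels, int)
    keep = ~np.isnan(v)
    v, y = v[keep], y[keep]
    classes = set(y.tolist())
    if classes != {0, 1}:
        raise DataError(f"labels must contain both classes 0/1, got {sorted(classes)}")
    if (y == 1).sum() < 3 or (y == 0).sum() < 3:
        raise DataError("roc_single needs >= 3 observations per class")
    auc = _auc_mann_whitney(v, y)
    orientation = 1
    if auc < 0.5:
        orientation = -1
        v = -v
        auc = _auc_mann_whitney(v, y)
    var = _delong_variance(v, y)
    z = stats.norm.ppf(0.5 + ci / 2.0)
    half = z * np.sqrt(var)
    return ROCResult(
        auc=float(auc), ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)), orientation=orientation,
        n_positive=int((y == 1).sum()), n_negative=int((y == 0).sum()),
    )


# ---------------------------------------------------------------------------
# combined logistic panel model
# ---------------------------------------------------------------------------


@dataclass
class PanelModel:
    peptide_ids: tuple[str, ...]
    coefficients: pd.Series  # on standardized log2 ratios
    intercept: float
    per_peptide_auc: dict[str, ROCResult]
    combined_auc: ROCResult
    fitted_probabilities: pd.Series
    ridge_used: bool
    n_samples_used: int
    dropped_samples: tuple[str, ...] = ()


def _fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Binary logistic MLE via statsmodels; tiny ridge IRLS on separation."""
    import statsmodels.api as sm

    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        beta = np.asarray(fit.params, float)
        converged = bool(fit.mle_retvals.get("converged", False))
        if converged and np.all(np.isfinite(beta)) and np.abs(beta).max() < 1e3:
            return beta, False
    except Exception:  # perfect separation raises in statsmodels
        pass
    beta = _ridge_irls(Xc, y, alpha=1e-6)
    log.info("roc_combined: separation detected; tiny ridge (1e-6) engaged")
    return beta, True


def _ridge_irls(X: np.ndarray, y: np.ndarray, alpha: float,
                max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    beta = np.zeros(X.shape[1])
    pen = alpha * np.eye(X.shape[1])
    pen[0, 0] = 0.0  # intercept unpenalized
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        z = eta + (y - p) / w
        A = X.T @ (w[:, None] * X) + pen
        new = np.linalg.solve(A, X.T @ (w * z))
        if np.max(np.abs(new - beta)) < tol:
            beta = new
            break
        beta = new
    if not np.all(np.isfinite(beta)):
        raise DataError("logistic fit did not converge even with ridge")
    return beta


def roc_combined(
    log2_ratios: pd.DataFrame,
    labels: Mapping[str, int],
    seed: int = 0,
    max_missing_fraction: float = 0.3,
    missing: str = "listwise",
) -> PanelModel:
    """Combined panel classifier: logistic regression on standardized log2 ratios.

    Samples are rows, panel peptides columns. Peptides missing in more than
    `max_missing_fraction` of samples are rejected. Missing values are
    handled by listwise deletion (reported) or median fill (flagged). The
    combined ROC uses the in-sample fitted probabilities; per-peptide AUCs
    are computed on the same sample set.
    """
    peptides = list(log2_ratios.columns)
    miss_frac = log2_ratios.isna().mean()
    too_missing = miss_frac[miss_frac > max_missing_fraction]
    if len(too_missing):
        raise DataError(
            f"peptide(s) exceed {max_missing_fraction:.0%} missingness: "
            f"{too_missing.round(2).to_dict()}"
        )
    df = log2_ratios.copy()
    dropped: tuple[str, ...] = ()
    if missing == "listwise":
        complete = df.dropna(axis=0)
        dropped = tuple(s for s in df.index if s not in complete.index)
        if dropped:
            log.info("roc_combined: listwise deletion dropped %d sample(s): %s",
                     len(dropped), list(dropped))
        df = complete
    elif missing == "median":
        log.warning("roc_combined: median fill of missing ratios (flagged)")
        df = df.fillna(df.median())
    else:
        raise DataError(f"unknown missing policy {missing!r}")
    y = np.array([labels[s] for s in df.index], int)
    if len(set(y.tolist())) != 2:
        raise DataError("labels must contain both classes after deletion")
    X = df.to_numpy(float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    beta, ridge_used = _fit_logistic(Z, y)
    eta = np.clip(beta[0] + Z @ beta[1:], -30, 30)
    prob = 1.0 / (1.0 + np.exp(-eta))
    combined = roc_single(prob, y)
    per_pep = {
        pep: roc_single(df[pep].to_numpy(float), y) for pep in peptides
    }
    return PanelModel(
        peptide_ids=tuple(peptides),
        coefficients=pd.Series(beta[1:], index=peptides),
        intercept=float(beta[0]),
        per_peptide_auc=per_pep,
        combined_auc=combined,
        fitted_probabilities=pd.Series(prob, index=df.index),
        ridge_used=ridge_used,
        n_samples_used=int(len(df)),
        dropped_samples=dropped,
    )


# ---------------------------------------------------------------------------
# external assay correlation
# ---------------------------------------------------------------------------


def correlate_external(
    peptide_values: pd.Series, external_values: pd.Series
) -> tuple[float, float, pd.DataFrame]:
    """Spearman r (+p) between a panel peptide and an external assay."""
    pairs = pd.DataFrame(
        {"peptide": peptide_values, "external": external_values}
    ).dropna()
    if len(pairs) < 3:
        raise DataError(f"need >= 3 complete pairs, got {len(pairs)}")
    res = stats.spearmanr(pairs["peptide"], pairs["external"])
    return float(res.statistic), float(res.pvalue), pairs
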