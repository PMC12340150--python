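"""Discovery-cohort statistics.

The differential test is an s0-moderated two-sample Student statistic with a
permutation-based false-discovery estimate (SAM/Perseus style):

    d_i = (mean_A - mean_B) / (se_pooled + s0)

where ``se_pooled`` is the pooled-variance two-sample standard error and the
small positive constant ``s0`` damps the significance of tiny-variance
peptides. The null distribution is generated by re-drawing balanced label
permutations; for a threshold |d| the estimated FDR is

    q(d) = E_perm[ #{null |d*| >= |d|} ] / #{observed |d'| >= |d|}

monotonized to be non-increasing in |d| and capped at 1.

Supporting steps: presence filtering with >=70% / >=3-per-group policies,
per-column Gaussian down-shift imputation of left-censored missing values
(mean - downshift*sd, width*sd), rank tests (Wilcoxon rank-sum,
Kruskal-Wallis + Dunn post hoc with Holm adjustment), Spearman correlation
matrices, and a separation summary (Ward clustering specificity + PCA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA

from ._utils import log, substream
from .io import DataError, QuantMatrix

PRESENCE_POLICIES = (
    "in_70pct_each_group",
    "in_70pct_any_group",
    "in_70pct_all",
    "min3_each_group",
    "min3_any_group",
)

#: policies whose retained peptides may still contain missing values and are
#: therefore analyzed after down-shift imputation
IMPUTING_POLICIES = ("in_70pct_each_group", "in_70pct_any_group", "in_70pct_all")


@dataclass(frozen=True)
class DiffParams:
    s0: float = 0.1
    fdr: float = 0.05
    n_permutations: int = 250
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    presence_policy: str = "in_70pct_any_group"
    quality_threshold: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fdr < 1:
            raise DataError(f"fdr must be in (0,1), got {self.fdr}")
        if self.n_permutations < 1:
            raise DataError("n_permutations must be >= 1")
        if self.impute_width <= 0:
            raise DataError("impute_width must be positive")
        if self.presence_policy not in PRESENCE_POLICIES:
            raise DataError(f"unknown presence policy {self.presence_policy!r}")


# ---------------------------------------------------------------------------
# filtering & imputation
# ---------------------------------------------------------------------------


def prepare_matrix(
    matrix: QuantMatrix,
    labels: Mapping[str, str],
    params: DiffParams,
    quality: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, Mapping[str, str], dict]:
    """Quality + presence filtering and log2 transform.

    `labels` maps sample id -> group label; exactly two groups are compared.
    Presence bounds use >= semantics (17/24 = 70.8% passes a 70% policy).
    Returns (log2 matrix restricted to compared samples, labels, drop report).
    """
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise DataError(f"need exactly two groups, got {groups}")
    samples = [s for s in matrix.sample_ids if s in labels]
    data = matrix.data[samples]
    std = set(matrix.standard_ids)
    data = data.loc[[p for p in data.index if p not in std]]
    report: dict = {"n_input": int(len(data))}

    if quality is not None:
        q = pd.Series({p: quality.get(p, np.nan) for p in data.index})
        keep = q >= params.quality_threshold
        report["dropped_quality"] = int((~keep).sum())
        data = data.loc[keep[keep].index]
    else:
        report["dropped_quality"] = 0

    by_group = {g: [s for s in samples if labels[s] == g] for g in groups}
    counts = {g: data[ss].notna().sum(axis=1) for g, ss in by_group.items()}
    n_g = {g: len(ss) for g, ss in by_group.items()}
    policy = params.presence_policy
    if policy == "in_70pct_each_group":
        keep = np.logical_and(
            *[counts[g] >= 0.7 * n_g[g] for g in groups]
        )
    elif policy == "in_70pct_any_group":
        keep = np.logical_or(*[counts[g] >= 0.7 * n_g[g] for g in groups])
    elif policy == "in_70pct_all":
        total = sum(counts[g] for g in groups)
        keep = total >= 0.7 * sum(n_g.values())
    elif policy == "min3_each_group":
        keep = np.logical_and(*[counts[g] >= 3 for g in groups])
    else:  # min3_any_group
        keep = np.logical_or(*[counts[g] >= 3 for g in groups])
    report["dropped_presence"] = int((~keep).sum())
    data = data.loc[keep[keep].index]
    report["n_retained"] = int(len(data))
    if len(data) == 0:
        log.warning("prepare_matrix: no peptides retained (%s)", report)
    with np.errstate(divide="ignore"):
        logged = np.log2(data)
    logged[data <= 0] = np.nan
    return logged, dict(labels), report


def impute_gaussian(
    log2_matrix: pd.DataFrame, params: DiffParams, seed: int | None = None
) -> pd.DataFrame:
    """Per-column down-shift imputation of missing log2 values.

    Missing entries of each sample are drawn from
    Normal(mean_col - downshift * sd_col, (width * sd_col)^2) computed over
    that column's observed values; observed entries are untouched. Columns
    with <2 observed values fall back (flagged) to the global distribution.
    """
    rng = substream(seed if seed is not None else params.seed, "impute")
    out = log2_matrix.copy()
    obs_all = log2_matrix.to_numpy().ravel()
    obs_all = obs_all[~np.isnan(obs_all)]
    g_mean = obs_all.mean() if obs_all.size else 0.0
    g_sd = obs_all.std(ddof=1) if obs_all.size > 1 else 1.0
    for col in out.columns:
        vals = out[col]
        mask = vals.isna()
        if not mask.any():
            continue
        observed = vals[~mask]
        if len(observed) < 2:
            log.warning(
                "impute_gaussian: column %s has %d observed values; "
                "falling back to the global distribution", col, len(observed)
            )
            mu, sd = g_mean, g_sd
        else:
            mu, sd = observed.mean(), observed.std(ddof=1)
        draw = rng.normal(
            mu - params.impute_downshift * sd,
            params.impute_width * sd,
            size=int(mask.sum()),
        )
        out.loc[mask, col] = draw
    return out


# ---------------------------------------------------------------------------
# s0 statistic & permutation FDR
# ---------------------------------------------------------------------------


def s0_t_test(
    group_a: np.ndarray, group_b: np.ndarray, s0: float = 0.1
) -> tuple[float, float]:
    """(difference, statistic) for one peptide; scalar front-end of the test."""
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size < 2 or b.size < 2:
        raise DataError("s0_t_test needs >= 2 values per group")
    diff, stat = _s0_stats(a[None, :], b[None, :], s0)
    return float(diff[0]), float(stat[0])


def _s0_stats(a: np.ndarray, b: np.ndarray, s0: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized s0 statistic over rows of (p x nA), (p x nB) arrays."""
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    diff = mean_a - mean_b
    denom = se + s0
    if s0 == 0 and np.any(denom == 0):
        raise DataError("degenerate variance with s0=0 gives an infinite statistic")
    return diff, diff / denom


@dataclass
class DifferentialResult:
    table: pd.DataFrame  # columns: log2_difference, statistic, q_value,
    #                      significant, direction
    params: DiffParams = field(default_factory=DiffParams)
    n_permutations_used: int = 0

    @property
    def significant_ids(self) -> list[str]:
        return self.table.index[self.table["significant"]].tolist()


def permutation_fdr(
    log2_matrix: pd.DataFrame,
    labels: Mapping[str, str],
    params: DiffParams,
) -> DifferentialResult:
    """s0-moderated test with permutation-based FDR over a complete matrix.

    The difference is mean(first group) - mean(second group) with groups in
    sorted label order, except that ('Con', 'ALS')-style designs report
    disease minus control (any non-'Con' group minus 'Con').
    """
    if log2_matrix.isna().any().any():
        raise DataError("permutation_fdr expects a complete (imputed) matrix")
    groups = sorted(set(labels.values()))
    if len(groups) != 2:
        raise DataError(f"need exactly two groups, got {groups}")
    if "Con" in groups:  # report disease-minus-control
        g_b = "Con"
        g_a = next(g for g in groups if g != "Con")
    else:
        g_a, g_b = groups
    cols = list(log2_matrix.columns)
    idx_a = [i for i, s in enumerate(cols) if labels[s] == g_a]
    idx_b = [i for i, s in enumerate(cols) if labels[s] == g_b]
    X = log2_matrix.to_numpy(float)
    obs_diff, obs_stat = _s0_stats(X[:, idx_a], X[:, idx_b], params.s0)
    obs_abs = np.abs(obs_stat)

    n = len(idx_a) + len(idx_b)
    n_arrangements = math.comb(n, len(idx_a))
    rng = substream(params.seed, "permutation_fdr")
    all_cols = np.array(idx_a + idx_b)
    if params.n_permutations >= n_arrangements:
        log.info(
            "permutation_fdr: %d permutations requested but only %d distinct "
            "arrangements; enumerating all", params.n_permutations, n_arrangements
        )
        perm_sets = [np.array(c) for c in combinations(all_cols, len(idx_a))]
    else:
        perm_sets = [
            rng.permutation(all_cols)[: len(idx_a)]
            for _ in range(params.n_permutations)
        ]
    null_abs = np.empty((len(perm_sets), X.shape[0]))
    colset = set(all_cols.tolist())
    for k, pa in enumerate(perm_sets):
        pb = np.array(sorted(colset - set(pa.tolist())))
        _, stat = _s0_stats(X[:, pa], X[:, pb], params.s0)
        null_abs[k] = np.abs(stat)

    order = np.argsort(-obs_abs, kind="stable")
    sorted_abs = obs_abs[order]
    # observed count with |stat| >= threshold is just the rank (ties handled
    # by counting all observed >= value)
    n_obs_ge = np.searchsorted(-sorted_abs, -sorted_abs, side="right")
    flat_null = np.sort(null_abs.ravel())
    n_null_ge = flat_null.size - np.searchsorted(flat_null, sorted_abs, side="left")
    mean_null_ge = n_null_ge / len(perm_sets)
    fdr_raw = np.minimum(mean_null_ge / np.maximum(n_obs_ge, 1), 1.0)
    q_sorted = np.minimum.accumulate(fdr_raw[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted

    significant = q <= params.fdr
    direction = np.where(
        significant & (obs_diff > 0), "up",
        np.where(significant & (obs_diff < 0), "down", "ns"),
    )
    table = pd.DataFrame(
        {
            "log2_difference": obs_diff,
            "statistic": obs_stat,
            "q_value": q,
            "significant": significant,
            "direction": direction,
        },
        index=log2_matrix.index,
    )
    table.attrs["group_a"] = g_a
    table.attrs["group_b"] = g_b
    return DifferentialResult(table, params, len(perm_sets))


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p with tie correction."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise DataError("wilcoxon_rank_sum needs >= 2 observations per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        log.warning("wilcoxon_rank_sum: all pooled values identical; p=1")
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]], adjust: str = "holm"
) -> tuple[float, pd.DataFrame]:
    """Kruskal-Wallis omnibus p + Dunn pairwise z-tests (Holm-adjusted).

    Dunn's z for groups i, j uses mean ranks over the pooled sample and the
    tie-corrected variance N(N+1)/12 - sum(t^3 - t)/(12(N-1)).
    """
    names = list(groups)
    arrays = {g: np.asarray(v, float) for g, v in groups.items()}
    arrays = {g: v[~np.isnan(v)] for g, v in arrays.items()}
    for g, v in arrays.items():
        if v.size < 2:
            raise DataError(f"group {g!r} has fewer than 2 observations")
    pooled = np.concatenate([arrays[g] for g in names])
    if np.all(pooled == pooled[0]):
        log.warning("kruskal_dunn: all pooled values identical; p=1")
        pairs = pd.DataFrame(
            [
                {"group_1": g1, "group_2": g2, "z": 0.0, "p": 1.0, "p_adjusted": 1.0}
                for g1, g2 in combinations(names, 2)
            ]
        )
        return 1.0, pairs
    omnibus = float(stats.kruskal(*[arrays[g] for g in names]).pvalue)
    ranks = stats.rankdata(pooled)
    N = pooled.size
    offsets = np.cumsum([0] + [arrays[g].size for g in names])
    mean_rank = {
        g: ranks[offsets[i] : offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in combinations(names, 2):
        n1, n2 = arrays[g1].size, arrays[g2].size
        se = np.sqrt(base_var * (1.0 / n1 + 1.0 / n2))
        z = (mean_rank[g1] - mean_rank[g2]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_1": g1, "group_2": g2, "z": float(z), "p": float(p)})
    pairs = pd.DataFrame(rows)
    from statsmodels.stats.multitest import multipletests

    pairs["p_adjusted"] = multipletests(pairs["p"], method=adjust)[1]
    return omnibus, pairs


def spearman_matrix(
    variables: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman correlation matrix + p-values.

    Pairs with fewer than `min_pairs` complete observations are NaN.
    p-values use the t-approximation; the diagonal is 1 / p=0.
    """
    cols = list(variables.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for c1, c2 in combinations(cols, 2):
        pair = variables[[c1, c2]].dropna()
        if len(pair) < min_pairs:
            r.loc[c1, c2] = r.loc[c2, c1] = np.nan
            p.loc[c1, c2] = p.loc[c2, c1] = np.nan
            continue
        res = stats.spearmanr(pair[c1], pair[c2])
        r.loc[c1, c2] = r.loc[c2, c1] = res.statistic
        p.loc[c1, c2] = p.loc[c2, c1] = res.pvalue
    return r, p


# ---------------------------------------------------------------------------
# separation summary
# ---------------------------------------------------------------------------


def separation_summary(
    log2_matrix: pd.DataFrame, labels: Mapping[str, str]
) -> dict:
    """Ward clustering at k=2 + PCA on significant-peptide profiles.

    Rows (peptides) are z-scored; samples are clustered with Ward linkage on
    Euclidean distance and cut at two clusters. Each cluster is assigned its
    majority group label; specificity = correctly grouped controls / controls
    (the control group is 'Con' if present, else the first sorted label).
    """
    if len(log2_matrix) < 2:
        raise DataError("separation_summary needs >= 2 peptides")
    groups = sorted(set(labels.values()))
    counts = {g: sum(1 for s in log2_matrix.columns if labels.get(s) == g)
              for g in groups}
    if any(c < 2 for c in counts.values()):
        raise DataError(f"each group needs >= 2 samples, got {counts}")
    X = log2_matrix.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = ((X - mu) / sd).T  # samples x peptides
    link = linkage(Z, method="ward", metric="euclidean")
    assign = fcluster(link, t=2, criterion="maxclust")
    samples = list(log2_matrix.columns)
    lab = np.array([labels[s] for s in samples])
    control = "Con" if "Con" in groups else groups[0]
    cluster_majority = {}
    for c in np.unique(assign):
        members = lab[assign == c]
        vals, cnts = np.unique(members, return_counts=True)
        cluster_majority[int(c)] = vals[np.argmax(cnts)]
    predicted = np.array([cluster_majority[int(c)] for c in assign])
    is_control = lab == control
    specificity = float(
        100.0 * np.mean(predicted[is_control] == control)
    )
    pca = PCA(n_components=2)
    coords = pca.fit_transform(Z)
    return {
        "specificity_percent": specificity,
        "control_group": control,
        "cluster_assignments": dict(zip(samples, (int(c) for c in assign))),
        "cluster_majority": cluster_majority,
        "pca_coordinates": {
            s: [float(coords[i, 0]), float(coords[i, 1])]
            for i, s in enumerate(samples)
        },
        "explained_variance_fraction": [float(v) for v in
                                        pca.explained_variance_ratio_],
    }
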