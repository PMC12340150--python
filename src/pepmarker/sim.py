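"""Synthetic CSF peptidome generator.

Emulates the statistical structure of an endogenous-peptide (peptidomics)
screen of cerebrospinal fluid so every downstream stage is testable without
external data:

* ~10^4 peptides per sample cut from synthetic parent proteins, with correct
  1-based coordinates and flanking residues;
* true mean abundances spanning a configurable dynamic range (default eight
  orders of magnitude on the log10 scale, matching rank-abundance curves of
  deep CSF peptidome screens);
* multiplicative per-sample technical factors and per-entry lognormal noise
  (default CV 20%);
* five non-human spike-in standard peptides ("StdPep") at high abundance that
  share the per-sample technical factor and carry an extra per-run spiking
  factor, so standard-based normalization is non-trivial but effective;
* abundance-dependent missingness: detection probability is a logistic,
  strictly increasing function of log10 abundance (missing-not-at-random,
  i.e. left-censored — the assumption behind down-shifted imputation);
* planted group effects (fold changes with direction) defining a known true
  differential set;
* a per-group tryptic-like observed fraction (peptides preceded by K/R and
  ending in K/R), steered by an abundance boost solved numerically;
* clinical covariates (age, sex, ALSFRS-r, disease duration, Qalb) with
  configurable Spearman correlation against designated peptides;
* transition-level PRM reports with light/heavy channels, optional transition
  interference and below-limit samples.

Determinism: all draws derive from one master seed through fixed labeled
sub-streams; identical (config, seed) reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import rankdata

from ._utils import substream
from .io import (
    PeptideRecord,
    ProteinRecord,
    QuantMatrix,
    SampleAnnotation,
    write_fasta,
    write_peptide_catalog,
    write_quant_table,
    write_sample_sheet,
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

STANDARD_IDS = ("STD_AQUA1", "STD_AQUA2", "STD_AQUA3", "STD_AQUA4", "STD_AQUA5")


@dataclass(frozen=True)
class EffectSpec:
    """A planted group effect: multiply `peptide_id` by `fold` in `group`."""

    peptide_id: str
    group: str
    fold: float
    direction: str = "up"  # "down" divides by fold instead

    def __post_init__(self):
        if self.fold < 1:
            raise ValueError(f"fold change must be >= 1, got {self.fold}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")

    @property
    def multiplier(self) -> float:
        return self.fold if self.direction == "up" else 1.0 / self.fold


@dataclass(frozen=True)
class ClinicalEffect:
    """Target Spearman correlation between a covariate and a peptide."""

    covariate: str
    peptide_id: str
    target_r: float

    def __post_init__(self):
        if abs(self.target_r) > 1:
            raise ValueError(f"|target r| must be <= 1, got {self.target_r}")


@dataclass
class SimConfig:
    seed: int = 0
    n_proteins: int = 300
    n_peptides: int = 10_000
    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"Con": 24, "ALS": 24}
    )
    n_qc: int = 3
    dynamic_range_orders: float = 8.0
    abundance_floor_log10: float = 2.0
    technical_cv: float = 0.2
    sample_factor_cv: float = 0.3
    effect_table: Sequence[EffectSpec] = ()
    # logistic detection curve in log10 abundance: (midpoint, steepness)
    missingness: tuple[float, float] = (3.0, 0.4)
    standard_nominal: float = 1e8
    standard_run_cv: float = 0.1
    tryptic_like_fraction: Mapping[str, float] | float = field(
        default_factory=lambda: {"Con": 0.20, "ALS": 0.25}
    )
    sex_effects: Mapping[str, float] = field(default_factory=dict)
    clinical_effects: Sequence[ClinicalEffect] = ()

    def __post_init__(self):
        if not 0 < self.technical_cv < 1:
            raise ValueError("technical_cv must be in (0, 1)")
        for g, n in self.n_per_group.items():
            if n < 2:
                raise ValueError(f"group {g!r}: size must be >= 2, got {n}")
        mid, steep = self.missingness
        if steep <= 0:
            raise ValueError("missingness steepness must be positive")
        self.effect_table = tuple(self.effect_table)
        self.clinical_effects = tuple(self.clinical_effects)

    def tryptic_target(self, group: str) -> float:
        if isinstance(self.tryptic_like_fraction, Mapping):
            return float(self.tryptic_like_fraction.get(group, 0.0))
        return float(self.tryptic_like_fraction)

    @property
    def catalog_tryptic_fraction(self) -> float:
        if isinstance(self.tryptic_like_fraction, Mapping):
            return float(max(self.tryptic_like_fraction.values(), default=0.0))
        return float(self.tryptic_like_fraction)


@dataclass
class TrueState:
    """Ground truth of a simulated cohort (reproducible from config + seed)."""

    base_log10: pd.Series  # per-peptide true mean log10 abundance
    group_multiplier: pd.DataFrame  # peptides x groups, fold applied per group
    tryptic_like: pd.Series  # per-peptide bool
    true_differential: tuple[str, ...]
    sample_factors: pd.Series | None = None
    standard_run_factors: pd.Series | None = None

    def to_json(self, path: str | Path) -> None:
        payload = {
            "base_log10": self.base_log10.round(10).to_dict(),
            "group_multiplier": self.group_multiplier.round(10).to_dict(),
            "tryptic_like": {k: bool(v) for k, v in self.tryptic_like.items()},
            "true_differential": list(self.true_differential),
            "sample_factors": None
            if self.sample_factors is None
            else self.sample_factors.round(10).to_dict(),
            "standard_run_factors": None
            if self.standard_run_factors is None
            else self.standard_run_factors.round(10).to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# proteome & peptidome
# ---------------------------------------------------------------------------


def planted_effect_table(
    n_peptides: int,
    n_effects: int = 56,
    group: str = "ALS",
    fold_range: tuple[float, float] = (2.0, 6.0),
    seed: int = 0,
) -> tuple[EffectSpec, ...]:
    """Deterministic planted effects on evenly spread catalog peptide ids.

    Defaults mirror a discovery screen where every regulated peptide changes
    by more than 100% (fold >= 2): half up, half down, folds log-uniform over
    `fold_range`.
    """
    rng = substream(seed, "effects")
    width = len(str(n_peptides))
    idx = np.linspace(1, n_peptides, num=n_effects, dtype=int)
    lo, hi = np.log(fold_range[0]), np.log(fold_range[1])
    folds = np.exp(rng.uniform(lo, hi, size=n_effects))
    return tuple(
        EffectSpec(
            peptide_id=f"PEP{i:0{width}d}", group=group,
            fold=float(np.round(f, 3)),
            direction="up" if k % 2 == 0 else "down",
        )
        for k, (i, f) in enumerate(zip(idx, folds))
    )


def generate_proteome(n_proteins: int, seed: int) -> list[ProteinRecord]:
    """Synthetic parent proteins: uniform 20-letter sequences, length 100-1500."""
    if n_proteins < 1:
        raise ValueError(f"n_proteins must be >= 1, got {n_proteins}")
    rng = substream(seed, "proteome")
    out = []
    width = len(str(n_proteins))
    for i in range(n_proteins):
        length = int(rng.integers(100, 1501))
        seq = "".join(rng.choice(_AA, size=length))
        acc = f"SYNP{i + 1:0{width}d}"
        out.append(
            ProteinRecord(
                accession=acc, sequence=seq,
                entry_name=f"{acc}_SYN", gene=f"SG{i + 1}",
            )
        )
    return out


def _cut_peptide(seq: str, rng: np.random.Generator, tryptic: bool,
                 max_tries: int = 60) -> tuple[int, int] | None:
    """Pick 1-based inclusive (start, end) for a peptide of length 7-40.

    tryptic=True requires a K/R immediately before the start and a K/R as the
    last residue; tryptic=False requires the and-rule to fail.
    """
    n = len(seq)
    if tryptic:
        basic = np.flatnonzero(np.frombuffer(seq.encode(), dtype=np.uint8) ==
                               ord("K")) .tolist()
        basic += np.flatnonzero(
            np.frombuffer(seq.encode(), dtype=np.uint8) == ord("R")
        ).tolist()
        basic = sorted(set(basic))  # 0-based positions of K/R
        if len(basic) < 2:
            return None
        for _ in range(max_tries):
            i = int(rng.integers(0, len(basic)))
            prev = basic[i]  # K/R preceding the peptide
            # candidate ends: K/R positions within (prev+7 .. prev+40)
            lo, hi = prev + 7, prev + 40
            ends = [b for b in basic if lo <= b <= hi and b < n]
            if not ends:
                continue
            end0 = ends[int(rng.integers(0, len(ends)))]
            return prev + 2, end0 + 1  # 1-based: start after prev, end at K/R
        return None
    for _ in range(max_tries):
        length = int(rng.integers(7, 41))
        if n < length + 2:
            continue
        start0 = int(rng.integers(1, n - length))  # keep both flanks inside
        prev_res = seq[start0 - 1]
        last_res = seq[start0 + length - 1]
        if prev_res in "KR" and last_res in "KR":
            continue  # would be tryptic-like under the and-rule
        return start0 + 1, start0 + length
    return None


def generate_peptidome(
    proteins: Sequence[ProteinRecord], config: SimConfig, seed: int
) -> tuple[list[PeptideRecord], TrueState]:
    """Cut a peptide catalog from parent proteins and assign true abundances.

    Log10 true means are uniform over the configured span and min-max rescaled
    so the realized catalog range equals ``dynamic_range_orders`` exactly
    (matching near-linear rank-abundance curves). The catalog tryptic-like
    fraction targets the maximum of the per-group targets; per-group observed
    fractions are steered later via detection-probability boosts.
    """
    if not proteins:
        raise ValueError("proteins must be non-empty")
    rng = substream(seed, "peptidome")
    n = config.n_peptides
    frac = config.catalog_tryptic_fraction
    want_tryptic = rng.random(n) < frac
    peptides: list[PeptideRecord] = []
    n_tryptic = 0
    width = len(str(n))
    for i in range(n):
        tryptic = bool(want_tryptic[i])
        placed = None
        for _ in range(40):
            prot = proteins[int(rng.integers(0, len(proteins)))]
            placed = _cut_peptide(prot.sequence, rng, tryptic)
            if placed is not None:
                break
        if placed is None:  # fall back to the other class rather than fail
            tryptic = not tryptic
            for _ in range(40):
                prot = proteins[int(rng.integers(0, len(proteins)))]
                placed = _cut_peptide(prot.sequence, rng, tryptic)
                if placed is not None:
                    break
        if placed is None:
            raise ValueError(
                "could not place peptides; proteins may lack K/R residues"
            )
        start, end = placed
        seq = prot.sequence[start - 1 : end]
        prev = prot.sequence[start - 2] if start > 1 else None
        nxt = prot.sequence[end] if end < len(prot.sequence) else None
        quality = float(np.round(rng.uniform(3.0, 60.0), 2))
        peptides.append(
            PeptideRecord(
                peptide_id=f"PEP{i + 1:0{width}d}",
                accession=prot.accession, sequence=seq, start=start, end=end,
                preceding_residue=prev, following_residue=nxt, quality=quality,
            )
        )
        n_tryptic += tryptic
    realized = n_tryptic / n
    if frac > 0 and abs(realized - frac) > 0.05:
        raise ValueError(
            f"unsatisfiable tryptic_like_fraction: target {frac:.3f}, "
            f"realized {realized:.3f}"
        )
    ids = [p.peptide_id for p in peptides]
    tryptic_flags = pd.Series(
        [p.preceding_residue in ("K", "R") and p.sequence[-1] in "KR"
         for p in peptides],
        index=ids,
    )

    lo = config.abundance_floor_log10
    hi = lo + config.dynamic_range_orders
    raw = rng.uniform(lo, hi, size=n)
    if n >= 2 and config.dynamic_range_orders > 0:
        raw = lo + (raw - raw.min()) / (raw.max() - raw.min()) * (hi - lo)
    base_log10 = pd.Series(raw, index=ids)

    groups = list(config.n_per_group)
    mult = pd.DataFrame(1.0, index=ids, columns=groups)
    true_diff = []
    for eff in config.effect_table:
        if eff.group not in mult.columns:
            raise ValueError(f"effect group {eff.group!r} not in config groups")
        if eff.peptide_id not in mult.index:
            raise ValueError(f"effect peptide {eff.peptide_id!r} not in catalog")
        mult.loc[eff.peptide_id, eff.group] *= eff.multiplier
        true_diff.append(eff.peptide_id)

    state = TrueState(
        base_log10=base_log10,
        group_multiplier=mult,
        tryptic_like=tryptic_flags,
        true_differential=tuple(dict.fromkeys(true_diff)),
    )
    return peptides, state


def _detect_prob(log10_abund: np.ndarray, mid: float, steep: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(log10_abund - mid) / steep))


def _solve_tryptic_shift(t_log: np.ndarray, n_log: np.ndarray, mid: float,
                         steep: float, target: float) -> float:
    """Detection-curve shift b so the expected observed tryptic share is `target`.

    Tryptic-like peptides in the affected group are detected with probability
    logistic(log10 abundance + b); abundances themselves are untouched, so
    the steering changes identification counts, not quantitative values.
    """

    def share(b: float) -> float:
        pt = _detect_prob(t_log + b, mid, steep).sum()
        pn = _detect_prob(n_log, mid, steep).sum()
        return pt / (pt + pn)

    lo, hi = -8.0, 8.0
    if share(lo) > target:
        return lo
    if share(hi) < target:
        return hi
    if abs(share(0.0) - target) < 1e-9:
        return 0.0
    return float(brentq(lambda b: share(b) - target, lo, hi, xtol=1e-6))


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------


def make_annotations(config: SimConfig, seed: int) -> list[SampleAnnotation]:
    """Sample sheet for the configured groups plus pooled QC injections."""
    rng = substream(seed, "annotations")
    out = []
    order = 1
    for g, n_g in config.n_per_group.items():
        for i in range(n_g):
            sex = "f" if rng.random() < 0.5 else "m"
            out.append(
                SampleAnnotation(
                    sample_id=f"{g}_{i + 1:02d}", group=g, sex=sex,
                    age=float(np.round(rng.normal(62, 9), 1)),
                    run_order=order,
                )
            )
            order += 1
    for i in range(config.n_qc):
        out.append(
            SampleAnnotation(sample_id=f"QC_{i + 1:02d}", group="QC",
                             run_order=order)
        )
        order += 1
    return out


def simulate_cohort(
    catalog: Sequence[PeptideRecord],
    true_state: TrueState,
    config: SimConfig,
    seed: int,
    annotations: Sequence[SampleAnnotation] | None = None,
) -> tuple[QuantMatrix, list[SampleAnnotation], TrueState]:
    """Draw a peptide x sample peak-area matrix with MNAR missingness.

    abundance = true mean x group fold x per-sample technical factor x
    lognormal(cv) noise; an entry is observed with logistic probability in its
    log10 abundance. The five spike-in standards are appended at high nominal
    abundance: they share the sample technical factor and carry an extra
    shared per-run spiking factor.
    """
    ids = [p.peptide_id for p in catalog]
    if list(true_state.base_log10.index) != ids:
        raise ValueError("catalog and true_state are inconsistent")
    if annotations is None:
        annotations = make_annotations(config, seed)
    for a in annotations:
        if a.group != "QC" and a.group not in config.n_per_group:
            raise ValueError(f"group {a.group!r} absent from config.n_per_group")
    rng = substream(seed, "cohort")
    samples = [a.sample_id for a in annotations]
    groups = {a.sample_id: a.group for a in annotations}
    n_pep, n_smp = len(ids), len(samples)

    sigma = np.sqrt(np.log1p(config.technical_cv**2))
    sample_factor = np.exp(
        rng.normal(0.0, np.sqrt(np.log1p(config.sample_factor_cv**2)), n_smp)
    )
    base = 10.0 ** true_state.base_log10.to_numpy()[:, None]
    fold = np.ones((n_pep, n_smp))
    qc_mult = true_state.group_multiplier.mean(axis=1).to_numpy()
    for j, s in enumerate(samples):
        g = groups[s]
        if g == "QC":
            fold[:, j] = qc_mult  # pooled sample: average of group means
        else:
            fold[:, j] = true_state.group_multiplier[g].to_numpy()
    sexes = {a.sample_id: a.sex for a in annotations}
    for pep, f in config.sex_effects.items():
        i = ids.index(pep)
        for j, s in enumerate(samples):
            if sexes.get(s) == "m":
                fold[i, j] *= f
    noise = np.exp(rng.normal(0.0, sigma, size=(n_pep, n_smp)))
    values = base * fold * sample_factor[None, :] * noise

    mid, steep = config.missingness
    log_values = np.log10(values)
    tryptic = true_state.tryptic_like.to_numpy()
    shift_by_group: dict[str, float] = {}
    if tryptic.any() and (~tryptic).any() and isinstance(
        config.tryptic_like_fraction, Mapping
    ):
        t_log = true_state.base_log10.to_numpy()[tryptic]
        n_log = true_state.base_log10.to_numpy()[~tryptic]
        for g in config.n_per_group:
            target = config.tryptic_target(g)
            if target > 0:
                shift_by_group[g] = _solve_tryptic_shift(
                    t_log, n_log, mid, steep, target
                )
    if shift_by_group:
        mean_shift = float(np.mean(list(shift_by_group.values())))
        for j, s in enumerate(samples):
            b = shift_by_group.get(groups[s], mean_shift if groups[s] == "QC"
                                   else 0.0)
            log_values[tryptic, j] += b  # detection side only; values untouched
    pdet = _detect_prob(log_values, mid, steep)
    observed = rng.random((n_pep, n_smp)) < pdet
    data = pd.DataFrame(np.where(observed, values, np.nan), index=ids,
                        columns=samples)

    run_factor = np.exp(
        rng.normal(0.0, np.sqrt(np.log1p(config.standard_run_cv**2)), n_smp)
    )
    std_sigma = sigma / 2  # standards are clean synthetic peptides
    std_noise = np.exp(
        rng.normal(0.0, std_sigma, size=(len(STANDARD_IDS), n_smp))
    )
    std = (
        config.standard_nominal
        * sample_factor[None, :]
        * run_factor[None, :]
        * std_noise
    )
    std_df = pd.DataFrame(std, index=list(STANDARD_IDS), columns=samples)
    data = pd.concat([data, std_df])

    matrix = QuantMatrix(data, "raw", STANDARD_IDS)
    state = TrueState(
        base_log10=true_state.base_log10,
        group_multiplier=true_state.group_multiplier,
        tryptic_like=true_state.tryptic_like,
        true_differential=true_state.true_differential,
        sample_factors=pd.Series(sample_factor, index=samples),
        standard_run_factors=pd.Series(run_factor, index=samples),
    )
    return matrix, list(annotations), state


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------

_COVARIATE_SCALES = {
    "age": ("normal", 62.0, 9.0, 35.0, 90.0),
    "alsfrs_r": ("normal", 40.0, 5.0, 0.0, 48.0),
    "disease_duration": ("lognormal", np.log(12.0), 0.6, 1.0, 120.0),
    "qalb": ("lognormal", np.log(6.0), 0.4, 1.0, 40.0),
}


def simulate_clinical(
    annotations: Sequence[SampleAnnotation],
    matrix: QuantMatrix,
    config: SimConfig,
    seed: int,
) -> list[SampleAnnotation]:
    """Fill clinical covariates with target Spearman links to measured peptides.

    A Gaussian-copula construction: the covariate's latent normal mixes the
    peptide's normal scores (rank-derived) with independent noise at a Pearson
    weight chosen so the implied Spearman correlation matches the target
    (r_pearson = 2 sin(pi r_s / 6)). The latent is then mapped through a
    monotone transform to a realistic clinical scale, preserving ranks.
    ALSFRS-r and disease duration are only defined for disease groups.
    """
    rng = substream(seed, "clinical")
    targets = {e.covariate: e for e in config.clinical_effects}
    for e in config.clinical_effects:
        if abs(e.target_r) > 1:
            raise ValueError(f"|target r| must be <= 1, got {e.target_r}")
    samples = [a.sample_id for a in annotations]
    out = []
    latent_by_cov: dict[str, np.ndarray] = {}
    for cov, (kind, loc, scale, lo, hi) in _COVARIATE_SCALES.items():
        eps = rng.standard_normal(len(samples))
        if cov in targets:
            e = targets[cov]
            if e.peptide_id not in matrix.data.index:
                raise ValueError(f"clinical effect peptide {e.peptide_id!r} "
                                 "not in matrix")
            vals = matrix.data.loc[e.peptide_id, samples].to_numpy(float)
            filled = np.where(np.isnan(vals), np.nanmin(vals) / 2, vals)
            ranks = rankdata(np.log(filled))
            z = (ranks - ranks.mean()) / max(ranks.std(), 1e-12)
            rho = 2 * np.sin(np.pi * e.target_r / 6)
            latent = rho * z + np.sqrt(max(1 - rho**2, 0.0)) * eps
        else:
            latent = eps
        latent_by_cov[cov] = latent
    for j, a in enumerate(annotations):
        fields = {}
        for cov, (kind, loc, scale, lo, hi) in _COVARIATE_SCALES.items():
            z = latent_by_cov[cov][j]
            x = loc + scale * z if kind == "normal" else float(np.exp(loc + scale * z))
            x = float(np.clip(x, lo, hi))
            if cov in ("alsfrs_r", "disease_duration") and a.group in ("Con", "QC"):
                x = None
            elif a.group == "QC":
                x = None
            fields[cov] = None if x is None else round(x, 2)
        out.append(
            SampleAnnotation(
                sample_id=a.sample_id, group=a.group, cohort=a.cohort, sex=a.sex,
                age=fields["age"], alsfrs_r=fields["alsfrs_r"],
                disease_duration=fields["disease_duration"], qalb=fields["qalb"],
                run_order=a.run_order,
            )
        )
    return out


# ---------------------------------------------------------------------------
# PRM simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelEntry:
    peptide_id: str
    protein: str
    transitions: tuple[str, ...]
    reference_rt: float
    relative_intensity: tuple[float, ...] = ()

    def intensities(self) -> np.ndarray:
        if self.relative_intensity:
            w = np.asarray(self.relative_intensity, float)
        else:  # geometric fall-off, a typical fragment-intensity profile
            w = 0.8 ** np.arange(len(self.transitions))
        return w / w.max()


@dataclass
class PRMSimConfig:
    technical_cv: float = 0.05
    heavy_nominal: float = 1e6
    abundance_cv: float = 0.6  # biological spread of the light channel
    fold_by_group: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    # named interferences: (peptide_id, transition, relative extra light area)
    interference: Sequence[tuple[str, str, float]] = ()
    # samples where the endogenous (light) peptide is below the detection limit
    below_limit: Sequence[tuple[str, str]] = ()  # (sample_id, peptide_id)
    rt_jitter_min: float = 0.02
    # peptides sharing a biological latent factor (e.g. co-released markers);
    # `correlation` is the shared fraction of biological log-variance
    correlation_groups: Sequence[Sequence[str]] = ()
    correlation: float = 0.0


def simulate_prm(
    panel: Sequence[PanelEntry],
    annotations: Sequence[SampleAnnotation],
    config: PRMSimConfig,
    seed: int,
) -> pd.DataFrame:
    """Transition-level PRM report with light/heavy channels.

    The light channel scales with a per-sample simulated peptide abundance
    (lognormal around a group-fold-adjusted nominal); the heavy channel is the
    constant spiked standard up to technical noise. Interference adds signal
    to one named light transition; below-limit samples lose all light peaks
    for that peptide.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    for entry in panel:
        if len(entry.transitions) < 3:
            raise ValueError(
                f"panel peptide {entry.peptide_id!r} declares "
                f"{len(entry.transitions)} transitions; need >= 3"
            )
    rng = substream(seed, "prm")
    tech_sigma = np.sqrt(np.log1p(config.technical_cv**2))
    bio_sigma = np.sqrt(np.log1p(config.abundance_cv**2))
    interf = {(p, t): f for p, t, f in config.interference}
    below = set(config.below_limit)
    n_samples = len(annotations)
    # biological z-scores, optionally correlated within latent groups
    latent_of = {p: k for k, grp in enumerate(config.correlation_groups)
                 for p in grp}
    latents = rng.standard_normal((max(len(config.correlation_groups), 1),
                                   n_samples))
    rho = float(config.correlation)
    z_bio: dict[str, np.ndarray] = {}
    for entry in panel:
        own = rng.standard_normal(n_samples)
        k = latent_of.get(entry.peptide_id)
        if k is None or rho <= 0:
            z_bio[entry.peptide_id] = own
        else:
            z_bio[entry.peptide_id] = (
                np.sqrt(rho) * latents[k] + np.sqrt(1.0 - rho) * own
            )
    rows = []
    for entry in panel:
        w = entry.intensities()
        folds = config.fold_by_group.get(entry.peptide_id, {})
        for j, a in enumerate(annotations):
            fold = float(folds.get(a.group, 1.0))
            abundance = (
                config.heavy_nominal
                * fold
                * np.exp(bio_sigma * z_bio[entry.peptide_id][j])
            )
            rt = entry.reference_rt + rng.normal(0.0, config.rt_jitter_min)
            light_gone = (a.sample_id, entry.peptide_id) in below
            for k, t in enumerate(entry.transitions):
                heavy = (
                    config.heavy_nominal * w[k]
                    * np.exp(rng.normal(0.0, tech_sigma))
                )
                rows.append(
                    dict(sample_id=a.sample_id, peptide_id=entry.peptide_id,
                         transition=t, channel="heavy",
                         rt_min=round(float(rt), 3), area=float(heavy))
                )
                if light_gone:
                    continue
                light = abundance * w[k] * np.exp(rng.normal(0.0, tech_sigma))
                light *= 1.0 + interf.get((entry.peptide_id, t), 0.0)
                rows.append(
                    dict(sample_id=a.sample_id, peptide_id=entry.peptide_id,
                         transition=t, channel="light",
                         rt_min=round(float(rt), 3), area=float(light))
                )
    return pd.DataFrame(rows, columns=list(PRM_COLUMNS_ORDER))


PRM_COLUMNS_ORDER = ("sample_id", "peptide_id", "transition", "channel",
                     "rt_min", "area")


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------


def write_dataset(
    outdir: str | Path,
    proteins: Sequence[ProteinRecord],
    catalog: Sequence[PeptideRecord],
    matrix: QuantMatrix,
    annotations: Sequence[SampleAnnotation],
    state: TrueState,
    prm_report: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write all simulator outputs as plain-text files; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": str(outdir / "proteins.fasta"),
        "catalog": str(outdir / "peptide_catalog.tsv"),
        "quant": str(outdir / "quant_matrix.tsv"),
        "samples": str(outdir / "sample_sheet.tsv"),
        "true_state": str(outdir / "true_state.json"),
    }
    write_fasta(proteins, paths["proteins"])
    write_peptide_catalog(catalog, paths["catalog"])
    write_quant_table(matrix, paths["quant"])
    write_sample_sheet(annotations, paths["samples"])
    state.to_json(paths["true_state"])
    if prm_report is not None:
        paths["prm"] = str(outdir / "prm_report.csv")
        prm_report.to_csv(paths["prm"], index=False)
    return paths
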