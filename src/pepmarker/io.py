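"""Data model and file I/O for peptidomics analyses.

Containers
----------
ProteinRecord / PeptideRecord
    Peptide coordinates are 1-based inclusive (the UniProt convention):
    a peptide spanning ``start..end`` has length ``end - start + 1`` and
    ``protein.sequence[start-1:end]`` must equal its sequence.
SampleAnnotation
    Per-sample clinical/technical metadata. Group labels come from a closed
    set covering control, ALS subtypes, other neurodegenerative diseases and
    pooled quality-control (QC) injections.
QuantMatrix
    Peptide x sample peak-area matrix (pandas DataFrame) plus its
    normalization state and the ids of the spiked-in standard peptides.

Files are plain text throughout: FASTA for proteins, TSV for quantification
matrices / sample sheets / peptide catalogs (empty cell = missing, zero =
measured zero), CSV for transition-level PRM reports, YAML/JSON for config.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._utils import log

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

GROUP_LABELS = frozenset(
    {"Con", "ALS", "sALS", "gALS", "C9orf72", "SOD1", "AD", "bvFTD", "PD", "QC"}
)

NORMALIZATION_STATES = ("raw", "tic", "stdpep", "log2")

PRM_COLUMNS = ("sample_id", "peptide_id", "transition", "channel", "rt_min", "area")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class ConfigError(ValueError):
    """Invalid configuration."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    entry_name: str = ""
    gene: str = ""

    def __post_init__(self):
        if not self.sequence:
            raise DataError(f"protein {self.accession!r}: empty sequence")
        seq = self.sequence.upper()
        bad = set(seq) - AMINO_ACIDS - {"X"}
        if bad:
            raise DataError(
                f"protein {self.accession!r}: invalid residues {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


_MOD_RE = re.compile(r"\(([^)]+)\)")


def parse_modified_sequence(text: str) -> tuple[str, list[tuple[int, str]]]:
    """Parse an inline-modified sequence like ``APKK(trimethylation)PV``.

    Returns the plain sequence and a list of (1-based position, name) pairs;
    each annotation applies to the residue immediately before it.
    """
    plain: list[str] = []
    mods: list[tuple[int, str]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "(":
            m = _MOD_RE.match(text, i)
            if m is None or not plain:
                raise DataError(f"malformed modification annotation in {text!r}")
            mods.append((len(plain), m.group(1)))
            i = m.end()
        else:
            plain.append(ch)
            i += 1
    return "".join(plain), mods


@dataclass(frozen=True)
class PeptideRecord:
    peptide_id: str
    accession: str
    sequence: str
    start: int
    end: int
    modifications: tuple[tuple[int, str, float], ...] = ()
    preceding_residue: str | None = None
    following_residue: str | None = None
    quality: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    group: str
    cohort: str = "default"
    sex: str | None = None
    age: float | None = None
    alsfrs_r: float | None = None
    disease_duration: float | None = None
    qalb: float | None = None
    run_order: int | None = None

    def __post_init__(self):
        if self.group not in GROUP_LABELS:
            raise DataError(
                f"sample {self.sample_id!r}: unknown group {self.group!r}; "
                f"allowed: {sorted(GROUP_LABELS)}"
            )


# ---------------------------------------------------------------------------
# quantification matrix
# ---------------------------------------------------------------------------


@dataclass
class QuantMatrix:
    """Peptide x sample abundance matrix with explicit normalization state."""

    data: pd.DataFrame  # rows = peptide ids, columns = sample ids, NaN = missing
    normalization_state: str = "raw"
    standard_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.normalization_state not in NORMALIZATION_STATES:
            raise DataError(
                f"unknown normalization state {self.normalization_state!r}"
            )
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate peptide ids: {dup}")
        if self.normalization_state == "raw":
            missing = set(self.standard_ids) - set(self.data.index)
            if missing:
                raise DataError(f"standard ids not in matrix: {sorted(missing)}")
        self.standard_ids = tuple(self.standard_ids)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def with_data(self, data: pd.DataFrame, state: str | None = None) -> "QuantMatrix":
        return QuantMatrix(
            data=data,
            normalization_state=state or self.normalization_state,
            standard_ids=self.standard_ids,
        )

    def drop_standards(self) -> "QuantMatrix":
        keep = [p for p in self.data.index if p not in set(self.standard_ids)]
        out = QuantMatrix(
            self.data.loc[keep].copy(), self.normalization_state, ()
        )
        return out

    def equals(self, other: "QuantMatrix") -> bool:
        return (
            self.normalization_state == other.normalization_state
            and self.standard_ids == other.standard_ids
            and self.data.equals(other.data)
        )


def read_quant_table(
    path: str | Path, *, normalization_state: str = "raw",
    standard_ids: Sequence[str] = (),
) -> QuantMatrix:
    """Read a TSV quantification table (first column peptide id, header samples)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise DataError(f"{path}: malformed table ({exc})") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate peptide ids: {dup}")
    values = pd.DataFrame(index=df.index.astype(str), columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col].str.strip()
        try:
            values[col] = np.where(raw == "", np.nan, raw.replace("", "0")).astype(
                float
            )
        except ValueError as exc:
            bad = raw[(raw != "") & raw.apply(_not_numeric)]
            raise DataError(
                f"{path}: non-numeric cell(s) in sample {col!r}: "
                f"{bad.head(3).to_dict()}"
            ) from exc
    values.index.name = "peptide_id"
    log.info("read quant table %s: %d peptides x %d samples", path, *values.shape)
    return QuantMatrix(values, normalization_state, tuple(standard_ids))


def _not_numeric(s: str) -> bool:
    try:
        float(s)
        return False
    except ValueError:
        return True


def write_quant_table(matrix: QuantMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.data.to_csv(path, sep="\t", na_rep="", index_label="peptide_id")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records; accession = first whitespace token of the header."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).replace(" ", "").upper()
        if not seq:
            raise DataError(f"{path}: header {rec.id!r} has no sequence")
        desc_parts = rec.description.split(None, 1)
        extra = desc_parts[1] if len(desc_parts) > 1 else ""
        entry_name, gene = _parse_header_extras(extra)
        records.append(
            ProteinRecord(accession=rec.id, sequence=seq, entry_name=entry_name,
                          gene=gene)
        )
    if not records:
        raise DataError(f"{path}: no FASTA records")
    log.info("read FASTA %s: %d proteins", path, len(records))
    return records


def _parse_header_extras(extra: str) -> tuple[str, str]:
    entry = gene = ""
    m = re.search(r"EN=(\S+)", extra)
    if m:
        entry = m.group(1)
    m = re.search(r"GN=(\S+)", extra)
    if m:
        gene = m.group(1)
    return entry, gene


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path) -> None:
    recs = []
    for p in proteins:
        desc = ""
        if p.entry_name:
            desc += f"EN={p.entry_name}"
        if p.gene:
            desc += f" GN={p.gene}"
        recs.append(SeqRecord(Seq(p.sequence), id=p.accession, description=desc.strip()))
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# peptide record validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationReport:
    peptide_id: str
    passed: bool
    expected_length: int
    failures: tuple[str, ...] = ()


def validate_peptide_record(
    peptide: PeptideRecord, protein: ProteinRecord
) -> ValidationReport:
    """Check coordinate/length/sequence/flank consistency of a peptide record.

    PASS iff (i) end - start + 1 equals the sequence length, (ii) the protein
    subsequence at the 1-based inclusive coordinates equals the peptide
    sequence, and (iii) the stated flanking residues match the protein context
    (no flank expected at the protein termini).
    """
    if peptide.accession != protein.accession:
        raise DataError(
            f"peptide {peptide.peptide_id!r} references {peptide.accession!r}, "
            f"got protein {protein.accession!r}"
        )
    failures: list[str] = []
    expected_length = peptide.end - peptide.start + 1
    if peptide.start < 1 or peptide.end < peptide.start:
        failures.append(
            f"coordinate order: start={peptide.start}, end={peptide.end}"
        )
    if expected_length != len(peptide.sequence):
        failures.append(
            f"length: end-start+1={expected_length} != len(sequence)="
            f"{len(peptide.sequence)}"
        )
    seq = protein.sequence
    if not failures:
        if peptide.end > len(seq):
            failures.append(
                f"coordinates beyond protein (length {len(seq)})"
            )
        elif seq[peptide.start - 1 : peptide.end] != peptide.sequence:
            failures.append("sequence mismatch at stated coordinates")
        else:
            expected_prev = seq[peptide.start - 2] if peptide.start > 1 else None
            expected_next = seq[peptide.end] if peptide.end < len(seq) else None
            if peptide.preceding_residue != expected_prev:
                failures.append(
                    f"preceding residue {peptide.preceding_residue!r} != "
                    f"{expected_prev!r}"
                )
            if peptide.following_residue != expected_next:
                failures.append(
                    f"following residue {peptide.following_residue!r} != "
                    f"{expected_next!r}"
                )
    return ValidationReport(
        peptide_id=peptide.peptide_id,
        passed=not failures,
        expected_length=expected_length,
        failures=tuple(failures),
    )


# ---------------------------------------------------------------------------
# peptide catalog / sample sheet / PRM report
# ---------------------------------------------------------------------------

CATALOG_COLUMNS = (
    "peptide_id", "accession", "sequence", "start", "end", "modifications",
    "preceding_residue", "following_residue", "quality",
)


def write_peptide_catalog(peptides: Iterable[PeptideRecord], path: str | Path) -> None:
    rows = []
    for p in peptides:
        mods = ";".join(f"{pos}:{name}:{mass:g}" for pos, name, mass in p.modifications)
        rows.append(
            dict(
                peptide_id=p.peptide_id, accession=p.accession, sequence=p.sequence,
                start=p.start, end=p.end, modifications=mods,
                preceding_residue=p.preceding_residue or "",
                following_residue=p.following_residue or "",
                quality=p.quality,
            )
        )
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_peptide_catalog(path: str | Path) -> list[PeptideRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing catalog columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        mods = []
        if row.modifications:
            for chunk in row.modifications.split(";"):
                pos, name, mass = chunk.split(":")
                mods.append((int(pos), name, float(mass)))
        out.append(
            PeptideRecord(
                peptide_id=row.peptide_id, accession=row.accession,
                sequence=row.sequence, start=int(row.start), end=int(row.end),
                modifications=tuple(mods),
                preceding_residue=row.preceding_residue or None,
                following_residue=row.following_residue or None,
                quality=float(row.quality) if row.quality else float("nan"),
            )
        )
    log.info("read peptide catalog %s: %d peptides", path, len(out))
    return out


SAMPLE_SHEET_COLUMNS = (
    "sample_id", "group", "cohort", "sex", "age", "alsfrs_r",
    "disease_duration", "qalb", "run_order",
)


def write_sample_sheet(annotations: Iterable[SampleAnnotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        rows.append({c: getattr(a, c) for c in SAMPLE_SHEET_COLUMNS})
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(
        path, sep="\t", index=False, na_rep=""
    )


def read_sample_sheet(path: str | Path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"sample_id", "group"} - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing sample sheet columns {sorted(missing)}")

    def opt_float(v: str) -> float | None:
        return float(v) if v not in ("", "nan") else None

    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            SampleAnnotation(
                sample_id=d["sample_id"], group=d["group"],
                cohort=d.get("cohort", "") or "default",
                sex=d.get("sex") or None,
                age=opt_float(d.get("age", "")),
                alsfrs_r=opt_float(d.get("alsfrs_r", "")),
                disease_duration=opt_float(d.get("disease_duration", "")),
                qalb=opt_float(d.get("qalb", "")),
                run_order=int(float(d["run_order"])) if d.get("run_order") else None,
            )
        )
    log.info("read sample sheet %s: %d samples", path, len(out))
    return out


def read_prm_report(path: str | Path) -> pd.DataFrame:
    """Read a transition-level PRM report (CSV).

    Mandatory columns: sample_id, peptide_id, transition, channel (light/heavy),
    rt_min, area. Unknown columns are preserved as opaque extras.
    """
    df = pd.read_csv(path)
    missing = set(PRM_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"{path}: missing PRM columns {sorted(missing)}")
    bad = set(df["channel"].unique()) - {"light", "heavy"}
    if bad:
        raise DataError(
            f"{path}: channel must be 'light' or 'heavy', got {sorted(bad)}"
        )
    log.info("read PRM report %s: %d transition rows", path, len(df))
    return df


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

CONFIG_DEFAULTS: Mapping[str, object] = {
    "s0": 0.1,
    "fdr": 0.05,
    "n_permutations": 250,
    "impute_width": 0.3,
    "impute_downshift": 1.8,
    "presence_policy": "in_70pct_any_group",
    "quality_threshold": 5.0,
    "normalization": "stdpep",
    "tryptic_mode": "and",
    "min_dotp": 0.7,
    "min_transitions": 10,
    "rt_tolerance_min": 1.0,
    "coelution_tolerance_min": 0.1,
    "stability_limit_percent": 30.0,
    "dilution_limit_percent": 20.0,
    "freeze_thaw_exclusion_percent": 100.0,
}

_CONFIG_VALIDATORS = {
    "s0": lambda v: v >= 0,
    "fdr": lambda v: 0 < v < 1,
    "n_permutations": lambda v: int(v) >= 1,
    "impute_width": lambda v: v > 0,
    "impute_downshift": lambda v: v >= 0,
    "presence_policy": lambda v: v in {
        "in_70pct_each_group", "in_70pct_any_group", "in_70pct_all",
        "min3_each_group", "min3_any_group",
    },
    "normalization": lambda v: v in {"none", "tic", "stdpep"},
    "tryptic_mode": lambda v: v in {"and", "or"},
    "min_dotp": lambda v: 0 <= v <= 1,
    "min_transitions": lambda v: int(v) >= 1,
}


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, object] | None = None) -> dict:
    """Load a YAML/JSON config, fill documented defaults, validate fields.

    Returns a plain dict; the key ``_defaulted`` records which values were
    filled from defaults (so e.g. a defaulted s0=0.1 is visible in manifests).
    """
    cfg: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) \
            else json.loads(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        cfg.update(loaded)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    defaulted = []
    for key, default in CONFIG_DEFAULTS.items():
        if key not in cfg:
            cfg[key] = default
            defaulted.append(key)
    unknown = set(cfg) - set(CONFIG_DEFAULTS) - {"seed", "outdir", "_defaulted"}
    for key, check in _CONFIG_VALIDATORS.items():
        try:
            ok = check(cfg[key])
        except TypeError:
            ok = False
        if not ok:
            raise ConfigError(f"config field {key}={cfg[key]!r} is invalid")
    if unknown:
        log.warning("config: ignoring unknown keys %s", sorted(unknown))
    cfg["_defaulted"] = sorted(defaulted)
    return cfg
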