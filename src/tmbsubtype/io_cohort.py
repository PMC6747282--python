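"""Cohort input/output: somatic mutation and clinical tables.

Reads MAF-like tab-separated mutation tables (configurable column mapping),
clinical tables, optionally annotates trinucleotide contexts from a FASTA,
and derives the binary gene x sample mutation matrix consumed downstream.

Coordinates are 1-based fully closed (MAF convention).  Indels never carry a
trinucleotide context; they still count toward mutation burden.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .enrichment import MutationMatrix

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class VariantClass(str, Enum):
    NONSENSE = "nonsense"
    MISSENSE = "missense"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    FRAMESHIFT_INDEL = "frameshift_indel"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"


#: Variant classes that do not alter the protein sequence.
SYNONYMOUS_CLASSES = frozenset({VariantClass.SYNONYMOUS})

#: Default synonym table mapping common MAF dialect strings onto VariantClass.
DEFAULT_CLASS_SYNONYMS: dict[str, VariantClass] = {
    "nonsense": VariantClass.NONSENSE,
    "nonsense_mutation": VariantClass.NONSENSE,
    "stop_gained": VariantClass.NONSENSE,
    "missense": VariantClass.MISSENSE,
    "missense_mutation": VariantClass.MISSENSE,
    "splice_site": VariantClass.SPLICE_SITE,
    "splice_region": VariantClass.SPLICE_SITE,
    "synonymous": VariantClass.SYNONYMOUS,
    "silent": VariantClass.SYNONYMOUS,
    "synonymous_variant": VariantClass.SYNONYMOUS,
    "frameshift_indel": VariantClass.FRAMESHIFT_INDEL,
    "frame_shift_del": VariantClass.FRAMESHIFT_INDEL,
    "frame_shift_ins": VariantClass.FRAMESHIFT_INDEL,
    "frameshift_variant": VariantClass.FRAMESHIFT_INDEL,
    "nonframeshift_indel": VariantClass.NONFRAMESHIFT_INDEL,
    "in_frame_del": VariantClass.NONFRAMESHIFT_INDEL,
    "in_frame_ins": VariantClass.NONFRAMESHIFT_INDEL,
    "inframe_indel": VariantClass.NONFRAMESHIFT_INDEL,
}


class AgeGroup(str, Enum):
    UNDER65 = "under65"
    AT_LEAST65 = "at_least65"


class Smoking(str, Enum):
    SMOKER = "smoker"
    NON_SMOKER = "non_smoker"
    UNKNOWN = "unknown"


class Stage(str, Enum):
    EARLY = "early"
    LATE = "late"
    UNKNOWN = "unknown"


class Metastasis(str, Enum):
    YES = "yes"
    NO = "no"
    UNKNOWN = "unknown"


class CohortError(ValueError):
    """Raised on malformed or inconsistent cohort input."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call in one sample (1-based, closed coords)."""

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: VariantClass
    context: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CohortError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise CohortError(
                f"ref and alt are identical ({self.ref}) at "
                f"{self.chrom}:{self.pos}"
            )
        if self.is_snv and (self.ref not in _BASES or self.alt not in _BASES):
            raise CohortError(
                f"SNV alleles must be single bases in ACGT: {self.ref}>{self.alt}"
            )
        if self.context is not None:
            if len(self.context) != 3 or any(b not in _BASES for b in self.context):
                raise CohortError(f"context must be a 3-mer over ACGT: {self.context!r}")
            if not self.is_snv:
                raise CohortError("only SNVs may carry a trinucleotide context")
            if self.context[1] != self.ref:
                raise CohortError(
                    f"context middle base {self.context[1]} != ref {self.ref}"
                )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and "-" not in (
            self.ref + self.alt
        )

    @property
    def is_indel(self) -> bool:
        return not self.is_snv


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    age: float | None
    age_group: AgeGroup | None
    smoking: Smoking
    stage: Stage
    metastasis: Metastasis
    dfs_time: float
    dfs_event: bool

    def __post_init__(self) -> None:
        if self.age is not None and self.age < 0:
            raise CohortError(f"age must be nonnegative, got {self.age}")
        if self.dfs_time < 0:
            raise CohortError(f"dfs_time must be nonnegative, got {self.dfs_time}")
        if self.age is not None and self.age_group is not None:
            expected = AgeGroup.AT_LEAST65 if self.age >= 65 else AgeGroup.UNDER65
            if self.age_group != expected:
                raise CohortError(
                    f"age_group {self.age_group.value} inconsistent with age {self.age}"
                )


@dataclass
class CohortTable:
    """Somatic mutations plus clinical covariates for an ordered sample list.

    Samples with zero mutations are retained (TMB 0), which is why the sample
    list is carried explicitly instead of being inferred from the mutations.
    """

    mutations: list[MutationRecord]
    clinical: list[ClinicalRecord] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            seen: dict[str, None] = {}
            for m in self.mutations:
                seen.setdefault(m.sample_id, None)
            for c in self.clinical:
                seen.setdefault(c.sample_id, None)
            self.sample_ids = list(seen)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CohortError("sample_ids contains duplicates")
        known = set(self.sample_ids)
        missing = {m.sample_id for m in self.mutations} - known
        if missing:
            raise CohortError(
                f"mutations reference samples absent from sample_ids: {sorted(missing)[:5]}"
            )
        ids = [c.sample_id for c in self.clinical]
        if len(set(ids)) != len(ids):
            raise CohortError("clinical sample_id not unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def clinical_by_sample(self) -> dict[str, ClinicalRecord]:
        return {c.sample_id: c for c in self.clinical}


# ---------------------------------------------------------------------------
# MAF-like dialect handling

#: default column mapping: logical field -> column name in the file
DEFAULT_MAF_COLUMNS: dict[str, str] = {
    "sample_id": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "chrom": "Chromosome",
    "pos": "Start_Position",
    "ref": "Reference_Allele",
    "alt": "Tumor_Seq_Allele2",
    "variant_class": "Variant_Classification",
    "context": "context",  # optional
}

_MANDATORY_FIELDS = ("sample_id", "gene", "chrom", "pos", "ref", "alt", "variant_class")


@dataclass(frozen=True)
class MafDialect:
    """Column-name mapping and variant-class synonym table for a MAF flavor."""

    columns: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MAF_COLUMNS)
    )
    class_synonyms: Mapping[str, VariantClass] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SYNONYMS)
    )

    def resolve_class(self, raw: str) -> VariantClass:
        key = raw.strip().lower()
        try:
            return self.class_synonyms[key]
        except KeyError:
            raise CohortError(
                f"unknown variant classification {raw!r}; extend the dialect synonym table"
            ) from None


def read_maf(path: str | Path, dialect: MafDialect | None = None) -> list[MutationRecord]:
    """Parse a MAF-like TSV into MutationRecords, preserving row order.

    Duplicate identical rows are collapsed with a warning (double reporting).
    """
    dialect = dialect or MafDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for logical in _MANDATORY_FIELDS:
        col = dialect.columns.get(logical, logical)
        if col not in df.columns:
            raise CohortError(f"mandatory column {col!r} (field {logical}) missing in {path}")
    ctx_col = dialect.columns.get("context", "context")
    col_ix = {c: i for i, c in enumerate(df.columns)}
    records: list[MutationRecord] = []
    seen: set[tuple] = set()
    n_dup = 0
    for i, row in enumerate(df.itertuples(index=False, name=None), start=2):
        get = lambda logical: row[col_ix[dialect.columns.get(logical, logical)]]
        raw_pos = get("pos")
        try:
            pos = int(raw_pos)
        except (TypeError, ValueError):
            raise CohortError(f"{path}, line {i}: malformed position {raw_pos!r}") from None
        ctx = None
        if ctx_col in df.columns:
            val = row[col_ix[ctx_col]]
            if isinstance(val, str) and val.strip() not in ("", ".", "NA"):
                ctx = val.strip().upper()
        rec = MutationRecord(
            sample_id=str(get("sample_id")),
            gene=str(get("gene")),
            chrom=str(get("chrom")),
            pos=pos,
            ref=str(get("ref")).upper(),
            alt=str(get("alt")).upper(),
            variant_class=dialect.resolve_class(str(get("variant_class"))),
            context=ctx,
        )
        key = (rec.sample_id, rec.gene, rec.chrom, rec.pos, rec.ref, rec.alt,
               rec.variant_class)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        records.append(rec)
    if n_dup:
        warnings.warn(f"collapsed {n_dup} duplicate mutation rows", stacklevel=2)
    return records


def write_maf(
    mutations: Iterable[MutationRecord],
    path: str | Path,
    dialect: MafDialect | None = None,
) -> None:
    """Write records as MAF-like TSV in the dialect's column names."""
    dialect = dialect or MafDialect()
    cols = dialect.columns
    rows = []
    for m in mutations:
        rows.append({
            cols.get("sample_id", "sample_id"): m.sample_id,
            cols.get("gene", "gene"): m.gene,
            cols.get("chrom", "chrom"): m.chrom,
            cols.get("pos", "pos"): m.pos,
            cols.get("ref", "ref"): m.ref,
            cols.get("alt", "alt"): m.alt,
            cols.get("variant_class", "variant_class"): m.variant_class.value,
            cols.get("context", "context"): m.context if m.context else ".",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


_CLINICAL_COLUMNS = [
    "sample_id", "age", "age_group", "smoking", "stage", "metastasis",
    "dfs_time", "dfs_event",
]


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"clinical table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        age = None if row.age in (None, "", ".", "NA") or pd.isna(row.age) else float(row.age)
        if row.age_group in (None, "", ".", "NA") or pd.isna(row.age_group):
            age_group = None if age is None else (
                AgeGroup.AT_LEAST65 if age >= 65 else AgeGroup.UNDER65
            )
        else:
            age_group = AgeGroup(row.age_group)
        out.append(ClinicalRecord(
            sample_id=str(row.sample_id),
            age=age,
            age_group=age_group,
            smoking=Smoking(row.smoking),
            stage=Stage(row.stage),
            metastasis=Metastasis(row.metastasis),
            dfs_time=float(row.dfs_time),
            dfs_event=str(row.dfs_event).strip().lower() in ("1", "true", "yes"),
        ))
    return out


def write_clinical(clinical: Iterable[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for c in clinical:
        rows.append({
            "sample_id": c.sample_id,
            "age": "." if c.age is None else c.age,
            "age_group": "." if c.age_group is None else c.age_group.value,
            "smoking": c.smoking.value,
            "stage": c.stage.value,
            "metastasis": c.metastasis.value,
            "dfs_time": c.dfs_time,
            "dfs_event": int(c.dfs_event),
        })
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cohort(
    maf_path: str | Path,
    clinical_path: str | Path | None = None,
    dialect: MafDialect | None = None,
    sample_ids: Sequence[str] | None = None,
) -> CohortTable:
    """Read mutation (and optionally clinical) tables into a CohortTable."""
    mutations = read_maf(maf_path, dialect)
    clinical = read_clinical(clinical_path) if clinical_path else []
    ids = list(sample_ids) if sample_ids is not None else []
    return CohortTable(mutations=mutations, clinical=clinical, sample_ids=ids)


# ---------------------------------------------------------------------------
# Context annotation

def annotate_context(
    mutations: Sequence[MutationRecord],
    reference_fasta: str | Path,
) -> tuple[list[MutationRecord], int]:
    """Fill trinucleotide contexts for SNVs from an indexed FASTA.

    Returns (records, n_flagged) where flagged records (reference mismatch or
    contig boundary) are returned with context=None and excluded from
    signature analysis by downstream classification.  Indels pass through
    untouched.
    """
    from pyfaidx import Fasta

    fasta = Fasta(str(reference_fasta), as_raw=True, sequence_always_upper=True)
    missing = {m.chrom for m in mutations if m.is_snv} - set(fasta.keys())
    if missing:
        raise CohortError(f"chromosomes absent from FASTA: {sorted(missing)}")
    out: list[MutationRecord] = []
    n_flagged = 0
    for m in mutations:
        if not m.is_snv:
            out.append(m)
            continue
        contig = fasta[m.chrom]
        if m.pos < 2 or m.pos > len(contig) - 1:
            n_flagged += 1
            out.append(replace(m, context=None))
            continue
        tri = contig[m.pos - 2 : m.pos + 1]  # 1-based closed -> 0-based slice
        if tri[1] != m.ref or any(b not in _BASES for b in tri):
            n_flagged += 1
            out.append(replace(m, context=None))
            continue
        out.append(replace(m, context=tri))
    if n_flagged:
        logger.info("annotate_context: %d SNVs flagged un-annotatable", n_flagged)
    return out, n_flagged


# ---------------------------------------------------------------------------
# Binary mutation matrix

def build_mutation_matrix(
    cohort: CohortTable, nonsynonymous_only: bool = False
) -> MutationMatrix:
    """Binary genes x samples incidence matrix.

    Entry (g, s) is 1 iff sample s carries at least one qualifying mutation in
    gene g.  With ``nonsynonymous_only`` synonymous records are excluded.
    All cohort samples appear as columns, including zero-TMB samples.
    """
    if cohort.n_samples == 0:
        raise CohortError("cohort has no samples")
    qualifying = [
        m for m in cohort.mutations
        if not (nonsynonymous_only and m.variant_class in SYNONYMOUS_CLASSES)
    ]
    genes: dict[str, None] = {}
    for m in qualifying:
        genes.setdefault(m.gene, None)
    gene_ix = {g: i for i, g in enumerate(genes)}
    samp_ix = {s: j for j, s in enumerate(cohort.sample_ids)}
    data = np.zeros((len(gene_ix), len(samp_ix)), dtype=np.int8)
    for m in qualifying:
        data[gene_ix[m.gene], samp_ix[m.sample_id]] = 1
    return MutationMatrix(data=data, genes=list(genes), samples=list(cohort.sample_ids))
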