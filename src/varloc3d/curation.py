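"""Reading, validation and curation of protein-level variant tables.

Variants arrive as TSV tables (ClinVar-like germline records, COSMIC/MAF-like
somatic records, or a generic dialect carrying both) and are curated into five
analysis classes: germline pathogenic / benign / VUS, and somatic primary /
metastatic.  Somatic records pass a recurrence filter (observed in at least
two tumour samples) and synonymous changes are excluded.  Rejected rows are
never silently dropped: every input row either yields a
:class:`VariantRecord` or is logged with a reason code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")
CONSEQUENCE_TAGS = {"missense", "nonsense", "frameshift", "inframe_del", "synonymous"}

GERMLINE_CLASSES = ("pathogenic", "benign", "vus")
TUMOUR_STAGES = ("primary", "metastatic")
ANALYSIS_CLASSES = GERMLINE_CLASSES + TUMOUR_STAGES

_GERMLINE_MAP = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "pathogenic",
    "pathogenic/likely pathogenic": "pathogenic",
    "benign": "benign",
    "likely benign": "benign",
    "benign/likely benign": "benign",
    "uncertain significance": "vus",
    "variant of uncertain significance": "vus",
    "vus": "vus",
}


@dataclass(frozen=True)
class ProteinRecord:
    """A protein-coding gene product with the attributes the analyses need."""

    gene_symbol: str
    protein_id: str
    length: int
    is_ddr: bool = False
    pathways: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be nonempty")
        if self.length < 1:
            raise ValueError(f"protein length must be >= 1, got {self.length}")


@dataclass(frozen=True)
class VariantRecord:
    """One protein-level variant.

    ``alt`` is either a one-letter amino-acid code, ``"*"`` for a stop gain,
    or a consequence tag (missense, nonsense, frameshift, inframe_del,
    synonymous).  Frameshift / stop-gain variants are assigned the 1-based
    index of their first affected residue.
    """

    gene_symbol: str
    position: int
    ref_aa: str
    alt: str
    origin: str  # germline | somatic
    germline_class: str = "none"  # pathogenic | benign | vus | none
    tumour_stage: str = "none"  # primary | metastatic | none
    sample_count: int = 0
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise ValueError("gene_symbol must be nonempty")
        if self.position < 1:
            raise ValueError(f"position must be a 1-based index, got {self.position}")
        if self.origin not in ("germline", "somatic"):
            raise ValueError(f"origin must be germline|somatic, got {self.origin!r}")
        if self.ref_aa and self.ref_aa not in AA_CODES:
            raise ValueError(f"ref_aa must be a one-letter code or empty, got {self.ref_aa!r}")
        if not (self.alt in AA_CODES or self.alt == "*" or self.alt in CONSEQUENCE_TAGS):
            raise ValueError(f"invalid alt {self.alt!r}")
        if self.sample_count < 0:
            raise ValueError("sample_count must be non-negative")
        if self.origin == "germline":
            if self.germline_class not in GERMLINE_CLASSES:
                raise ValueError("germline variant requires germline_class in "
                                 f"{GERMLINE_CLASSES}, got {self.germline_class!r}")
            if self.tumour_stage != "none":
                raise ValueError("germline variant must have tumour_stage 'none'")
        else:
            if self.tumour_stage not in TUMOUR_STAGES:
                raise ValueError("somatic variant requires tumour_stage in "
                                 f"{TUMOUR_STAGES}, got {self.tumour_stage!r}")
            if self.germline_class != "none":
                raise ValueError("somatic variant must have germline_class 'none'")

    @property
    def analysis_class(self) -> str:
        """One of pathogenic/benign/vus/primary/metastatic."""
        return self.germline_class if self.origin == "germline" else self.tumour_stage

    def check_against(self, protein: ProteinRecord) -> None:
        if self.position > protein.length:
            raise ValueError(
                f"{self.gene_symbol} position {self.position} beyond protein "
                f"length {protein.length}")


@dataclass(frozen=True)
class CohortCount:
    """Carriers of variants in one gene within one published cohort."""

    study_label: str
    gene_symbol: str
    carrier_count: int
    n_patients: int

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0 <= self.carrier_count <= self.n_patients:
            raise ValueError("carrier_count must lie in [0, n_patients]")


@dataclass
class CurationResult:
    """Outcome of reading a variant table: retained records plus a reject log."""

    variants: list[VariantRecord] = field(default_factory=list)
    rejected: list[tuple[int, str]] = field(default_factory=list)  # (row index, reason code)

    @property
    def n_total(self) -> int:
        return len(self.variants) + len(self.rejected)


class FormatError(ValueError):
    """A table is missing required columns or is otherwise unreadable."""


_DIALECT_COLUMNS = {
    "generic": ["gene", "position", "ref_aa", "alt", "origin", "class_or_stage", "sample_count"],
    "clinvar_like": ["gene", "position", "ref_aa", "alt", "clinical_significance"],
    "cosmic_like": ["gene", "position", "ref_aa", "alt", "tumour_stage", "sample_count"],
}


def classify_germline(raw_significance: str) -> Optional[str]:
    """Map a free-text clinical-significance annotation onto the three
    germline analysis classes, or ``None`` for anything unclear.

    Pathogenic and likely-pathogenic collapse to ``pathogenic``; benign and
    likely-benign to ``benign``; uncertain-significance to ``vus``.
    Conflicting, risk-factor, drug-response etc. annotations are rejected
    (returned as ``None``), mirroring curation that discards unclear records.
    """
    key = " ".join(str(raw_significance).strip().lower().replace("_", " ").split())
    return _GERMLINE_MAP.get(key)


def read_variants(path: str | Path, dialect: str = "generic") -> CurationResult:
    """Read a variant TSV into :class:`VariantRecord` objects.

    Supported dialects: ``generic`` (explicit origin + class_or_stage
    columns), ``clinvar_like`` (germline; class from a clinical_significance
    column), ``cosmic_like`` (somatic; stage + sample recurrence columns).
    Lines starting with ``#`` are comments.  Every row is either retained or
    appended to the reject log with a reason code; order is preserved.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise FormatError(f"unknown dialect {dialect!r}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in _DIALECT_COLUMNS[dialect] if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing} for dialect {dialect!r}")

    result = CurationResult()
    for i, row in enumerate(df.itertuples(index=False)):
        rec, reason = _parse_row(row._asdict(), dialect)
        if rec is None:
            result.rejected.append((i, reason))
        else:
            result.variants.append(rec)
    return result


def _parse_row(row: dict, dialect: str) -> tuple[Optional[VariantRecord], str]:
    try:
        position = int(str(row["position"]).strip())
    except (TypeError, ValueError):
        return None, "bad_position"
    fields = dict(
        gene_symbol=str(row["gene"]).strip(),
        position=position,
        ref_aa=str(row.get("ref_aa", "")).strip(),
        alt=str(row["alt"]).strip(),
        source_label=str(row.get("source", "")).strip(),
    )
    try:
        if dialect == "clinvar_like":
            cls = classify_germline(row["clinical_significance"])
            if cls is None:
                return None, "unclear_significance"
            rec = VariantRecord(origin="germline", germline_class=cls, **fields)
        elif dialect == "cosmic_like":
            rec = VariantRecord(
                origin="somatic",
                tumour_stage=str(row["tumour_stage"]).strip().lower(),
                sample_count=int(str(row["sample_count"]).strip()),
                **fields,
            )
        else:
            origin = str(row["origin"]).strip().lower()
            label = str(row["class_or_stage"]).strip().lower()
            sample_count = int(str(row["sample_count"]).strip() or 0)
            if origin == "germline":
                cls = classify_germline(label) or (label if label in GERMLINE_CLASSES else None)
                if cls is None:
                    return None, "unclear_significance"
                rec = VariantRecord(origin="germline", germline_class=cls,
                                    sample_count=sample_count, **fields)
            else:
                rec = VariantRecord(origin=origin, tumour_stage=label,
                                    sample_count=sample_count, **fields)
    except ValueError:
        return None, "invalid_record"
    return rec, ""


def filter_somatic(variants: Iterable[VariantRecord], min_samples: int = 2) -> list[VariantRecord]:
    """Recurrence filter for somatic variants.

    Keeps records observed in at least ``min_samples`` tumour samples and
    drops synonymous changes; putative-driver curation keeps only variants
    recurring in two or more samples.  Germline input is a contract violation.
    """
    variants = list(variants)
    for v in variants:
        if v.origin != "somatic":
            raise ValueError(f"filter_somatic received a germline record: {v}")
    return [v for v in variants
            if v.sample_count >= min_samples and v.alt != "synonymous"]


def dedupe_variants(variants: Iterable[VariantRecord]) -> list[VariantRecord]:
    """Collapse duplicate rows (same gene/position/alt/origin/class), summing
    sample_count — COSMIC-style recurrence semantics."""
    merged: dict[tuple, VariantRecord] = {}
    for v in variants:
        key = (v.gene_symbol, v.position, v.alt, v.origin, v.germline_class, v.tumour_stage)
        if key in merged:
            prev = merged[key]
            merged[key] = VariantRecord(
                gene_symbol=v.gene_symbol, position=v.position, ref_aa=prev.ref_aa,
                alt=v.alt, origin=v.origin, germline_class=v.germline_class,
                tumour_stage=v.tumour_stage,
                sample_count=prev.sample_count + v.sample_count,
                source_label=prev.source_label)
        else:
            merged[key] = v
    return list(merged.values())


def carrier_percentage(c: CohortCount, decimals: int = 1) -> float:
    """Percentage of patients in a cohort carrying a variant in one gene,
    rounded half-even to the requested number of decimals."""
    pct = Decimal(100) * Decimal(c.carrier_count) / Decimal(c.n_patients)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_EVEN))


def read_cohorts(path: str | Path) -> list[CohortCount]:
    """Read a cohort TSV with columns study, gene, carriers, n."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["study", "gene", "carriers", "n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s) {missing}")
    return [CohortCount(str(r.study), str(r.gene), int(r.carriers), int(r.n))
            for r in df.itertuples(index=False)]
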