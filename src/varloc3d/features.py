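"""Annotation of variants against sequence feature tracks.

Feature tracks are labelled interval sets on a protein sequence: Pfam domain
spans, protein-interaction interface residues, and intrinsically disordered
regions (IDRs).  Intervals are 1-based inclusive (the Pfam/UniProt
convention); a converter from 0-based half-open (BED) coordinates is
provided.  Interface tracks given as residue lists are stored as length-1
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .curation import ProteinRecord, VariantRecord

TRACK_KINDS = ("pfam_domain", "interface", "idr")


@dataclass(frozen=True)
class FeatureTrack:
    """Labelled intervals of one kind on one protein.

    ``intervals`` are 1-based inclusive (start, end) pairs; within a single
    track they may not overlap one another.
    """

    protein_id: str
    kind: str
    intervals: tuple[tuple[int, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"kind must be one of {TRACK_KINDS}, got {self.kind!r}")
        ivs = tuple(sorted((int(s), int(e)) for s, e in self.intervals))
        for s, e in ivs:
            if not 1 <= s <= e:
                raise ValueError(f"invalid interval ({s}, {e})")
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping intervals within one track: {ivs}")
        object.__setattr__(self, "intervals", ivs)

    def contains(self, position: int) -> bool:
        return any(s <= position <= e for s, e in self.intervals)

    @property
    def n_residues(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)

    @classmethod
    def from_residues(cls, protein_id: str, kind: str, residues: Iterable[int],
                      label: str = "") -> "FeatureTrack":
        """Build a track from a bare residue list (e.g. interface residues)."""
        ivs = tuple((r, r) for r in sorted(set(int(r) for r in residues)))
        return cls(protein_id, kind, ivs, label)


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: VariantRecord
    in_domain: bool
    domain_labels: frozenset[str]
    in_interface: bool
    in_idr: bool
    structure_hits: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.in_domain != bool(self.domain_labels):
            raise ValueError("domain_labels must be nonempty iff in_domain")


def bed_to_protein_interval(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open [start, end) interval to 1-based inclusive."""
    if end0 <= start0:
        raise ValueError(f"empty BED interval [{start0}, {end0})")
    return start0 + 1, end0


def protein_to_bed_interval(start1: int, end1: int) -> tuple[int, int]:
    return start1 - 1, end1


def annotate_variant(v: VariantRecord, tracks: Sequence[FeatureTrack],
                     protein: Optional[ProteinRecord] = None) -> AnnotatedVariant:
    """Flag a variant's membership in domain/interface/IDR tracks.

    A membership flag is true iff the variant position lies in at least one
    interval of the corresponding kind; all matching domain labels are
    collected.
    """
    if protein is not None:
        v.check_against(protein)
    domain_labels = frozenset(
        t.label for t in tracks if t.kind == "pfam_domain" and t.contains(v.position))
    return AnnotatedVariant(
        variant=v,
        in_domain=bool(domain_labels),
        domain_labels=domain_labels,
        in_interface=any(t.kind == "interface" and t.contains(v.position) for t in tracks),
        in_idr=any(t.kind == "idr" and t.contains(v.position) for t in tracks),
    )


def annotate_variants(variants: Iterable[VariantRecord],
                      tracks_by_protein: dict[str, Sequence[FeatureTrack]]
                      ) -> list[AnnotatedVariant]:
    """Annotate a variant list, looking tracks up by gene symbol."""
    return [annotate_variant(v, tracks_by_protein.get(v.gene_symbol, ())) for v in variants]


def count_by_feature(annotated: Iterable[AnnotatedVariant],
                     class_filter: Optional[Iterable[str]] = None) -> pd.DataFrame:
    """Tally variants per (analysis class, feature kind) and per domain label.

    Returns a tidy frame with columns class, kind, label, count.  Rows with
    ``label == "*"`` are per-kind totals, counting a variant once however
    many intervals or labels of that kind it hits; per-label rows count it
    once per matching label.  ``label == "total"`` under kind ``"any"`` is
    the class size.
    """
    keep = set(class_filter) if class_filter is not None else None
    rows: dict[tuple[str, str, str], int] = {}

    def bump(cls: str, kind: str, label: str) -> None:
        rows[(cls, kind, label)] = rows.get((cls, kind, label), 0) + 1

    for av in annotated:
        cls = av.variant.analysis_class
        if keep is not None and cls not in keep:
            continue
        bump(cls, "any", "total")
        if av.in_domain:
            bump(cls, "pfam_domain", "*")
            for label in sorted(av.domain_labels):
                bump(cls, "pfam_domain", label)
        if av.in_interface:
            bump(cls, "interface", "*")
        if av.in_idr:
            bump(cls, "idr", "*")

    df = pd.DataFrame(
        [(c, k, l, n) for (c, k, l), n in rows.items()],
        columns=["class", "kind", "label", "count"],
    )
    return df.sort_values(["class", "kind", "label"], ignore_index=True)


def read_features(path: str | Path, coords: str = "protein") -> list[FeatureTrack]:
    """Read a feature TSV with columns protein, kind, start, end, label.

    ``coords="protein"`` expects 1-based inclusive intervals; ``coords="bed"``
    declares 0-based half-open input and converts.
    """
    if coords not in ("protein", "bed"):
        raise ValueError(f"coords must be 'protein' or 'bed', got {coords!r}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"label": str},
                     keep_default_na=False)
    required = ["protein", "kind", "start", "end", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing}")
    tracks = []
    # one track per (protein, kind, label) grouping of rows
    for (protein, kind, label), grp in df.groupby(["protein", "kind", "label"], sort=False):
        ivs = []
        for r in grp.itertuples(index=False):
            s, e = int(r.start), int(r.end)
            if coords == "bed":
                s, e = bed_to_protein_interval(s, e)
            ivs.append((s, e))
        tracks.append(FeatureTrack(str(protein), str(kind), tuple(ivs), str(label)))
    return tracks


def write_features(tracks: Iterable[FeatureTrack], path: str | Path) -> None:
    rows = [(t.protein_id, t.kind, s, e, t.label)
            for t in tracks for s, e in t.intervals]
    pd.DataFrame(rows, columns=["protein", "kind", "start", "end", "label"]).to_csv(
        path, sep="\t", index=False)
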