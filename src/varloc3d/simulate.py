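"""Seeded generators for every input the pipeline consumes.

The generators emulate the shape of the real study inputs at desk scale:
proteins with log-normal lengths clipped to the observed 44-7,968 aa range,
non-overlapping Pfam-like domain intervals covering a configured fraction of
each sequence, interface residues with configurable overlap with
intrinsically disordered regions, class-labelled variants with controllable
domain/interface enrichment, C-alpha traces (ideal alpha-helix or
self-avoiding walk) with optionally planted 3D variant clusters, a
protein-interaction edge list, and tumor/background cohort count matrices
for uEMD scoring.  Every generator is a pure function of (config, seed);
ground-truth labels go to sidecar tables, never into the analysis-facing
files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

from .cluster3d import StructureModel
from .curation import ProteinRecord, VariantRecord
from .features import FeatureTrack

AA = "ACDEFGHIKLMNPQRSTVWY"

# Study-shaped defaults: class sizes follow the curated-dataset proportions
# (pathogenic 10,301 : benign 1,117 : VUS 28,248 : primary 5,795 :
# metastatic 2,030) scaled down 10x for desk-scale runs.
DEFAULT_CLASS_COUNTS = {
    "pathogenic": 1030, "benign": 112, "vus": 2825, "primary": 580, "metastatic": 203,
}

LENGTH_MIN, LENGTH_MAX = 44, 7968


@dataclass(frozen=True)
class PlantedCluster:
    """Ground truth for one planted 3D cluster: k variant positions whose
    representative coordinates lie within ``max_diameter`` Angstroms."""

    gene: str
    k: int
    max_diameter: float
    class_label: str = "pathogenic"


@dataclass
class SimConfig:
    n_proteins: int = 120
    ddr_fraction: float = 229 / 1411  # DDR share of network nodes
    length_mu: float = 6.1  # log-normal log-mean -> mean length ~ 735 aa
    length_sigma: float = 1.0
    domain_coverage: float = 0.25
    interface_coverage: float = 0.12
    idr_coverage: float = 0.20
    idr_interface_overlap: float = 0.5
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    theta_domain: float | Mapping[str, float] = 1.0
    theta_interface: float | Mapping[str, float] = 1.0
    planted_clusters: tuple[PlantedCluster, ...] = ()
    # cohort generation
    n_genes: int = 200
    n_tumor: int = 200
    n_background: int = 200
    base_rate: float = 1.0
    rate_sigma: float = 0.5
    exposure_sigma: float = 0.3
    driver_genes: tuple[str, ...] = ()
    driver_multiplier: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("domain_coverage", "interface_coverage", "idr_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.9:
                raise ValueError(f"{name} must lie in [0, 0.9], got {v}")
        if isinstance(self.theta_domain, (int, float)) and self.theta_domain < 0:
            raise ValueError("theta_domain must be >= 0")
        if isinstance(self.theta_interface, (int, float)) and self.theta_interface < 0:
            raise ValueError("theta_interface must be >= 0")


def _theta(value: float | Mapping[str, float], cls: str) -> float:
    return float(value[cls]) if isinstance(value, Mapping) else float(value)


def _random_intervals(length: int, coverage: float, rng: np.random.Generator,
                      typical: int = 120) -> list[tuple[int, int]]:
    """Non-overlapping 1-based inclusive intervals whose total residue count
    equals round(coverage * length) exactly."""
    total = int(round(coverage * length))
    if total == 0:
        return []
    k = max(1, min(total, total // typical if total >= typical else 1))
    # split covered residues into k pieces of >= 1 each
    cuts = np.sort(rng.choice(total - 1, size=k - 1, replace=False)) + 1 if k > 1 else np.array([], int)
    lengths = np.diff(np.concatenate([[0], cuts, [total]])).astype(int)
    gaps = rng.multinomial(length - total, np.full(k + 1, 1.0 / (k + 1)))
    intervals = []
    pos = 1
    for gap, seg in zip(gaps, lengths):
        start = pos + int(gap)
        intervals.append((start, start + int(seg) - 1))
        pos = start + int(seg)
    return intervals


def gen_proteins(config: SimConfig, rng: Optional[np.random.Generator] = None
                 ) -> tuple[dict[str, ProteinRecord], dict[str, list[FeatureTrack]]]:
    """Generate proteins with domain / interface / IDR tracks.

    Lengths are log-normal clipped to [44, 7968] aa; domain and IDR
    intervals are non-overlapping within their tracks and cover the
    configured sequence fraction exactly (up to rounding); interface
    residues are sampled with the configured overlap with IDR residues.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_ddr = int(round(config.n_proteins * config.ddr_fraction))
    proteins: dict[str, ProteinRecord] = {}
    tracks: dict[str, list[FeatureTrack]] = {}
    for i in range(config.n_proteins):
        gene = f"G{i:04d}"
        length = int(np.clip(round(rng.lognormal(config.length_mu, config.length_sigma)),
                             LENGTH_MIN, LENGTH_MAX))
        proteins[gene] = ProteinRecord(
            gene_symbol=gene, protein_id=f"P{i:04d}", length=length,
            is_ddr=i < n_ddr)
        trk: list[FeatureTrack] = []
        for j, (s, e) in enumerate(_random_intervals(length, config.domain_coverage, rng)):
            trk.append(FeatureTrack(gene, "pfam_domain", ((s, e),),
                                    label=f"PF{rng.integers(0, 99999):05d}.{j}"))
        idr_ivs = _random_intervals(length, config.idr_coverage, rng, typical=80)
        if idr_ivs:
            trk.append(FeatureTrack(gene, "idr", tuple(idr_ivs), label="idr"))
        n_if = int(round(config.interface_coverage * length))
        if n_if:
            idr_res = np.array([r for s, e in idr_ivs for r in range(s, e + 1)], int)
            n_from_idr = min(int(round(config.idr_interface_overlap * n_if)), idr_res.size)
            chosen = set()
            if n_from_idr:
                chosen.update(rng.choice(idr_res, size=n_from_idr, replace=False).tolist())
            pool = np.setdiff1d(np.arange(1, length + 1), np.fromiter(chosen, int, len(chosen)))
            extra = rng.choice(pool, size=min(n_if - len(chosen), pool.size), replace=False)
            chosen.update(extra.tolist())
            trk.append(FeatureTrack.from_residues(gene, "interface", chosen, label="iface"))
        tracks[gene] = trk
    return proteins, tracks


def gen_structure(n_residues: int, mode: str = "saw",
                  rng: Optional[np.random.Generator | int] = None,
                  structure_id: Optional[str] = None) -> StructureModel:
    """Generate a C-alpha trace with 3.8 A virtual bonds.

    ``helix`` places residues on ideal alpha-helix geometry (1.5 A rise,
    100 degrees per residue, radius chosen so consecutive C-alpha distance
    is exactly 3.8 A).  ``saw`` grows a self-avoiding random walk whose
    non-bonded residue pairs stay >= 4.0 A apart (backtracking on dead
    ends).
    """
    if n_residues < 2:
        raise ValueError("n_residues must be >= 2")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    if mode == "helix":
        rise, turn = 1.5, math.radians(100.0)
        radius = math.sqrt(3.8**2 - rise**2) / (2.0 * math.sin(turn / 2.0))
        i = np.arange(n_residues)
        coords = np.column_stack([radius * np.cos(i * turn),
                                  radius * np.sin(i * turn),
                                  rise * i])
    elif mode == "saw":
        coords = _self_avoiding_walk(n_residues, rng)
    else:
        raise ValueError(f"mode must be helix|saw, got {mode!r}")
    return StructureModel(
        structure_id=structure_id or f"sim_{mode}_{n_residues}",
        positions=tuple(range(1, n_residues + 1)),
        coords=coords, atom_convention="c_alpha", note=f"synthetic {mode} trace")


def _self_avoiding_walk(n: int, rng: np.random.Generator, step: float = 3.8,
                        exclusion: float = 4.0, tries_per_step: int = 60,
                        max_backtracks: int = 20000) -> np.ndarray:
    pts = [np.zeros(3)]
    backtracks = 0
    while len(pts) < n:
        placed = False
        for _ in range(tries_per_step):
            v = rng.normal(size=3)
            cand = pts[-1] + step * v / np.linalg.norm(v)
            if len(pts) < 2:
                placed = True
            else:
                d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
                placed = bool(d.min() >= exclusion)
            if placed:
                pts.append(cand)
                break
        if not placed:
            if len(pts) == 1 or backtracks >= max_backtracks:
                raise RuntimeError("self-avoiding walk failed; increase retries")
            pts.pop()
            backtracks += 1
    return np.asarray(pts)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as a C-alpha-only PDB file (chain A, ALA)."""
    st = gemmi.Structure()
    st.name = structure.structure_id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for pos, xyz in zip(structure.positions, structure.coords):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(pos), " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*map(float, xyz))
        atom.occ = 1.0
        res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def plant_cluster(structure: StructureModel, k: int, max_diameter: float,
                  rng: np.random.Generator) -> tuple[int, ...]:
    """Choose k residue positions whose coordinates lie within a ball of
    diameter ``max_diameter`` (so pairwise distances <= max_diameter)."""
    coords = structure.coords
    order = rng.permutation(structure.n_residues)
    for center_idx in order:
        d = np.linalg.norm(coords - coords[center_idx], axis=1)
        ball = np.nonzero(d <= max_diameter / 2.0)[0]
        if ball.size >= k:
            pick = rng.choice(ball, size=k, replace=False)
            return tuple(sorted(structure.positions[i] for i in pick))
    raise ValueError(f"no ball of diameter {max_diameter} A holds {k} residues")


def gen_variants(config: SimConfig,
                 proteins: Mapping[str, ProteinRecord],
                 tracks: Mapping[str, Sequence[FeatureTrack]],
                 structures: Optional[Mapping[str, StructureModel]] = None,
                 rng: Optional[np.random.Generator] = None
                 ) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Generate class-labelled variants with controllable feature enrichment.

    Positions are drawn from a per-residue mixture: weight theta_domain
    inside domain intervals and theta_interface on interface residues
    (multiplicative where both apply), uniform elsewhere.  Planted 3D
    clusters add k positions within the stated diameter on the named
    structure.  Returns the variants plus a ground-truth sidecar table
    (gene, position, class, planted_cluster id).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = list(proteins)
    lengths = np.array([proteins[g].length for g in genes], float)
    gene_p = lengths / lengths.sum()

    weight_cache: dict[tuple[str, float, float], np.ndarray] = {}

    def weights(gene: str, td: float, ti: float) -> np.ndarray:
        key = (gene, td, ti)
        if key not in weight_cache:
            L = proteins[gene].length
            w = np.ones(L)
            for t in tracks.get(gene, ()):
                mask = np.zeros(L, bool)
                for s, e in t.intervals:
                    mask[s - 1:e] = True
                if t.kind == "pfam_domain":
                    w[mask] *= td
                elif t.kind == "interface":
                    w[mask] *= ti
            total = w.sum()
            if total == 0:
                w = np.ones(L)
                total = L
            weight_cache[key] = w / total
        return weight_cache[key]

    variants: list[VariantRecord] = []
    truth_rows: list[tuple] = []
    for cls, count in config.class_counts.items():
        td = _theta(config.theta_domain, cls)
        ti = _theta(config.theta_interface, cls)
        origin = "germline" if cls in ("pathogenic", "benign", "vus") else "somatic"
        gidx = rng.choice(len(genes), size=count, p=gene_p)
        for gi in gidx:
            gene = genes[gi]
            pos = int(rng.choice(proteins[gene].length, p=weights(gene, td, ti))) + 1
            variants.append(_make_variant(gene, pos, cls, origin, rng))
            truth_rows.append((gene, pos, cls, ""))

    for ci, plant in enumerate(config.planted_clusters):
        if structures is None or plant.gene not in structures:
            raise ValueError(f"planted cluster references unknown structure {plant.gene!r}")
        positions = plant_cluster(structures[plant.gene], plant.k,
                                  plant.max_diameter, rng)
        origin = "germline" if plant.class_label in ("pathogenic", "benign", "vus") else "somatic"
        for pos in positions:
            variants.append(_make_variant(plant.gene, pos, plant.class_label, origin, rng))
            truth_rows.append((plant.gene, pos, plant.class_label, f"cluster{ci}"))

    truth = pd.DataFrame(truth_rows, columns=["gene", "position", "class",
                                              "planted_cluster"])
    return variants, truth


def _make_variant(gene: str, pos: int, cls: str, origin: str,
                  rng: np.random.Generator) -> VariantRecord:
    ref = AA[rng.integers(len(AA))]
    alt = AA[rng.integers(len(AA))]
    while alt == ref:
        alt = AA[rng.integers(len(AA))]
    if origin == "germline":
        return VariantRecord(gene_symbol=gene, position=pos, ref_aa=ref, alt=alt,
                             origin="germline", germline_class=cls,
                             source_label="sim")
    return VariantRecord(gene_symbol=gene, position=pos, ref_aa=ref, alt=alt,
                         origin="somatic", tumour_stage=cls,
                         sample_count=int(rng.integers(2, 20)), source_label="sim")


def gen_cohorts(config: SimConfig, rng: Optional[np.random.Generator] = None):
    """Generate tumor and background individuals x genes count matrices.

    Counts are Poisson(rate_gene * exposure_individual) with log-normal
    per-gene rates and per-individual exposures; genes listed in
    ``config.driver_genes`` get their tumor-cohort rate multiplied by
    ``driver_multiplier``.  Returns (tumor, background) CohortMatrix pair.
    """
    from .uemd import CohortMatrix

    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    rates = config.base_rate * rng.lognormal(0.0, config.rate_sigma, size=config.n_genes)
    tumor_rates = rates.copy()
    for g in config.driver_genes:
        tumor_rates[genes.index(g)] *= config.driver_multiplier

    def draw(n_ind: int, gene_rates: np.ndarray) -> pd.DataFrame:
        exposure = rng.lognormal(0.0, config.exposure_sigma, size=n_ind)
        lam = np.outer(exposure, gene_rates)
        return pd.DataFrame(rng.poisson(lam), columns=genes,
                            index=[f"I{i:04d}" for i in range(n_ind)])

    tumor = CohortMatrix("sim_tumor", "tumor", draw(config.n_tumor, tumor_rates))
    background = CohortMatrix("sim_background", "background",
                              draw(config.n_background, rates))
    return tumor, background


def gen_network(config: SimConfig, proteins: Mapping[str, ProteinRecord],
                rng: Optional[np.random.Generator] = None,
                p_base: float = 0.02, p_ddr: float = 0.15
                ) -> list[tuple[str, str]]:
    """Erdos-Renyi-style edge list over the generated proteins, with a
    higher connection probability among DDR genes (hubs)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    genes = list(proteins)
    edges = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            both_ddr = proteins[genes[i]].is_ddr and proteins[genes[j]].is_ddr
            if rng.random() < (p_ddr if both_ddr else p_base):
                edges.append((genes[i], genes[j]))
    return edges


def write_variants(variants: Iterable[VariantRecord], path: str | Path) -> None:
    """Write variants in the generic TSV dialect accepted by read_variants."""
    rows = [(v.gene_symbol, v.position, v.ref_aa, v.alt, v.origin,
             v.analysis_class, v.sample_count) for v in variants]
    pd.DataFrame(rows, columns=["gene", "position", "ref_aa", "alt", "origin",
                                "class_or_stage", "sample_count"]).to_csv(
        path, sep="\t", index=False)


def write_cohort_matrix(matrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="individual")


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(edges, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)
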