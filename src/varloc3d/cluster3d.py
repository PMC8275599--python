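"""3D clustering of variants on protein structures with a bootstrap null.

Variant positions are mapped to one representative coordinate per residue
(the C-alpha atom, or the side-chain heavy-atom centroid) on a PDB-format
chain.  Clusters are found by complete-linkage agglomerative clustering cut
at a maximum cluster diameter CL (default 30.0 A): merging stops as soon as
a merge would exceed CL, so every reported cluster's maximum pairwise
distance is <= CL.  Clusters smaller than ``min_size`` (default 3) are
discarded.

Significance is assessed empirically: in each of ``n_boot`` iterations
(default 10,000) the same number of substitutions is placed uniformly at
random on the structure's residues, the clustering is re-run, and the
diameter of the tightest null cluster with at least as many members as the
observed one is recorded (infinity if none forms).  The p-value is the
percentile rank (b + 1) / (n_boot + 1), where b counts null iterations at
least as tight as observed; its floor at 10,000 iterations is 1/10,001,
about 9.9e-5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numba
import numpy as np
import gemmi
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .curation import VariantRecord

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class StructureModel:
    """Ordered residue -> 3D coordinate map for one protein chain.

    ``positions`` are strictly increasing sequence positions (structure
    numbering); ``coords`` the matching representative coordinates in
    Angstroms.  ``mapping`` optionally translates protein (e.g. UniProt)
    numbering to structure numbering; by default the two are identical.
    """

    structure_id: str
    positions: tuple[int, ...]
    coords: np.ndarray  # (n, 3) float
    atom_convention: str = "c_alpha"
    mapping: Optional[Mapping[int, int]] = None
    note: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(self.positions), 3):
            raise ValueError("coords must be (n_residues, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("residue positions must be strictly increasing")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(
            self, "_index", {p: i for i, p in enumerate(self.positions)})

    def resolve(self, protein_position: int) -> Optional[int]:
        """Structure-residue index for a protein sequence position, or None
        if the position is not covered by the model."""
        pos = protein_position
        if self.mapping is not None:
            if protein_position not in self.mapping:
                return None
            pos = self.mapping[protein_position]
        return self._index.get(pos)

    def coord_of(self, protein_position: int) -> Optional[np.ndarray]:
        i = self.resolve(protein_position)
        return None if i is None else self.coords[i]

    @property
    def n_residues(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class ClusterParams:
    cl_diameter: float = 30.0
    min_size: int = 3
    n_boot: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cl_diameter <= 0:
            raise ValueError("cl_diameter must be > 0")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")


@dataclass(frozen=True)
class Cluster3D:
    """A set of variant positions proximal in 3D.

    ``p_value`` is the per-cluster empirical p (the cluster's diameter ranked
    against the tightest null cluster of at least its size).  ``p_adjusted``
    is the family-wise p of the cluster's tightest sub-cluster ("core"),
    corrected across all candidate cluster sizes by a min-P (Westfall-Young)
    adjustment on the same bootstrap null; it is the value to threshold when
    asking whether a structure carries any significant hotspot.
    """

    members: tuple[int, ...]  # protein sequence positions, sorted
    diameter: float
    p_value: Optional[float] = None
    n_boot: int = 0
    p_adjusted: Optional[float] = None
    core_members: Optional[tuple[int, ...]] = None
    core_diameter: Optional[float] = None


class ChainNotFoundError(ValueError):
    pass


def read_structure(path: str | Path, chain: str,
                   atom_convention: str = "c_alpha",
                   mapping: Optional[Mapping[int, int]] = None) -> StructureModel:
    """Read one chain of a PDB file into a residue->coordinate map.

    ``atom_convention`` picks the representative point per residue: the
    C-alpha atom, or the mean of side-chain heavy atoms (falling back to
    C-alpha for glycine or residues with no modelled side chain).  Where a
    residue has alternate locations, the highest-occupancy altloc of each
    atom is used.  Residues lacking any usable atom are skipped.
    """
    if atom_convention not in ("c_alpha", "sidechain_centroid"):
        raise ValueError(f"unknown atom_convention {atom_convention!r}")
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    model = st[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise ChainNotFoundError(f"chain {chain!r} not found in {path}")
    positions: list[int] = []
    coords: list[tuple[float, float, float]] = []
    for res in ch:
        xyz = _representative_coord(res, atom_convention)
        if xyz is None:
            continue
        positions.append(res.seqid.num)
        coords.append(xyz)
    if not positions:
        raise ValueError(f"no usable residues on chain {chain!r} of {path}")
    return StructureModel(
        structure_id=f"{Path(path).stem}_{chain}",
        positions=tuple(positions),
        coords=np.asarray(coords, dtype=float),
        atom_convention=atom_convention,
        mapping=mapping,
        note=f"read from {Path(path).name}")


def _best_altloc(res: gemmi.Residue) -> dict[str, gemmi.Atom]:
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    return best


def _representative_coord(res: gemmi.Residue, convention: str):
    atoms = _best_altloc(res)
    ca = atoms.get("CA")
    if convention == "sidechain_centroid":
        side = [a for name, a in atoms.items()
                if name not in BACKBONE_ATOMS and a.element.name != "H"]
        if side:
            pts = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in side])
            return tuple(pts.mean(axis=0))
    if ca is None:
        return None
    return (ca.pos.x, ca.pos.y, ca.pos.z)


def map_positions(variants: Sequence[VariantRecord], structure: StructureModel
                  ) -> tuple[list[tuple[VariantRecord, np.ndarray]], list[VariantRecord]]:
    """Map variants onto structure coordinates.

    A variant maps iff its (mapping-adjusted) position resolves to a modelled
    residue; unmapped variants are returned, never silently dropped.
    """
    mapped, unmapped = [], []
    for v in variants:
        xyz = structure.coord_of(v.position)
        if xyz is None:
            unmapped.append(v)
        else:
            mapped.append((v, xyz))
    return mapped, unmapped


def diameter(positions: Sequence[int], structure: StructureModel) -> float:
    """Maximum pairwise Euclidean distance (A) among the representative
    coordinates of the given protein positions; 0 for a single position."""
    if len(positions) == 0:
        raise ValueError("at least one position required")
    coords = []
    for p in positions:
        xyz = structure.coord_of(p)
        if xyz is None:
            raise ValueError(f"position {p} is not mapped on {structure.structure_id}")
        coords.append(xyz)
    return _coord_diameter(np.asarray(coords))


def _coord_diameter(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    return float(pdist(coords).max())


def _cluster_coords(coords: np.ndarray, labels: Sequence[int], cl: float,
                    min_size: int) -> list[tuple[tuple[int, ...], float]]:
    """Complete-linkage clustering of labelled coordinates; returns
    (sorted member labels, diameter) for clusters of >= min_size."""
    n = len(coords)
    if n < min_size:
        return []
    assignments = fcluster(linkage(pdist(coords), method="complete"), t=cl,
                           criterion="distance")
    out = []
    for cid in np.unique(assignments):
        idx = np.nonzero(assignments == cid)[0]
        if len(idx) < min_size:
            continue
        members = tuple(sorted(labels[i] for i in idx))
        out.append((members, _coord_diameter(coords[idx])))
    out.sort(key=lambda c: (c[0][0], c[0]))
    return out


def find_clusters(mapped: Sequence[tuple[VariantRecord, np.ndarray]],
                  structure: StructureModel,
                  params: ClusterParams = ClusterParams()) -> list[Cluster3D]:
    """Find 3D clusters of mapped variant positions.

    Each distinct sequence position counts once regardless of how many
    variants or samples hit it.  Complete-linkage merging proceeds while the
    merged cluster's diameter stays <= CL; clusters below ``min_size`` are
    discarded.  Each position belongs to at most one cluster.
    """
    by_pos: dict[int, np.ndarray] = {}
    for v, xyz in mapped:
        by_pos.setdefault(v.position, np.asarray(xyz, dtype=float))
    if len(by_pos) < params.min_size:
        return []
    labels = sorted(by_pos)
    coords = np.asarray([by_pos[p] for p in labels])
    return [Cluster3D(members=m, diameter=d)
            for m, d in _cluster_coords(coords, labels, params.cl_diameter,
                                        params.min_size)]


@numba.njit(cache=False)
def _min_diam_by_size(D: np.ndarray, cl: float, min_size: int,
                      out_flat: np.ndarray, out_node: np.ndarray) -> None:
    """Complete-linkage clustering of a small distance matrix, cut at ``cl``.

    Fills ``out_flat[s]`` with the minimum diameter over flat-cut clusters
    having at least ``s`` members and ``out_node[s]`` with the minimum over
    all dendrogram nodes (tight sub-clusters) of at least ``s`` members
    (inf if none).  Merge height equals the merged cluster's diameter
    because complete linkage is monotone, so stopping at the first merge
    above ``cl`` reproduces the flat cut.
    """
    n = D.shape[0]
    C = D.copy()
    sizes = np.ones(n, np.int64)
    diam = np.zeros(n)
    alive = np.ones(n, numba.boolean)
    while True:
        bi, bj, bd = -1, -1, np.inf
        for i in range(n):
            if not alive[i]:
                continue
            for j in range(i + 1, n):
                if alive[j] and C[i, j] < bd:
                    bd = C[i, j]
                    bi, bj = i, j
        if bi < 0 or bd > cl:
            break
        sizes[bi] += sizes[bj]
        diam[bi] = bd
        alive[bj] = False
        if sizes[bi] >= min_size and bd < out_node[sizes[bi]]:
            out_node[sizes[bi]] = bd
        for m in range(n):
            if alive[m] and m != bi:
                d = C[bi, m] if C[bi, m] > C[bj, m] else C[bj, m]
                C[bi, m] = d
                C[m, bi] = d
    for i in range(n):
        if alive[i] and sizes[i] >= min_size and diam[i] < out_flat[sizes[i]]:
            out_flat[sizes[i]] = diam[i]
    for s in range(n - 1, min_size - 1, -1):  # suffix min: >= s members
        if out_flat[s + 1] < out_flat[s]:
            out_flat[s] = out_flat[s + 1]
        if out_node[s + 1] < out_node[s]:
            out_node[s] = out_node[s + 1]


@numba.njit(cache=False)
def _null_pass(coords: np.ndarray, placements: np.ndarray, cl: float,
               min_size: int) -> np.ndarray:
    """For each random placement (row of residue indices), the minimum null
    cluster diameter per size threshold: result[t, 0, s] over flat-cut
    clusters and result[t, 1, s] over dendrogram nodes with >= s members in
    iteration t (inf if none)."""
    n_boot, k = placements.shape
    out = np.full((n_boot, 2, k + 2), np.inf)
    D = np.empty((k, k))
    for t in range(n_boot):
        idx = placements[t]
        for a in range(k):
            D[a, a] = 0.0
            for b in range(a + 1, k):
                dx = coords[idx[a], 0] - coords[idx[b], 0]
                dy = coords[idx[a], 1] - coords[idx[b], 1]
                dz = coords[idx[a], 2] - coords[idx[b], 2]
                d = math.sqrt(dx * dx + dy * dy + dz * dz)
                D[a, b] = d
                D[b, a] = d
        _min_diam_by_size(D, cl, min_size, out[t, 0], out[t, 1])
    return out


def _draw_placements(structure: StructureModel, n_variants_total: int,
                     params: ClusterParams, rng: np.random.Generator) -> np.ndarray:
    placements = np.empty((params.n_boot, n_variants_total), np.int64)
    for t in range(params.n_boot):
        placements[t] = rng.choice(structure.n_residues, size=n_variants_total,
                                   replace=False)
    return placements


def bootstrap_pvalue(cluster: Cluster3D, n_variants_total: int,
                     structure: StructureModel,
                     params: ClusterParams = ClusterParams(),
                     rng: Optional[np.random.Generator] = None) -> float:
    """Empirical percentile-rank p-value for one observed cluster.

    Each iteration places ``n_variants_total`` substitutions uniformly at
    random (without replacement) on the structure's residues, re-runs the
    clustering, and records the diameter of the tightest null cluster with
    at least ``len(cluster.members)`` members (infinity if none).  The
    p-value is (b + 1) / (n_boot + 1) with b the number of iterations whose
    recorded diameter is <= the observed diameter.
    """
    k = len(cluster.members)
    if n_variants_total < k:
        raise ValueError("n_variants_total must be >= cluster size")
    if n_variants_total > structure.n_residues:
        raise ValueError("cannot place more substitutions than modelled residues")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    placements = _draw_placements(structure, n_variants_total, params, rng)
    null = _null_pass(structure.coords, placements, params.cl_diameter,
                      params.min_size)
    b = int((null[:, 0, min(k, n_variants_total)] <= cluster.diameter).sum())
    return (b + 1) / (params.n_boot + 1)


def analyze_structure(variants: Sequence[VariantRecord], structure: StructureModel,
                      params: ClusterParams = ClusterParams(),
                      rng: Optional[np.random.Generator] = None
                      ) -> tuple[list[Cluster3D], list[VariantRecord]]:
    """Map variants, find clusters, and attach bootstrap p-values.

    Returns (clusters with p-values, unmapped variants).  The null places as
    many substitutions as there are distinct mapped positions; one shared
    null pass serves every cluster of the run.

    Each reported (flat) cluster carries two significance measures.
    ``p_value`` ranks the cluster's own diameter against the tightest null
    cluster of at least its size.  Because a tight hotspot can be absorbed
    into a looser flat cluster, every dendrogram node inside the cluster is
    additionally evaluated at its own size, and the minimum node p is
    corrected for the implicit search across node sizes by a min-P
    (Westfall-Young) adjustment against the same bootstrap null; the result
    is ``p_adjusted`` with the winning node in ``core_members`` /
    ``core_diameter``.  ``p_adjusted`` is family-wise valid: under a uniform
    null the smallest reported ``p_adjusted`` is distributed no lower than
    uniform.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    mapped, unmapped = map_positions(variants, structure)
    n_distinct = len({v.position for v, _ in mapped})
    clusters = find_clusters(mapped, structure, params)
    if not clusters:
        return [], unmapped
    placements = _draw_placements(structure, n_distinct, params, rng)
    null = _null_pass(structure.coords, placements, params.cl_diameter,
                      params.min_size)
    flat_null, node_null = null[:, 0, :], null[:, 1, :]
    n_boot = params.n_boot

    # per-size sorted node nulls and the null distribution of the min
    # across-size rank (the Westfall-Young reference)
    k_cols = range(params.min_size, node_null.shape[1])
    sorted_cols = {k: np.sort(node_null[:, k]) for k in k_cols}
    min_rank = np.full(n_boot, 1.0)
    for k in k_cols:
        col = node_null[:, k]
        finite = np.isfinite(col)
        ranks = np.searchsorted(sorted_cols[k], col, side="right") / n_boot
        min_rank[finite] = np.minimum(min_rank[finite], ranks[finite])

    by_pos = {}
    for v, xyz in mapped:
        by_pos.setdefault(v.position, np.asarray(xyz, dtype=float))
    nodes = _dendrogram_nodes(by_pos, params.cl_diameter, params.min_size)

    out = []
    for c in clusters:
        k = min(len(c.members), n_distinct)
        b = int((flat_null[:, k] <= c.diameter).sum())
        member_set = set(c.members)
        best_p, best_node = np.inf, None
        for node_members, node_diam in nodes:
            if not set(node_members) <= member_set:
                continue
            kk = min(len(node_members), node_null.shape[1] - 1)
            p_node = (np.searchsorted(sorted_cols[kk], node_diam, side="right")
                      + 1) / (n_boot + 1)
            if p_node < best_p:
                best_p, best_node = p_node, (node_members, node_diam)
        p_adj = None
        core_members = core_diam = None
        if best_node is not None:
            b_adj = int((min_rank <= best_p).sum())
            p_adj = (b_adj + 1) / (n_boot + 1)
            core_members, core_diam = best_node
        out.append(replace(c, p_value=(b + 1) / (n_boot + 1), n_boot=n_boot,
                           p_adjusted=p_adj, core_members=core_members,
                           core_diameter=core_diam))
    return out, unmapped


def _dendrogram_nodes(by_pos: Mapping[int, np.ndarray], cl: float,
                      min_size: int) -> list[tuple[tuple[int, ...], float]]:
    """All complete-linkage dendrogram nodes with >= min_size members and
    diameter <= cl, as (sorted member positions, diameter)."""
    labels = sorted(by_pos)
    if len(labels) < 2:
        return []
    coords = np.asarray([by_pos[p] for p in labels])
    Z = linkage(pdist(coords), method="complete")
    members: dict[int, tuple[int, ...]] = {i: (labels[i],) for i in range(len(labels))}
    nodes = []
    for row_i, (a, b, height, _) in enumerate(Z):
        m = members[int(a)] + members[int(b)]
        members[len(labels) + row_i] = m
        if height <= cl and len(m) >= min_size:
            nodes.append((tuple(sorted(m)), float(height)))
    return nodes
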