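"""Structure reading, variant mapping, complete-linkage 3D clustering under a
maximum-diameter cut, and the bootstrap empirical p-value."""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from varloc3d.cluster3d import (ChainNotFoundError, Cluster3D, ClusterParams,
                                StructureModel, analyze_structure,
                                bootstrap_pvalue, diameter, find_clusters,
                                map_positions, read_structure)
from varloc3d.simulate import gen_structure, write_pdb

from conftest import make_somatic


def toy_structure(coords, positions=None):
    coords = np.asarray(coords, float)
    positions = positions or tuple(range(1, len(coords) + 1))
    return StructureModel("toy", tuple(positions), coords)


def mapped_at(structure, positions):
    variants = [make_somatic(pos=p) for p in positions]
    mapped, unmapped = map_positions(variants, structure)
    assert not unmapped
    return mapped


def pdb_line(serial, name, alt, res, chain, seq, x, y, z, occ=1.0, elem="C"):
    return (f"ATOM  {serial:>5} {name:<4}{alt}{res:>3} {chain}{seq:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{10.0:6.2f}          {elem:>2}")


class TestReadStructure:
    def test_roundtrip_of_synthetic_trace(self, tmp_path):
        trace = gen_structure(12, "helix")
        path = tmp_path / "t.pdb"
        write_pdb(trace, path)
        model = read_structure(path, "A")
        assert model.positions == trace.positions
        assert np.abs(model.coords - trace.coords).max() < 1e-3

    def test_missing_chain_raises(self, tmp_path):
        path = tmp_path / "t.pdb"
        write_pdb(gen_structure(5, "helix"), path)
        with pytest.raises(ChainNotFoundError):
            read_structure(path, "Z")

    def test_highest_occupancy_altloc_wins(self, tmp_path):
        lines = [
            pdb_line(1, "CA", "A", "ALA", "A", 1, 0.0, 0.0, 0.0, occ=0.40),
            pdb_line(2, "CA", "B", "ALA", "A", 1, 5.0, 0.0, 0.0, occ=0.60),
            pdb_line(3, "CA", " ", "ALA", "A", 2, 3.8, 0.0, 0.0),
            "END",
        ]
        path = tmp_path / "alt.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path, "A")
        assert model.coords[0].tolist() == [5.0, 0.0, 0.0]

    def test_sidechain_centroid_with_glycine_fallback(self, tmp_path):
        lines = [
            pdb_line(1, "CA", " ", "SER", "A", 1, 0.0, 0.0, 0.0),
            pdb_line(2, "CB", " ", "SER", "A", 1, 2.0, 0.0, 0.0),
            pdb_line(3, "OG", " ", "SER", "A", 1, 4.0, 0.0, 0.0, elem="O"),
            pdb_line(4, "CA", " ", "GLY", "A", 2, 3.8, 0.0, 0.0),
            "END",
        ]
        path = tmp_path / "sc.pdb"
        path.write_text("\n".join(lines) + "\n")
        model = read_structure(path, "A", atom_convention="sidechain_centroid")
        assert model.coords[0].tolist() == [3.0, 0.0, 0.0]  # mean of CB, OG
        assert model.coords[1].tolist() == [3.8, 0.0, 0.0]  # Gly falls back to CA


class TestMapPositions:
    structure = toy_structure([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0]], (10, 11, 12))

    def test_inside_and_outside_model_range(self):
        mapped, unmapped = map_positions(
            [make_somatic(pos=10), make_somatic(pos=99)], self.structure)
        assert [v.position for v, _ in mapped] == [10]
        assert [v.position for v in unmapped] == [99]

    def test_identity_vs_explicit_mapping_table(self):
        explicit = StructureModel("toy", self.structure.positions,
                                  self.structure.coords,
                                  mapping={10: 10, 11: 11, 12: 12})
        vs = [make_somatic(pos=p) for p in (10, 11, 12, 13)]
        m1, u1 = map_positions(vs, self.structure)
        m2, u2 = map_positions(vs, explicit)
        assert [(v.position, tuple(c)) for v, c in m1] == [
            (v.position, tuple(c)) for v, c in m2]
        assert [v.position for v in u1] == [v.position for v in u2] == [13]


class TestDiameter:
    def test_single_position_zero(self):
        assert diameter([1], toy_structure([[1, 2, 3]])) == 0.0

    def test_three_point_hand_geometry(self):
        st = toy_structure([[0, 0, 0], [3, 4, 0], [0, 0, 5]])
        # pairwise distances 5, 5 and sqrt(9+16+25)
        assert diameter([1, 2, 3], st) == pytest.approx(math.sqrt(50))

    def test_unmapped_position_is_error(self):
        with pytest.raises(ValueError, match="not mapped"):
            diameter([9], toy_structure([[0, 0, 0]]))

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(8, 3)) * 10
        d0 = diameter(range(1, 9), toy_structure(coords))
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        moved = coords @ rot.T + np.array([5.0, -3.0, 11.0])
        assert diameter(range(1, 9), toy_structure(moved)) == pytest.approx(d0)
        shuffled = coords[rng.permutation(8)]
        assert pdist(shuffled).max() == pytest.approx(d0)


def complete_linkage_oracle(coords, cl, min_size):
    """Independent naive agglomerative oracle: repeatedly merge the pair of
    clusters with the smallest complete-linkage distance while it is <= cl."""
    coords = np.asarray(coords, float)
    D = squareform(pdist(coords))
    clusters = [[i] for i in range(len(coords))]
    while len(clusters) > 1:
        best, best_d = None, np.inf
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if d < best_d:
                best, best_d = (a, b), d
        if best_d > cl:
            break
        a, b = best
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    out = []
    for c in clusters:
        if len(c) >= min_size:
            diam = max((D[i, j] for i, j in itertools.combinations(c, 2)), default=0.0)
            out.append((tuple(sorted(c)), diam))
    return sorted(out)


class TestFindClusters:
    def test_three_tight_points_form_one_cluster(self):
        st = toy_structure([[0, 0, 0], [4, 0, 0], [0, 4, 0]])
        clusters = find_clusters(mapped_at(st, [1, 2, 3]), st)
        assert len(clusters) == 1
        assert clusters[0].members == (1, 2, 3)
        assert clusters[0].diameter == pytest.approx(math.sqrt(32))

    def test_collinear_spread_yields_no_min3_cluster(self):
        st = toy_structure([[0, 0, 0], [20, 0, 0], [40, 0, 0]])
        assert find_clusters(mapped_at(st, [1, 2, 3]), st) == []

    def test_duplicate_positions_count_once(self):
        st = toy_structure([[0, 0, 0], [4, 0, 0], [0, 4, 0]])
        mapped = mapped_at(st, [1, 1, 2])  # only two distinct positions
        assert find_clusters(mapped, st) == []

    def test_reported_diameter_never_exceeds_cl(self, rng):
        st = toy_structure(rng.normal(size=(30, 3)) * 15)
        clusters = find_clusters(mapped_at(st, range(1, 31)), st)
        assert all(c.diameter <= 30.0 for c in clusters)

    def test_matches_naive_agglomerative_oracle(self, rng):
        for _ in range(15):
            coords = rng.uniform(0, 40, size=(10, 3))
            st = toy_structure(coords)
            got = sorted((tuple(i - 1 for i in c.members), c.diameter)
                         for c in find_clusters(mapped_at(st, range(1, 11)), st))
            expected = complete_linkage_oracle(coords, 30.0, 3)
            assert [m for m, _ in got] == [m for m, _ in expected]
            assert np.allclose([d for _, d in got], [d for _, d in expected])


def line_plus_tight_triple(n_far=60):
    """Residues spread far apart on a line, plus one tight triple: the only
    possible >=3-member cluster is the planted one."""
    far = np.column_stack([np.arange(n_far) * 40.0, np.zeros(n_far), np.zeros(n_far)])
    triple = np.array([[0, 100, 0], [6, 100, 0], [3, 105, 0]], float)
    return toy_structure(np.vstack([far, triple]))


class TestBootstrapPvalue:
    def test_floor_when_null_never_ties(self):
        # with 4 substitutions on 203 residues, the chance that a null draw
        # contains the whole planted triple is ~3e-6, so b = 0 and the
        # p-value sits at its (b+1)/(n+1) floor
        st = line_plus_tight_triple(n_far=200)
        n = st.n_residues
        clusters = find_clusters(mapped_at(st, [n - 2, n - 1, n]), st)
        params = ClusterParams(n_boot=999, seed=7)
        p = bootstrap_pvalue(clusters[0], 4, st, params)
        assert p == pytest.approx(1 / 1000)

    def test_p_is_one_when_null_always_ties(self):
        st = toy_structure([[0, 0, 0], [10, 0, 0], [0, 10, 0]])
        params = ClusterParams(cl_diameter=30, min_size=2, n_boot=50, seed=3)
        clusters = find_clusters(mapped_at(st, [1, 2, 3]), st, params)
        (c,) = clusters
        # the observed cluster spans the whole structure, so every placement
        # of 3 variants on 3 residues reproduces it exactly
        assert bootstrap_pvalue(c, 3, st, params) == 1.0

    def test_matches_exhaustive_placement_oracle(self, rng):
        coords = rng.uniform(0, 25, size=(5, 3))
        st = toy_structure(coords)
        params = ClusterParams(cl_diameter=30, min_size=3, n_boot=4000, seed=11)
        clusters = find_clusters(mapped_at(st, [1, 3, 5]), st, params)
        if not clusters:
            pytest.skip("degenerate draw: observed positions formed no cluster")
        c = clusters[0]
        # exact null: enumerate all C(5,3) placements of the 3 substitutions
        qualifying = 0
        subsets = list(itertools.combinations(range(5), 3))
        for sub in subsets:
            null = complete_linkage_oracle(coords[list(sub)], 30, 3)
            best = min((d for m, d in null if len(m) >= 3), default=np.inf)
            qualifying += best <= c.diameter + 1e-12
        exact = qualifying / len(subsets)
        p = bootstrap_pvalue(c, 3, st, params)
        b_rate = p * (params.n_boot + 1) / params.n_boot - 1 / params.n_boot
        mc_sd = math.sqrt(exact * (1 - exact) / params.n_boot) + 1e-9
        assert abs(b_rate - exact) < 4 * mc_sd + 1e-6

    def test_undersized_total_is_contract_violation(self):
        st = line_plus_tight_triple()
        c = Cluster3D(members=(1, 2, 3), diameter=5.0)
        with pytest.raises(ValueError, match=">= cluster size"):
            bootstrap_pvalue(c, 2, st)


class TestAnalyzeStructure:
    def test_end_to_end_attaches_pvalues_and_reports_unmapped(self):
        st = line_plus_tight_triple(n_far=30)
        n = st.n_residues
        variants = [make_somatic(pos=p) for p in (n - 2, n - 1, n, 5, 12, 999)]
        params = ClusterParams(n_boot=300, seed=1)
        clusters, unmapped = analyze_structure(variants, st, params)
        assert [v.position for v in unmapped] == [999]
        assert len(clusters) == 1
        c = clusters[0]
        assert c.n_boot == 300 and 0 < c.p_value <= 1
        assert c.p_value <= 5 / 301  # planted triple is essentially unbeatable
        assert c.p_adjusted is not None and c.p_adjusted <= 0.05
        assert set(c.core_members) <= set(c.members)
        assert c.core_diameter <= c.diameter + 1e-9
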