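"""Synthetic-data generators: determinism, geometric invariants, calibrated
feature enrichment, and round-trips through the readers."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chisquare

from varloc3d.cluster3d import diameter, read_structure
from varloc3d.curation import read_variants
from varloc3d.features import read_features, write_features
from varloc3d.simulate import (PlantedCluster, SimConfig, gen_cohorts,
                               gen_network, gen_proteins, gen_structure,
                               gen_variants, plant_cluster, write_cohort_matrix,
                               write_pdb, write_variants)
from varloc3d.uemd import read_cohort_matrix, uemd_scores


class TestGenProteins:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_proteins=20, seed=9)
        p1, t1 = gen_proteins(cfg)
        p2, t2 = gen_proteins(cfg)
        assert p1 == p2
        assert all(t1[g] == t2[g] for g in p1)

    def test_lengths_within_observed_range(self):
        proteins, _ = gen_proteins(SimConfig(n_proteins=300, seed=1))
        lengths = [p.length for p in proteins.values()]
        assert min(lengths) >= 44 and max(lengths) <= 7968

    def test_zero_coverage_means_empty_tracks(self):
        cfg = SimConfig(n_proteins=5, domain_coverage=0.0, idr_coverage=0.0,
                        interface_coverage=0.0, seed=2)
        _, tracks = gen_proteins(cfg)
        assert all(len(ts) == 0 for ts in tracks.values())

    def test_realized_domain_coverage_matches_target(self):
        cfg = SimConfig(n_proteins=1000, domain_coverage=0.25, seed=3)
        proteins, tracks = gen_proteins(cfg)
        covs = []
        for g, p in proteins.items():
            covered = sum(t.n_residues for t in tracks[g] if t.kind == "pfam_domain")
            covs.append(covered / p.length)
        assert abs(np.mean(covs) - 0.25) < 0.02

    def test_ddr_fraction(self):
        proteins, _ = gen_proteins(SimConfig(n_proteins=100, ddr_fraction=0.2, seed=4))
        assert sum(p.is_ddr for p in proteins.values()) == 20


class TestGenStructure:
    def test_helix_bond_lengths_exact(self):
        trace = gen_structure(10, "helix")
        bonds = np.linalg.norm(np.diff(trace.coords, axis=0), axis=1)
        assert np.abs(bonds - 3.8).max() < 1e-6

    def test_saw_nonbonded_exclusion(self):
        trace = gen_structure(300, "saw", rng=7)
        D = squareform(pdist(trace.coords))
        n = trace.n_residues
        nonbonded = [D[i, j] for i in range(n) for j in range(i + 2, n)]
        assert min(nonbonded) >= 4.0
        bonds = np.diag(D, k=1)
        assert np.abs(bonds - 3.8).max() < 1e-6

    def test_pdb_roundtrip(self, tmp_path):
        trace = gen_structure(50, "saw", rng=11)
        path = tmp_path / "trace.pdb"
        write_pdb(trace, path)
        back = read_structure(path, "A")
        assert back.positions == trace.positions
        assert np.abs(back.coords - trace.coords).max() < 1e-3

    def test_deterministic_given_seed(self):
        a = gen_structure(60, "saw", rng=5)
        b = gen_structure(60, "saw", rng=5)
        assert np.array_equal(a.coords, b.coords)


class TestGenVariants:
    def test_null_thetas_give_uniform_positions(self):
        cfg = SimConfig(n_proteins=1, domain_coverage=0.25, idr_coverage=0.0,
                        interface_coverage=0.0,
                        class_counts={"pathogenic": 10_000},
                        theta_domain=1.0, seed=6)
        proteins, tracks = gen_proteins(cfg)
        variants, _ = gen_variants(cfg, proteins, tracks)
        (gene,) = proteins
        L = proteins[gene].length
        positions = np.array([v.position for v in variants])
        k = 10
        edges = np.linspace(1, L + 1, k + 1)
        counts, _ = np.histogram(positions, bins=edges)
        _, p = chisquare(counts)
        assert p > 0.01

    def test_domain_enrichment_matches_mixture_closed_form(self):
        cfg = SimConfig(n_proteins=1, domain_coverage=0.25, idr_coverage=0.0,
                        interface_coverage=0.0,
                        class_counts={"pathogenic": 10_000},
                        theta_domain=3.0, seed=8)
        proteins, tracks = gen_proteins(cfg)
        variants, _ = gen_variants(cfg, proteins, tracks)
        (gene,) = proteins
        in_domain = np.zeros(proteins[gene].length + 1, bool)
        for t in tracks[gene]:
            if t.kind == "pfam_domain":
                for s, e in t.intervals:
                    in_domain[s:e + 1] = True
        frac = np.mean([in_domain[v.position] for v in variants])
        expected = 3 * 0.25 / (3 * 0.25 + 0.75)
        assert abs(frac - expected) < 0.02

    def test_planted_cluster_diameter_bound(self):
        structure = gen_structure(300, "saw", rng=13)
        cfg = SimConfig(n_proteins=1, class_counts={"primary": 6},
                        planted_clusters=(PlantedCluster("G0000", 4, 12.0),),
                        seed=13)
        proteins, tracks = gen_proteins(cfg)
        variants, truth = gen_variants(cfg, proteins, tracks,
                                       structures={"G0000": structure})
        planted = truth[truth["planted_cluster"] == "cluster0"]
        assert len(planted) == 4
        assert diameter(planted["position"].tolist(), structure) <= 12.0

    def test_plant_cluster_infeasible_raises(self):
        # an extended helix has no 12 A ball containing 200 residues
        structure = gen_structure(250, "helix")
        with pytest.raises(ValueError, match="no ball"):
            plant_cluster(structure, 200, 12.0, np.random.default_rng(0))

    def test_ground_truth_is_sidecar_only(self, tmp_path):
        cfg = SimConfig(n_proteins=3, class_counts={"vus": 20}, seed=14)
        proteins, tracks = gen_proteins(cfg)
        variants, truth = gen_variants(cfg, proteins, tracks)
        path = tmp_path / "v.tsv"
        write_variants(variants, path)
        header = path.read_text().splitlines()[0]
        assert "planted" not in header and "truth" not in header
        assert set(truth.columns) == {"gene", "position", "class", "planted_cluster"}


class TestGenCohorts:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_genes=30, n_tumor=20, n_background=20, seed=15)
        t1, b1 = gen_cohorts(cfg)
        t2, b2 = gen_cohorts(cfg)
        assert t1.counts.equals(t2.counts) and b1.counts.equals(b2.counts)

    def test_equal_rates_give_near_zero_scores(self):
        cfg = SimConfig(n_genes=100, n_tumor=200, n_background=200, seed=16)
        tumor, background = gen_cohorts(cfg)
        scores = uemd_scores(tumor, background)
        assert scores.median() < 0.05

    def test_driver_rate_multiplier_raises_driver_score(self):
        cfg = SimConfig(n_genes=100, n_tumor=200, n_background=200,
                        driver_genes=("G0000",), driver_multiplier=5.0, seed=17)
        tumor, background = gen_cohorts(cfg)
        scores = uemd_scores(tumor, background)
        assert scores["G0000"] > np.percentile(scores.drop("G0000"), 95)


class TestRoundTrips:
    def test_generated_files_parse_with_zero_rejects(self, tmp_path):
        cfg = SimConfig(n_proteins=10, class_counts={"pathogenic": 50, "primary": 30},
                        seed=18)
        proteins, tracks = gen_proteins(cfg)
        variants, _ = gen_variants(cfg, proteins, tracks)
        vpath = tmp_path / "v.tsv"
        write_variants(variants, vpath)
        res = read_variants(vpath, "generic")
        assert len(res.variants) == len(variants) and not res.rejected

        fpath = tmp_path / "f.tsv"
        write_features([t for ts in tracks.values() for t in ts], fpath)
        assert sum(len(t.intervals) for t in read_features(fpath)) == \
            sum(len(t.intervals) for ts in tracks.values() for t in ts)

        tumor, background = gen_cohorts(cfg)
        cpath = tmp_path / "t.tsv"
        write_cohort_matrix(tumor, cpath)
        back = read_cohort_matrix(cpath, "t", "tumor")
        assert back.counts.equals(tumor.counts)

    def test_network_edges_reference_generated_proteins(self):
        cfg = SimConfig(n_proteins=40, seed=19)
        proteins, _ = gen_proteins(cfg)
        edges = gen_network(cfg, proteins)
        genes = set(proteins)
        assert edges and all(a in genes and b in genes for a, b in edges)
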