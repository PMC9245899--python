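import numpy as np
import pytest

from insulome.core_io import MISSING, GenotypeMatrix, InsulomeError, Segment
from insulome.ibd_geography import (
    IbdMatrix,
    IbdParams,
    detect_ibd,
    filter_relatives,
    group_summary,
    ibd_pca,
    kinship,
    lod_table,
    ne_eligibility,
    pairwise_ibd_matrix,
    site_lod,
)
from insulome.synthetic_data import Haplotype, diploid_genotypes, meiosis
from oracles import enumerate_site_lod


class TestSiteLod:
    def test_matches_enumeration_oracle_everywhere(self):
        """Exhaustive check over genotype pairs and a frequency grid."""
        for eps in (0.001, 0.005, 0.02):
            for p in np.linspace(0.05, 0.95, 13):
                for g1 in (0, 1, 2):
                    for g2 in (0, 1, 2):
                        got = site_lod(g1, g2, float(p), eps)
                        want = enumerate_site_lod(g1, g2, float(p), eps)
                        assert got == pytest.approx(want, abs=1e-12)

    def test_shared_rare_homozygote_supports_ibd(self):
        assert site_lod(2, 2, 0.05, 0.005) > 0

    def test_opposite_homozygotes_oppose_ibd(self):
        assert site_lod(0, 2, 0.5, 0.005) < 0

    def test_missing_genotype_contributes_zero(self):
        assert site_lod(MISSING, 2, 0.5, 0.005) == 0.0

    def test_boundary_frequency_fatal(self):
        with pytest.raises(InsulomeError):
            site_lod(0, 0, 0.0, 0.005)
        with pytest.raises(InsulomeError):
            lod_table(np.array([0.5, 1.0]), 0.005)


def _sib_pair(panel, gmap, rng, founder_base=0):
    f = [Haplotype.founder(gmap, founder_base + i) for i in range(4)]
    parents = [(f[0], f[1]), (f[2], f[3])]
    mk = lambda: (meiosis(parents[0], gmap, rng)[0], meiosis(parents[1], gmap, rng)[0])
    return mk(), mk()


class TestDetectIbd:
    def test_duplicated_individual_tiles_the_genome(self, small_gmap, small_panel):
        rng = np.random.default_rng(3)
        sib1, _ = _sib_pair(small_panel, small_gmap, rng)
        gm = diploid_genotypes({"a": sib1, "b": sib1}, small_panel, small_gmap)
        segs = detect_ibd(gm, "a", "b", IbdParams())
        by_chrom = {}
        for s in segs:
            by_chrom[s.chrom] = by_chrom.get(s.chrom, 0.0) + s.length_cm
        for chrom in small_gmap.chromosomes:
            assert by_chrom.get(chrom, 0.0) >= 0.99 * small_gmap.length_cm(chrom)

    def test_identical_ids_fatal(self, small_gmap, small_panel):
        rng = np.random.default_rng(4)
        sib1, sib2 = _sib_pair(small_panel, small_gmap, rng)
        gm = diploid_genotypes({"a": sib1, "b": sib2}, small_panel, small_gmap)
        with pytest.raises(InsulomeError):
            detect_ibd(gm, "a", "a", IbdParams())

    def test_no_segment_shorter_than_min_length(self, small_gmap, small_panel):
        rng = np.random.default_rng(5)
        params = IbdParams()
        for base in (0, 8, 16):
            sib1, sib2 = _sib_pair(small_panel, small_gmap, rng, founder_base=base)
            gm = diploid_genotypes({"a": sib1, "b": sib2}, small_panel, small_gmap)
            for s in detect_ibd(gm, "a", "b", params):
                assert s.length_cm >= params.min_length_cm
                assert s.lod >= params.lod_min

    def test_unrelated_individuals_share_little(self, small_gmap, small_panel):
        gm = diploid_genotypes(
            {
                "a": (Haplotype.founder(small_gmap, 0), Haplotype.founder(small_gmap, 1)),
                "b": (Haplotype.founder(small_gmap, 2), Haplotype.founder(small_gmap, 3)),
            },
            small_panel,
            small_gmap,
        )
        segs = detect_ibd(gm, "a", "b", IbdParams())
        assert sum(s.length_cm for s in segs) < 0.05 * small_gmap.total_length_cm


class TestKinship:
    def test_duplicate_with_hets_gives_half(self, small_gmap, small_panel):
        h = (Haplotype.founder(small_gmap, 0), Haplotype.founder(small_gmap, 1))
        gm = diploid_genotypes({"a": h, "b": h}, small_panel, small_gmap)
        assert kinship(gm, "a", "b") == pytest.approx(0.5)

    def test_parent_offspring_near_quarter(self, small_gmap, small_panel):
        rng = np.random.default_rng(6)
        phis = []
        for k in range(12):
            p = (Haplotype.founder(small_gmap, 4 * k), Haplotype.founder(small_gmap, 4 * k + 1))
            other = (
                Haplotype.founder(small_gmap, 4 * k + 2),
                Haplotype.founder(small_gmap, 4 * k + 3),
            )
            child = (meiosis(p, small_gmap, rng)[0], meiosis(other, small_gmap, rng)[0])
            gm = diploid_genotypes({"p": p, "c": child}, small_panel, small_gmap)
            phis.append(kinship(gm, "p", "c"))
        assert np.mean(phis) == pytest.approx(0.25, abs=0.02)

    def test_insufficient_overlap_returns_nan(self, small_gmap, small_panel):
        h = (Haplotype.founder(small_gmap, 0), Haplotype.founder(small_gmap, 1))
        gm = diploid_genotypes({"a": h, "b": h}, small_panel, small_gmap)
        g = gm.genotypes.copy()
        g[0, 200:] = MISSING
        g[1, :3900] = MISSING  # < 100 shared sites
        gm2 = GenotypeMatrix(ids=gm.ids, sites=gm.sites, genotypes=g)
        assert np.isnan(kinship(gm2, "a", "b"))

    def test_filter_relatives_removes_planted_duplicates(self, small_gmap, small_panel):
        rng = np.random.default_rng(7)
        pairs = {}
        for k in range(6):
            pairs[f"u{k}"] = (
                Haplotype.founder(small_gmap, 2 * k),
                Haplotype.founder(small_gmap, 2 * k + 1),
            )
        pairs["dup_of_u0"] = pairs["u0"]
        gm = diploid_genotypes(pairs, small_panel, small_gmap)
        kept, removed = filter_relatives(gm)
        assert len(removed) == 1
        removed_ids = {r[0] for r in removed}
        # one member of the duplicate pair removed, tie -> later id
        assert removed_ids == {"dup_of_u0"}
        assert "u0" in kept and len(kept) == 6


class TestIbdMatrix:
    def test_two_unrelated_individuals_give_zero_matrix(self, small_gmap, small_panel):
        gm = diploid_genotypes(
            {
                "a": (Haplotype.founder(small_gmap, 0), Haplotype.founder(small_gmap, 1)),
                "b": (Haplotype.founder(small_gmap, 2), Haplotype.founder(small_gmap, 3)),
            },
            small_panel,
            small_gmap,
        )
        matrix, segs = pairwise_ibd_matrix(gm, IbdParams(lod_min=30.0))
        assert matrix.total_cm.tolist() == [[0.0, 0.0], [0.0, 0.0]]
        assert segs == []

    def test_symmetry_enforced(self):
        with pytest.raises(InsulomeError):
            IbdMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]),
                      np.zeros((2, 2), dtype=np.int64))

    def test_single_individual_fatal(self, small_gmap, small_panel):
        gm = diploid_genotypes(
            {"a": (Haplotype.founder(small_gmap, 0), Haplotype.founder(small_gmap, 1))},
            small_panel,
            small_gmap,
        )
        with pytest.raises(InsulomeError):
            pairwise_ibd_matrix(gm, IbdParams())


class TestGroupSummary:
    def _matrix(self, ids, totals):
        n = len(ids)
        m = np.zeros((n, n))
        for (i, j), v in totals.items():
            m[i, j] = m[j, i] = v
        return IbdMatrix(ids, m, np.zeros((n, n), dtype=np.int64))

    def test_singleton_groups_excluded(self):
        m = self._matrix(["a", "b", "c"], {(0, 1): 10.0})
        gs = group_summary(m, {"a": "g1", "b": "g1", "c": "solo"})
        assert gs.labels == ["g1"]

    def test_within_group_mean_over_pairs(self):
        m = self._matrix(["a", "b", "c"], {(0, 1): 10.0, (0, 2): 20.0, (1, 2): 30.0})
        gs = group_summary(m, {"a": "g", "b": "g", "c": "g"})
        assert gs.mean_total_cm.loc["g", "g"] == pytest.approx(20.0)
        assert gs.pair_counts.loc["g", "g"] == 3

    def test_permutation_invariance(self):
        ids = ["a", "b", "c", "d"]
        totals = {(0, 1): 5.0, (2, 3): 7.0, (0, 2): 1.0, (1, 3): 2.0, (0, 3): 3.0, (1, 2): 4.0}
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        m1 = self._matrix(ids, totals)
        perm = [2, 0, 3, 1]
        m2 = IbdMatrix(
            [ids[k] for k in perm],
            m1.total_cm[np.ix_(perm, perm)],
            m1.n_segments[np.ix_(perm, perm)],
        )
        g1 = group_summary(m1, groups)
        g2 = group_summary(m2, groups)
        assert g1.mean_total_cm.equals(g2.mean_total_cm)

    def test_empty_groups_fatal(self):
        m = self._matrix(["a", "b"], {(0, 1): 1.0})
        with pytest.raises(InsulomeError):
            group_summary(m, {})


class TestPca:
    def _block_matrix(self, n_per_block=5, within=50.0):
        n = 2 * n_per_block
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j and (i < n_per_block) == (j < n_per_block):
                    m[i, j] = within
        return IbdMatrix([f"i{k}" for k in range(n)], m, np.zeros((n, n), dtype=np.int64))

    def test_pc1_separates_two_blocks(self):
        scores, _ = ibd_pca(self._block_matrix())
        pc1 = scores["PC1"].to_numpy()
        assert len(set(np.sign(pc1[:5]))) == 1
        assert len(set(np.sign(pc1[5:]))) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[5])

    def test_variance_fractions_valid(self):
        rng = np.random.default_rng(0)
        n = 8
        x = rng.uniform(0, 30, size=(n, n))
        m = np.triu(x, 1) + np.triu(x, 1).T
        matrix = IbdMatrix([f"i{k}" for k in range(n)], m, np.zeros((n, n), dtype=np.int64))
        _, var_frac = ibd_pca(matrix)
        assert np.all(var_frac >= 0) and np.all(var_frac <= 1)
        assert np.all(np.diff(var_frac) <= 1e-12)
        assert var_frac.sum() <= 1 + 1e-9

    def test_constant_matrix_fatal(self):
        m = IbdMatrix(["a", "b", "c"], np.zeros((3, 3)), np.zeros((3, 3), dtype=np.int64))
        with pytest.raises(InsulomeError):
            ibd_pca(m)


class TestNeEligibility:
    def _segs(self, n, length_cm=3.0):
        return [
            Segment("IBD", ("a", "b"), "1", 1, 2, 0.0, length_cm, 10, lod=4.0)
            for _ in range(n)
        ]

    def test_boundary_at_90_segments(self):
        flags = ne_eligibility({"g89": self._segs(89), "g90": self._segs(90)})
        assert flags == {"g89": False, "g90": True}

    def test_short_segments_never_counted(self):
        flags = ne_eligibility({"g": self._segs(200, length_cm=1.9)})
        assert flags == {"g": False}
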