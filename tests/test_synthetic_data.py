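import numpy as np
import pytest
from scipy import stats

from insulome.core_io import MISSING, GeneticMap, InsulomeError
from insulome.synthetic_data import (
    AncestryTruth,
    Haplotype,
    NeTrajectory,
    add_errors,
    diploid_genotypes,
    haplotype_alleles,
    make_founders,
    meiosis,
    simulate_population,
    true_f_roh,
    true_segments,
)


class TestMakeFounders:
    def test_determinism_under_seed(self, small_gmap):
        a = make_founders(10, 200, small_gmap, seed=5)
        b = make_founders(10, 200, small_gmap, seed=5)
        np.testing.assert_array_equal(a.alleles, b.alleles)
        assert a.sites.equals(b.sites)

    def test_odd_or_tiny_haplotype_count_rejected(self, small_gmap):
        with pytest.raises(InsulomeError):
            make_founders(3, 100, small_gmap)
        with pytest.raises(InsulomeError):
            make_founders(2, 100, small_gmap)

    def test_invalid_beta_params_fatal(self, small_gmap):
        with pytest.raises(InsulomeError):
            make_founders(10, 100, small_gmap, freq_beta_params=(0.0, 1.0))

    def test_flat_beta_frequencies_uniform_on_truncated_range(self, small_gmap):
        panel = make_founders(4, 5000, small_gmap, freq_beta_params=(1, 1), seed=2)
        p = panel.sites["p"].to_numpy()
        assert p.min() >= 0.05 and p.max() <= 0.95
        counts, _ = np.histogram(p, bins=np.linspace(0.05, 0.95, 10))
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        # 9 dof; p ~ 0.001 cutoff
        assert chi2 < stats.chi2.ppf(0.999, df=9)

    def test_empirical_allele_frequency_tracks_site_p(self, small_gmap):
        panel = make_founders(400, 500, small_gmap, seed=3)
        emp = panel.alleles.mean(axis=0)
        resid = emp - panel.sites["p"].to_numpy()
        assert np.abs(resid).mean() < 0.02


class TestMeiosis:
    def test_zero_length_chromosome_copies_one_parent(self):
        gmap = GeneticMap({"c": (np.array([1, 2]), np.array([0.0, 0.0]))})
        a, b = Haplotype.founder(gmap, 0), Haplotype.founder(gmap, 1)
        gamete, xs = meiosis((a, b), gmap, seed=1)
        assert len(xs["c"]) == 0
        assert gamete.equals(a) or gamete.equals(b)

    def test_crossover_count_is_poisson_in_map_length(self):
        gmap = GeneticMap.uniform({"c": 100.0})
        a, b = Haplotype.founder(gmap, 0), Haplotype.founder(gmap, 1)
        rng = np.random.default_rng(0)
        n = 10_000
        counts = np.array([len(meiosis((a, b), gmap, rng)[1]["c"]) for _ in range(n)])
        se = counts.std() / np.sqrt(n)
        assert abs(counts.mean() - 1.0) < 3 * se
        # Poisson: variance approximately equals the mean
        assert abs(counts.var() - counts.mean()) < 0.1

    def test_identical_parents_give_identical_gamete(self, small_gmap, small_panel):
        a = Haplotype.founder(small_gmap, 3)
        gamete, _ = meiosis((a, a), small_gmap, seed=7)
        np.testing.assert_array_equal(
            haplotype_alleles(gamete, small_panel, small_gmap),
            haplotype_alleles(a, small_panel, small_gmap),
        )

    def test_mismatched_chromosome_sets_fatal(self, small_gmap):
        a = Haplotype.founder(small_gmap, 0)
        other = GeneticMap.uniform({"weird": 50.0})
        b = Haplotype.founder(other, 1)
        with pytest.raises(InsulomeError):
            meiosis((a, b), small_gmap, seed=0)

    def test_gamete_mosaic_tiles_chromosomes(self, small_gmap):
        rng = np.random.default_rng(4)
        hap = Haplotype.founder(small_gmap, 0)
        other = Haplotype.founder(small_gmap, 1)
        for _ in range(50):
            hap2, _ = meiosis((hap, other), small_gmap, rng)
            hap = hap2
        truth = AncestryTruth({"x": (hap, other)}, small_gmap)
        truth.check_tiling()


class TestTrueSegments:
    def test_full_founder_identity_spans_chromosomes(self, small_gmap):
        h = Haplotype.founder(small_gmap, 5)
        truth = AncestryTruth({"x": (h, h)}, small_gmap)
        segs = true_segments(truth, "x", "x")
        assert len(segs) == 2  # one per chromosome
        assert sum(s.length_cm for s in segs) == pytest.approx(270.0)
        assert true_f_roh(truth, "x") == pytest.approx(1.0)

    def test_unrelated_founders_share_nothing(self, small_gmap):
        truth = AncestryTruth(
            {
                "x": (Haplotype.founder(small_gmap, 0), Haplotype.founder(small_gmap, 1)),
                "y": (Haplotype.founder(small_gmap, 2), Haplotype.founder(small_gmap, 3)),
            },
            small_gmap,
        )
        assert true_segments(truth, "x", "x") == []
        assert true_segments(truth, "x", "y") == []

    def test_unknown_id_fatal(self, small_gmap):
        truth = AncestryTruth({"x": (Haplotype.founder(small_gmap, 0),) * 2}, small_gmap)
        with pytest.raises(InsulomeError):
            true_segments(truth, "x", "nobody")

    def test_pair_segments_union_all_four_haplotype_combos(self, small_gmap):
        # y shares founder 0 on one haplotype with x: IBD everywhere
        truth = AncestryTruth(
            {
                "x": (Haplotype.founder(small_gmap, 0), Haplotype.founder(small_gmap, 1)),
                "y": (Haplotype.founder(small_gmap, 2), Haplotype.founder(small_gmap, 0)),
            },
            small_gmap,
        )
        segs = true_segments(truth, "x", "y")
        assert sum(s.length_cm for s in segs) == pytest.approx(270.0)


class TestExpectedInbreeding:
    """Ground-truth F equals the genealogical expectation for known loops."""

    @pytest.mark.parametrize(
        "label,expected",
        [
            ("first_degree_sib", 1 / 4),
            ("second_degree_avuncular", 1 / 8),
            ("third_degree_first_cousins", 1 / 16),
        ],
    )
    def test_truth_f_matches_analytic_kinship(self, small_gmap, label, expected):
        from insulome.pedigree_sim import _drop_focal, scenario_pedigrees

        sc = {s.label: s for s in scenario_pedigrees()}[label]
        rng = np.random.default_rng(hash(label) % 2**31)
        panel = make_founders(16, 50, small_gmap, seed=1)
        n_reps = 150
        fs = np.empty(n_reps)
        for r in range(n_reps):
            focal = _drop_focal(sc, panel, small_gmap, rng)
            truth = AncestryTruth({"x": focal}, small_gmap)
            fs[r] = true_f_roh(truth, "x")
        se = fs.std() / np.sqrt(n_reps)
        assert abs(fs.mean() - expected) < 3 * se + 1e-9


class TestSimulatePopulation:
    def test_determinism_and_tiling(self, small_gmap):
        panel = make_founders(40, 300, small_gmap, seed=8)
        traj = NeTrajectory.constant(10, 5)
        gm1, truth1 = simulate_population(panel, traj, seed=3, gmap=small_gmap)
        gm2, _ = simulate_population(panel, traj, seed=3, gmap=small_gmap)
        np.testing.assert_array_equal(gm1.genotypes, gm2.genotypes)
        assert gm1.ids == gm2.ids
        truth1.check_tiling()

    def test_two_isolated_demes_share_no_ibd(self, small_gmap):
        panel = make_founders(64, 300, small_gmap, seed=8)
        traj = NeTrajectory.constant(8, 12, n_demes=2, migration=0.0)
        gm, truth = simulate_population(panel, traj, seed=5, gmap=small_gmap)
        deme0 = [i for i in gm.ids if gm.groups[i] == "deme0"]
        deme1 = [i for i in gm.ids if gm.groups[i] == "deme1"]
        for a in deme0[:4]:
            for b in deme1[:4]:
                assert true_segments(truth, a, b, min_cm=2.0) == []

    def test_smaller_population_accumulates_more_roh(self, small_gmap):
        panel = make_founders(700, 100, small_gmap, seed=2)
        f_means = []
        for n in (20, 300):
            traj = NeTrajectory.constant(n, 12)
            gm, truth = simulate_population(panel, traj, seed=42, gmap=small_gmap)
            fs = [true_f_roh(truth, i, min_cm=4.0) for i in gm.ids[:20]]
            f_means.append(np.mean(fs))
        assert f_means[0] > f_means[1]

    def test_insufficient_founders_fatal(self, small_gmap):
        panel = make_founders(10, 100, small_gmap, seed=1)
        with pytest.raises(InsulomeError):
            simulate_population(panel, NeTrajectory.constant(50, 3), seed=0, gmap=small_gmap)

    def test_trajectory_validation(self):
        with pytest.raises(InsulomeError):
            NeTrajectory(np.array([10, 1, 10]))
        with pytest.raises(InsulomeError):
            NeTrajectory(np.array([10, 10]), migration=1.0)


class TestAddErrors:
    def test_zero_rates_are_identity(self, small_gmap):
        panel = make_founders(20, 300, small_gmap, seed=1)
        traj = NeTrajectory.constant(5, 2)
        gm, _ = simulate_population(panel, traj, seed=1, gmap=small_gmap)
        out = add_errors(gm, 0.0, 0.0, seed=1)
        np.testing.assert_array_equal(out.genotypes, gm.genotypes)

    def test_miscall_rate_matches_binomial_expectation(self, small_gmap):
        panel = make_founders(64, 2000, small_gmap, seed=3)
        traj = NeTrajectory.constant(30, 2)
        gm, _ = simulate_population(panel, traj, seed=2, gmap=small_gmap)
        rate = 0.005
        out = add_errors(gm, rate, 0.0, seed=9, recompute_freq=False)
        # count changed alleles: |delta| in genotype space equals flipped alleles
        # except het<->het double flips, which are O(rate^2) and ignored
        delta = np.abs(out.genotypes.astype(int) - gm.genotypes)
        n_alleles = 2 * gm.genotypes.size
        frac = delta.sum() / n_alleles
        se = np.sqrt(rate * (1 - rate) / n_alleles)
        assert abs(frac - rate) < 3 * se + 2 * rate**2

    def test_full_dropout_then_site_filter_is_fatal(self, small_gmap):
        from insulome.core_io import SiteFilterConfig, filter_sites

        panel = make_founders(10, 100, small_gmap, seed=4)
        traj = NeTrajectory.constant(4, 1)
        gm, _ = simulate_population(panel, traj, seed=3, gmap=small_gmap)
        out = add_errors(gm, 0.0, 1.0, seed=0, recompute_freq=False)
        assert np.all(out.genotypes == MISSING)
        with pytest.raises(InsulomeError):
            filter_sites(out, SiteFilterConfig())

    def test_out_of_range_rates_fatal(self, small_gmap):
        panel = make_founders(6, 50, small_gmap, seed=5)
        gm = diploid_genotypes(
            {"a": (Haplotype.founder(small_gmap, 0), Haplotype.founder(small_gmap, 1))},
            panel,
            small_gmap,
        )
        with pytest.raises(InsulomeError):
            add_errors(gm, 0.2, 0.0)
        with pytest.raises(InsulomeError):
            add_errors(gm, 0.0, -0.1)
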