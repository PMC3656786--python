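import numpy as np
import pytest

import ssrpopkit as sk
from ssrpopkit import selection as sel
from ssrpopkit.genotypes import GenotypeMatrix, LinkageMap
from ssrpopkit.simulate import engineer_sweeps, two_group_scan_config


@pytest.fixture(scope="module")
def scan_dataset():
    cfg = two_group_scan_config(3, n_loci=60)
    gm, lmap, grouping, truth = sk.simulate(cfg)
    ga = [i for i, g in grouping.items() if int(g[4:]) <= 4]
    gb = [i for i, g in grouping.items() if int(g[4:]) > 4]
    return gm, lmap, ga, gb


class TestBalancedSubset:
    def test_full_pool_returned(self, scan_dataset):
        gm, _, ga, _ = scan_dataset
        out = sel.select_balanced_subset(gm, ga, len(ga), seed=1)
        assert sorted(out) == sorted(ga)

    def test_identical_genotypes_any_subset(self):
        calls = np.tile(np.array([[100, 102]], dtype=np.int32), (6, 4, 1)).reshape(6, 4, 2)
        gm = GenotypeMatrix([f"i{k}" for k in range(6)], [f"L{j}" for j in range(4)], calls)
        out = sel.select_balanced_subset(gm, gm.individuals, 3, n_candidate_sets=10, seed=0)
        assert len(out) == 3

    def test_returned_subset_minimizes_distance_to_mean(self, scan_dataset):
        gm, _, _, gb = scan_dataset
        rng = np.random.default_rng(7)
        out = sel.select_balanced_subset(gm, gb, 12, n_candidate_sets=20, seed=7)
        # re-enumerate the same candidate stream
        counts = []
        cands = []
        for _ in range(20):
            pick = list(rng.choice(gb, size=12, replace=False))
            cands.append(pick)
            counts.append(sel.total_allele_count(gm, pick))
        mean = np.mean(counts)
        best = int(np.argmin([abs(c - mean) for c in counts]))
        assert out == cands[best]

    def test_oversized_request_raises(self, scan_dataset):
        gm, _, ga, _ = scan_dataset
        with pytest.raises(ValueError):
            sel.select_balanced_subset(gm, ga, len(ga) + 1)


class TestEwensWatterson:
    def test_all_singletons_boundary(self):
        # k = n: the conditional null is a point mass at the minimum F
        counts = {a: 1 for a in range(10)}
        res = sel.ew_test(counts, n_sim=200, seed=0)
        assert res.f_obs == pytest.approx(0.1)
        assert res.p >= 0.95
        assert not res.significant

    def test_near_fixed_boundary_is_conditional_maximum(self):
        n = 20
        counts = {1: n - 1, 2: 1}
        res = sel.ew_test(counts, n_sim=300, seed=1)
        from ssrpopkit.selection import _ewens_f_null

        null = _ewens_f_null(n, 2, 300, np.random.default_rng(1))
        assert res.f_obs >= null.max() - 1e-12

    def test_monomorphic_inapplicable(self):
        res = sel.ew_test({1: 30})
        assert not res.applicable and not res.significant

    def test_null_flag_rate_at_most_nominal(self):
        """Ewens-distributed neutral configurations are rarely flagged."""
        rng = np.random.default_rng(5)

        def urn(n, theta):
            labels = [0]
            nl = 1
            for i in range(1, n):
                if rng.random() < theta / (theta + i):
                    labels.append(nl)
                    nl += 1
                else:
                    labels.append(labels[rng.integers(0, i)])
            c = np.bincount(labels)
            return {j: int(x) for j, x in enumerate(c) if x > 0}

        flags = 0
        tot = 0
        cache = {}
        for _ in range(150):
            counts = urn(40, 1.5)
            if len(counts) < 2:
                continue
            nk = (40, len(counts))
            if nk not in cache:
                cache[nk] = sel._ewens_f_null(40, len(counts), 400, np.random.default_rng(sum(nk)))
            res = sel.ew_test(counts, f_null=cache[nk])
            tot += 1
            flags += res.significant
        assert flags / tot <= 0.05


class TestLnRH:
    def test_degenerate_zero_variance_raises(self):
        # He_A = He_B at every locus -> all raw lnRH = 0 -> sd = 0
        he = np.linspace(0.1, 0.8, 12)
        with pytest.raises(ValueError, match="zero variance"):
            sel.lnrh_test(he, he.copy())

    def test_too_few_loci_raises(self):
        with pytest.raises(ValueError, match=">= 10"):
            sel.lnrh_test(np.array([0.5, 0.4]), np.array([0.3, 0.2]))

    def test_fixed_locus_excluded(self):
        rng = np.random.default_rng(0)
        he_a = rng.uniform(0.2, 0.8, 15)
        he_b = rng.uniform(0.2, 0.8, 15)
        he_a[3] = 0.0  # monomorphic in group A
        z, flags = sel.lnrh_test(he_a, he_b)
        assert np.isnan(z[3]) and not flags[3]

    def test_one_sided_mode(self):
        rng = np.random.default_rng(1)
        he_a = rng.uniform(0.2, 0.8, 30)
        he_b = rng.uniform(0.2, 0.8, 30)
        z, two = sel.lnrh_test(he_a, he_b, two_sided=True)
        _, one = sel.lnrh_test(he_a, he_b, two_sided=False)
        assert one.sum() <= two.sum()


class TestIslandScans:
    def test_fst_recentering_converges(self, scan_dataset):
        gm, _, ga, gb = scan_dataset
        fd = sel.fdist_scan(gm, ga, gb, n_sim=2000, seed=4)
        assert abs(fd.achieved_fst - fd.target_fst) <= 0.01

    def test_zero_fst_locus_never_flagged(self, scan_dataset):
        gm, _, ga, gb = scan_dataset
        # plant a locus with identical fixed genotype everywhere
        gm2 = GenotypeMatrix(list(gm.individuals), list(gm.loci), gm.calls.copy(), gm.populations)
        gm2.calls[:, 0, :] = 100
        fd = sel.fdist_scan(gm2, ga, gb, n_sim=2000, seed=5)
        assert not fd.flags[0]

    def test_planted_sweep_has_top_quantile(self, scan_dataset):
        gm, _, ga, gb = scan_dataset
        planted = engineer_sweeps(gm, ga, [gm.loci[7]], seed=42)
        fd = sel.fdist_scan(planted, ga, gb, n_sim=3000, seed=6)
        assert fd.quantile[7] == np.nanmax(fd.quantile)
        assert fd.flags[7]

    def test_hierarchy_reduces_to_plain_island(self, scan_dataset):
        """With ratio 1 the hierarchical model is a plain island model."""
        gm, _, ga, gb = scan_dataset
        hi = sel.hierarchical_scan(gm, ga, gb, k_within=50, n_sim=2000, seed=7,
                                   within_between_ratio=1.0)
        fd = sel.fdist_scan(gm, ga, gb, n_sim=2000, demes=100, seed=7)
        ok = ~np.isnan(hi.quantile) & ~np.isnan(fd.quantile)
        # same machinery, same seeds: quantiles agree within Monte-Carlo error
        assert np.nanmean(np.abs(hi.quantile[ok] - fd.quantile[ok])) < 0.12


class TestConsensus:
    @pytest.mark.parametrize(
        "flags,expected",
        [((True, True, False, False), True),
         ((True, False, False, False), False),
         ((False, False, False, False), False),
         ((True, True, True, True), True)],
    )
    def test_two_of_four_rule(self, flags, expected):
        out = sel.consensus_outliers(np.array([flags]))
        assert bool(out[0]) is expected

    def test_pure_function_of_flags(self):
        rng = np.random.default_rng(0)
        flags = rng.random((50, 4)) < 0.3
        out = sel.consensus_outliers(flags)
        assert np.array_equal(out, flags.sum(axis=1) >= 2)


class TestCandidateWindow:
    def setup_method(self):
        self.lmap = LinkageMap({"out": ("LG3", 10.0), "nb": ("LG3", 11.3)})

    def test_high_ld_same_scaffold_ratio_window(self):
        scaff = {"out": ("sc1", 0.0), "nb": ("sc1", 473_200.0)}
        w = sel.candidate_window("out", "nb", 1.0, self.lmap, scaff)
        assert w.mode == "ratio"
        assert w.window_kb == pytest.approx(473.2, abs=1.0)  # ~474 kb

    def test_weak_ld_or_different_scaffold_fallback(self):
        scaff = {"out": ("sc1", 0.0), "nb": ("sc2", 50_000.0)}
        w = sel.candidate_window("out", "nb", 0.05, self.lmap, scaff)
        assert w.mode == "fallback"
        assert w.window_kb == 20.0

    def test_moderate_ld_decay_window(self):
        lmap = LinkageMap({"out": ("LG1", 0.0), "nb": ("LG1", 1.9)})
        scaff = {"out": ("sc9", 0.0), "nb": ("sc9", 338_200.0)}  # 178 kb/cM
        w = sel.candidate_window("out", "nb", 0.22, lmap, scaff, decay_span_cm=0.2)
        assert w.mode == "decay"
        assert w.window_kb == pytest.approx(35.6, abs=1.0)  # ~36 kb

    def test_zero_cm_span_falls_back_with_warning(self):
        lmap = LinkageMap({"out": ("LG1", 5.0), "nb": ("LG1", 5.0)})
        scaff = {"out": ("sc1", 0.0), "nb": ("sc1", 1000.0)}
        w = sel.candidate_window("out", "nb", 0.9, lmap, scaff)
        assert w.mode == "fallback" and w.warning

    def test_unmapped_marker_raises(self):
        with pytest.raises(KeyError):
            sel.candidate_window("out", "zz", 0.9, self.lmap, {})
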