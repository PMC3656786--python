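import numpy as np
import pytest

from ssrpopkit import popstructure as ps
from ssrpopkit.genotypes import GenotypeMatrix, LinkageMap
from ssrpopkit.phylogeny import DistanceMatrix


def two_pop_matrix(seed=0, n_per=20, n_loci=30, disjoint=True):
    """Fully homozygous matrix: two populations fixed-ish for different alleles."""
    rng = np.random.default_rng(seed)
    calls = np.zeros((2 * n_per, n_loci, 2), dtype=np.int32)
    for j in range(n_loci):
        a_alleles = [100, 102]
        b_alleles = [200, 202] if disjoint else a_alleles
        calls[:n_per, j, 0] = calls[:n_per, j, 1] = rng.choice(a_alleles, n_per)
        calls[n_per:, j, 0] = calls[n_per:, j, 1] = rng.choice(b_alleles, n_per)
    inds = [f"i{k}" for k in range(2 * n_per)]
    pops = {i: ("P" if k < n_per else "Q") for k, i in enumerate(inds)}
    return GenotypeMatrix(inds, [f"L{j}" for j in range(n_loci)], calls, pops)


class TestThinning:
    def test_duplicated_locus_one_copy_kept(self):
        rng = np.random.default_rng(2)
        col = rng.choice([100, 102, 104], size=20)
        calls = np.zeros((20, 2, 2), dtype=np.int32)
        calls[:, 0, 0] = calls[:, 0, 1] = col
        calls[:, 1, 0] = calls[:, 1, 1] = col  # exact duplicate, r2 = 1
        gm = GenotypeMatrix([f"i{k}" for k in range(20)], ["A", "B"], calls)
        lm = LinkageMap({"A": ("LG1", 1.0), "B": ("LG1", 2.0)})
        kept = ps.thin_by_ld(gm, lm)
        assert kept == ["A"]

    def test_all_low_ld_retained(self):
        rng = np.random.default_rng(4)
        n = 200
        calls = np.zeros((n, 3, 2), dtype=np.int32)
        for j in range(3):
            col = rng.choice([100, 102], size=n)
            calls[:, j, 0] = calls[:, j, 1] = col
        gm = GenotypeMatrix([f"i{k}" for k in range(n)], ["A", "B", "C"], calls)
        lm = LinkageMap({"A": ("LG1", 1.0), "B": ("LG1", 5.0), "C": ("LG1", 9.0)})
        kept = ps.thin_by_ld(gm, lm)
        assert kept == ["A", "B", "C"]

    def test_retained_pairs_below_threshold(self, flax_dataset):
        from ssrpopkit.ld import pair_r2

        gm, lmap, _, _ = flax_dataset
        kept = ps.thin_by_ld(gm, lmap, r2_max=0.4)
        by_lg = {}
        for l in kept:
            if l in lmap:
                by_lg.setdefault(lmap.linkage_group(l), []).append(l)
        for loci in by_lg.values():
            for x in range(len(loci)):
                for y in range(x + 1, len(loci)):
                    r2, _, _ = pair_r2(gm, loci[x], loci[y], n_perm=0)
                    if not np.isnan(r2):
                        assert r2 <= 0.4 + 1e-9


class TestPCoA:
    def test_points_on_a_line(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        res = ps.pcoa(DistanceMatrix(list("abcd"), d), n_axes=2)
        spacing = np.diff(np.sort(res.coordinates[:, 0]))
        assert np.allclose(sorted(spacing), sorted(np.diff(x)), atol=1e-8)
        assert res.pct_variation[1] == pytest.approx(0.0, abs=1e-6)

    def test_two_cluster_separation(self):
        gm = two_pop_matrix(seed=1)
        from ssrpopkit.phylogeny import nei_minimum_distance_matrix

        dm = nei_minimum_distance_matrix(gm)
        res = ps.pcoa(dm)
        ax1 = res.coordinates[:, 0]
        assert (ax1[:20] > 0).all() != (ax1[20:] > 0).all()  # opposite signs

    def test_planar_distances_two_axes_full_variance(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        res = ps.pcoa(DistanceMatrix([f"p{k}" for k in range(10)], d), n_axes=2)
        assert res.pct_variation.sum() == pytest.approx(100.0, abs=1e-6)
        # Euclidean-embeddable: no meaningfully negative eigenvalues
        assert res.eigenvalues.min() > -1e-8 * max(res.eigenvalues.max(), 1)

    def test_matches_scikit_bio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(8, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"p{k}" for k in range(8)]
        mine = ps.pcoa(DistanceMatrix(labels, d), n_axes=3)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d, labels))
        assert np.allclose(
            np.abs(mine.coordinates), np.abs(theirs.samples.values[:, :3]), atol=1e-6
        )


class TestAdmixture:
    def test_k1_exact_ones(self, flax_dataset):
        gm, _, _, _ = flax_dataset
        sub = gm.subset(individuals=gm.individuals[:12])
        q = ps.admixture_gibbs(sub, 1, burn_in=10, iters=50, seed=0)
        assert np.all(q.q == 1.0)
        assert np.isfinite(q.ln_prob_data)

    def test_separable_data_fully_recovered(self):
        gm = two_pop_matrix(seed=5, n_per=15, n_loci=50)
        q = ps.admixture_gibbs(gm, 2, burn_in=150, iters=400, seed=2)
        hard = q.q.argmax(axis=1)
        assert len(set(hard[:15])) == 1 and len(set(hard[15:])) == 1
        assert hard[0] != hard[-1]
        assert np.allclose(q.q.sum(axis=1), 1.0, atol=1e-6)

    def test_seed_determinism_bit_identical(self):
        gm = two_pop_matrix(seed=6, n_per=8, n_loci=12)
        q1 = ps.admixture_gibbs(gm, 2, burn_in=50, iters=100, seed=9)
        q2 = ps.admixture_gibbs(gm, 2, burn_in=50, iters=100, seed=9)
        assert np.array_equal(q1.q, q2.q)
        assert q1.ln_prob_data == q2.ln_prob_data

    def test_entropy_shrinks_with_more_loci(self):
        ents = []
        for n_loci in (10, 50, 200):
            gm = two_pop_matrix(seed=7, n_per=10, n_loci=n_loci)
            q = ps.admixture_gibbs(gm, 2, burn_in=100, iters=250, seed=1)
            p = np.clip(q.q, 1e-12, 1)
            ents.append(float((-p * np.log(p)).sum(axis=1).mean()))
        assert ents[2] < ents[0]

    def test_k_too_large_raises(self):
        gm = two_pop_matrix(n_per=2, n_loci=4)
        with pytest.raises(ValueError):
            ps.admixture_gibbs(gm, 10)


class TestEvanno:
    def test_hand_worked_example(self):
        # mean L(K) = -1000, -500, -490, -480 with replicate sd 1 at each K
        d = 1 / np.sqrt(2)
        scan = {k: [m - d, m + d] for k, m in zip(range(1, 5), (-1000.0, -500.0, -490.0, -480.0))}
        out = ps.evanno_delta_k(scan)
        dk2 = out.loc[out["K"] == 2, "delta_k"].iloc[0]
        assert dk2 == pytest.approx(490.0, rel=1e-9)

    def test_linear_lnp_gives_zero(self):
        d = 1 / np.sqrt(2)
        scan = {k: [-100.0 * k - d, -100.0 * k + d] for k in range(1, 6)}
        out = ps.evanno_delta_k(scan)
        interior = out.dropna(subset=["delta_k"])
        assert np.allclose(interior["delta_k"], 0.0, atol=1e-9)

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        scan = {k: list(rng.normal(-1000 - 50 * k, 2, size=3)) for k in range(1, 6)}
        shifted = {k: [v + 123.0 for v in vals] for k, vals in scan.items()}
        a = ps.evanno_delta_k(scan).dropna(subset=["delta_k"])["delta_k"].to_numpy()
        b = ps.evanno_delta_k(shifted).dropna(subset=["delta_k"])["delta_k"].to_numpy()
        assert np.allclose(a, b, rtol=1e-9)

    def test_true_k2_recovered(self):
        """Simulated two-cluster data: argmax delta-K lands on K = 2."""
        gm = two_pop_matrix(seed=11, n_per=12, n_loci=40)
        rng = np.random.default_rng(4)
        scan = {}
        for k in (1, 2, 3, 4):
            scan[k] = [
                ps.admixture_gibbs(gm, k, burn_in=60, iters=150, seed=int(rng.integers(0, 2**31 - 1))).ln_prob_data
                for _ in range(3)
            ]
        out = ps.evanno_delta_k(scan)
        interior = out.dropna(subset=["delta_k"])
        assert int(interior.loc[interior["delta_k"].idxmax(), "K"]) == 2


class TestAssignment:
    def test_threshold_examples(self):
        q = ps.QMatrix(["x", "y", "z"], np.array([[0.71, 0.29], [0.5, 0.5], [0.69, 0.31]]),
                       -1.0, 2, 0, 0, 0, 1.0)
        out = ps.assign_groups(q, threshold=0.70)
        assert out == {"x": "cluster1", "y": ps.ADMIXED, "z": ps.ADMIXED}

    def test_zero_threshold_assigns_everyone(self):
        q = ps.QMatrix(["x", "y"], np.array([[0.51, 0.49], [0.2, 0.8]]), -1.0, 2, 0, 0, 0, 1.0)
        out = ps.assign_groups(q, threshold=0.0)
        assert out == {"x": "cluster1", "y": "cluster2"}


class TestFst:
    def test_fixed_difference_theta_one(self):
        gm = two_pop_matrix(seed=0, n_per=10, n_loci=10)
        # make fully fixed: one allele per pop
        gm.calls[:10] = 100
        gm.calls[10:] = 200
        out = ps.pairwise_fst(gm, gm.populations, n_perm=99, seed=1)
        row = out.iloc[0]
        assert row["theta"] == pytest.approx(1.0)
        assert row["gst"] == pytest.approx(1.0)
        assert row["p"] <= 1 / 100 + 1e-9

    def test_random_split_theta_near_zero(self):
        rng = np.random.default_rng(12)
        n = 40
        calls = np.zeros((n, 25, 2), dtype=np.int32)
        for j in range(25):
            calls[:, j, :] = rng.choice([100, 102, 104], size=(n, 2))
        gm = GenotypeMatrix([f"i{k}" for k in range(n)], [f"L{j}" for j in range(25)],
                            np.sort(calls, axis=2))
        grouping = {f"i{k}": ("P" if k < 20 else "Q") for k in range(n)}
        out = ps.pairwise_fst(gm, grouping, n_perm=99, seed=2)
        assert abs(out.iloc[0]["theta"]) < 0.05
        assert out.iloc[0]["p"] > 0.05

    def test_theta_and_gst_agree_in_sign(self, flax_dataset):
        gm, _, grouping, _ = flax_dataset
        theta = ps.wc_theta(gm, grouping)
        gst = ps.nei_gst(gm, grouping)
        assert np.sign(theta) == np.sign(gst)

    def test_island_simulation_theta_near_realized(self):
        """Random-mating island model: sample theta within 3 SE of the
        generator's realized FST over 100 loci."""
        import ssrpopkit as sk

        cfg = sk.SimConfig(seed=3, n_demes=2, deme_size=100, n_loci=100,
                           n_generations=60, sample_size=50, selfing_rate=0.0,
                           migration_rate=0.006, mutation_rate=5e-4)
        gm, _, grouping, truth = sk.simulate(cfg)
        theta_per_locus = ps.wc_theta(gm, grouping, per_locus=True)
        ok = ~np.isnan(theta_per_locus)
        se = np.nanstd(theta_per_locus, ddof=1) / np.sqrt(ok.sum())
        realized = float(np.nanmean(truth.per_locus_fst_final))
        assert abs(ps.wc_theta(gm, grouping) - realized) < 3 * se + 0.01

    def test_monomorphic_pair_flagged(self):
        calls = np.full((6, 3, 2), 100, dtype=np.int32)
        gm = GenotypeMatrix([f"i{k}" for k in range(6)], ["a", "b", "c"], calls)
        grouping = {f"i{k}": ("P" if k < 3 else "Q") for k in range(6)}
        out = ps.pairwise_fst(gm, grouping, n_perm=9)
        assert np.isnan(out.iloc[0]["theta"])
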