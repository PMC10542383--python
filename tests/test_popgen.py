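import numpy as np
import pandas as pd
import pytest
from scipy import stats

import refbias as rb


def wc_theta_loop(g_a, g_b):
    """Independent per-site Weir-Cockerham (1984) theta, coded as explicit
    loops straight from the variance-component definitions."""
    out = []
    g_a, g_b = np.asarray(g_a), np.asarray(g_b)
    for j in range(g_a.shape[1]):
        pops = []
        for g in (g_a[:, j], g_b[:, j]):
            called = [x for x in g if x >= 0]
            n = len(called)
            if n == 0:
                pops = None
                break
            p = sum(called) / (2 * n)
            h = sum(1 for x in called if x == 1) / n
            pops.append((n, p, h))
        if pops is None:
            out.append(None)
            continue
        (n1, p1, h1), (n2, p2, h2) = pops
        if (p1 == 0 and p2 == 0) or (p1 == 1 and p2 == 1):
            out.append(None)
            continue
        r = 2
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        out.append(a / (a + b + c) if (a + b + c) != 0 else None)
    return out


def _gm(genotypes, pos=None):
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_samples, n_sites = genotypes.shape
    if pos is None:
        pos = np.arange(n_sites) * 100 + 50
    return rb.GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_samples)],
        chrom=np.array(["chr1"] * n_sites, dtype=object),
        pos=np.asarray(pos),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        genotypes=genotypes,
    )


def _two_pop_map(n_a, n_b):
    pops = {f"s{i}": ("A" if i < n_a else "B") for i in range(n_a + n_b)}
    return rb.PopulationMap(population=pops)


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        gm = _gm([[2, 2], [2, 2], [0, 0], [0, 0]])
        pm = _two_pop_map(2, 2)
        fst = rb.weir_cockerham_fst(gm, pm, "A", "B")
        assert fst["fst"].tolist() == [1.0, 1.0]

    def test_identical_populations_average_near_zero(self):
        rng = np.random.default_rng(40)
        n_sites = 1_000
        p = rng.uniform(0.1, 0.9, n_sites)
        g = rng.binomial(2, p, size=(40, n_sites)).astype(np.int8)
        gm = _gm(g)
        pm = _two_pop_map(20, 20)
        fst = rb.weir_cockerham_fst(gm, pm, "A", "B")
        vals = fst["fst"].dropna()
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_matches_independent_loop_implementation(self):
        rng = np.random.default_rng(41)
        g = rng.choice([-1, 0, 1, 2], p=[0.05, 0.45, 0.3, 0.2], size=(12, 50)).astype(np.int8)
        gm = _gm(g)
        pm = _two_pop_map(5, 7)
        fst = rb.weir_cockerham_fst(gm, pm, "A", "B")
        expected = wc_theta_loop(g[:5], g[5:])
        expected_kept = [
            (j, v) for j, v in enumerate(expected) if v is not None
        ]
        got = dict(zip(((fst["pos"] - 50) // 100).tolist(), fst["fst"].tolist()))
        for j, v in expected_kept:
            assert got[j] == pytest.approx(v, abs=1e-10)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(42)
        g = rng.integers(0, 3, size=(10, 30)).astype(np.int8)
        gm = _gm(g)
        pm = _two_pop_map(4, 6)
        ab = rb.weir_cockerham_fst(gm, pm, "A", "B")["fst"]
        ba = rb.weir_cockerham_fst(gm, pm, "B", "A")["fst"]
        assert np.allclose(ab, ba, equal_nan=True)

    def test_empty_population_rejected(self, toy_gm, toy_popmap):
        with pytest.raises(ValueError, match="empty"):
            rb.weir_cockerham_fst(toy_gm, toy_popmap, "A", "C")


class TestWindowedFst:
    def test_single_site_window_equals_site_value(self):
        gm = _gm([[2], [2], [0], [0]])
        pm = _two_pop_map(2, 2)
        site = rb.weir_cockerham_fst(gm, pm, "A", "B")
        win = rb.windowed_fst(site, window=1_000, step=1_000, chrom_length=1_000)
        assert len(win) == 1
        assert win.loc[0, "fst"] == site.loc[0, "fst"]

    def test_all_fixed_differences_give_one(self):
        gm = _gm([[2] * 5, [2] * 5, [0] * 5, [0] * 5])
        pm = _two_pop_map(2, 2)
        site = rb.weir_cockerham_fst(gm, pm, "A", "B")
        win = rb.windowed_fst(site, window=1_000, step=1_000, chrom_length=1_000)
        assert win.loc[0, "fst"] == 1.0

    def test_ratio_of_averages_matches_component_sums(self):
        rng = np.random.default_rng(43)
        g = rng.integers(0, 3, size=(14, 120)).astype(np.int8)
        gm = _gm(g, pos=np.sort(rng.choice(30_000, 120, replace=False)))
        pm = _two_pop_map(7, 7)
        site = rb.weir_cockerham_fst(gm, pm, "A", "B")
        win = rb.windowed_fst(site, window=10_000, step=2_000, chrom_length=30_000)
        for _, row in win.iterrows():
            sel = site[(site["pos"] >= row["start"]) & (site["pos"] < row["end"])]
            assert row["n_variants"] == len(sel)
            expected = sel["a"].sum() / (sel["a"] + sel["b"] + sel["c"]).sum()
            assert row["fst"] == pytest.approx(expected, abs=1e-12)

    def test_empty_windows_omitted_and_bad_step_rejected(self):
        gm = _gm([[2], [0]], pos=[50])
        pm = _two_pop_map(1, 1)
        site = rb.weir_cockerham_fst(gm, pm, "A", "B")
        win = rb.windowed_fst(site, window=100, step=100, chrom_length=10_000)
        assert len(win) == 1  # 99 empty windows dropped
        with pytest.raises(ValueError):
            rb.windowed_fst(site, step=0)


class TestEmpiricalP:
    def test_rank_formula(self):
        null = np.arange(999, dtype=float)
        assert rb.empirical_p(999.5, null) == pytest.approx(0.001)
        assert rb.empirical_p(float(null.min()), null) == 1.0

    def test_never_zero_and_monotone(self):
        rng = np.random.default_rng(44)
        null = rng.normal(size=500)
        obs = np.linspace(-5, 5, 100)
        p = rb.empirical_p(obs, null)
        assert (p > 0).all()
        assert (np.diff(p) <= 0).all()

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError):
            rb.empirical_p(1.0, [])

    def test_uniform_under_null(self):
        rng = np.random.default_rng(45)
        null = rng.normal(size=10_000)
        obs = rng.normal(size=10_000)
        p = rb.empirical_p(obs, null)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_cutoff_matches_alpha(self):
        rng = np.random.default_rng(46)
        null = rng.normal(size=10_000)
        cut = rb.empirical_cutoff(null, alpha=0.05)
        assert rb.empirical_p(cut, null) == pytest.approx(0.05, abs=0.01)


class TestDifferentiatedRegions:
    def test_majority_rule(self):
        regions = [("chr1", 0, 100), ("chr1", 100, 200)]
        chroms = ["chr1"] * 7
        pos = [10, 20, 30, 40, 50, 110, 120]
        p = [0.01, 0.01, 0.01, 0.2, 0.2, 0.04, 0.2]
        calls = rb.call_differentiated_regions(regions, chroms, pos, p)
        assert calls[0].passed  # 3 of 5
        assert not calls[1].passed  # 1 of 2: 0.5 is not > 0.5

    def test_region_without_snvs_flagged(self):
        calls = rb.call_differentiated_regions(
            [("chr1", 0, 10)], ["chr1"], [50], [0.01]
        )
        assert not calls[0].passed
        assert calls[0].no_snvs

    def test_matches_exhaustive_count_on_random_sets(self):
        rng = np.random.default_rng(47)
        pos = np.sort(rng.choice(100_000, 500, replace=False))
        p = rng.random(500)
        chroms = ["chr1"] * 500
        regions = []
        for _ in range(50):
            s = int(rng.integers(0, 95_000))
            regions.append(("chr1", s, s + int(rng.integers(500, 5_000))))
        calls = rb.call_differentiated_regions(regions, chroms, pos, p)
        for (chrom, s, e), call in zip(regions, calls):
            inside = [pv for pp, pv in zip(pos, p) if s <= pp < e]
            if not inside:
                assert call.no_snvs and not call.passed
            else:
                n_sig = sum(1 for pv in inside if pv < 0.05)
                assert call.passed == (n_sig / len(inside) > 0.5)
                assert call.n_snvs == len(inside)


class TestMappingBias:
    def test_exact_linear_relationship(self):
        fst = rb.simulate_fst_matrix([f"P{i}" for i in range(20)] + ["CHS", "CEU"], seed=50)
        ms = rb.simulate_mapping_stats(fst, slope=-1.0, noise_sd=0.0,
                                       cfg=rb.SimulationConfig(seed=50))
        _, r, p = rb.mapping_bias_correlation(ms, fst)
        assert abs(abs(r) - 1.0) < 1e-12
        assert r < 0

    def test_clip_metric_has_opposite_sign(self):
        fst = rb.simulate_fst_matrix([f"P{i}" for i in range(20)] + ["CHS", "CEU"], seed=51)
        ms = rb.simulate_mapping_stats(fst, slope=-1.0, noise_sd=0.0,
                                       cfg=rb.SimulationConfig(seed=51))
        _, r_map, _ = rb.mapping_bias_correlation(ms, fst, metric="uniqmap")
        _, r_clip, _ = rb.mapping_bias_correlation(ms, fst, metric="uniqclip")
        assert r_map < -0.99 and r_clip > 0.99

    def test_independent_noise_gives_no_correlation(self):
        rng = np.random.default_rng(52)
        pops = [f"P{i}" for i in range(80)] + ["CHS", "CEU"]
        fst = rb.simulate_fst_matrix(pops, seed=52)
        rows = []
        for pop in pops:
            rows.append(
                {
                    "sample": f"{pop}_0",
                    "population": pop,
                    "uniqmap_cn1": 90.0,
                    "uniqmap_chm13": 90.0 + rng.normal(),
                    "uniqclip_cn1": 5.0,
                    "uniqclip_chm13": 5.0,
                }
            )
        _, r, p = rb.mapping_bias_correlation(pd.DataFrame(rows), fst)
        assert abs(r) < 2.5 / np.sqrt(len(pops))  # within CI of zero

    def test_population_missing_from_matrix_rejected(self):
        fst = rb.simulate_fst_matrix(["CHS", "CEU"], seed=53)
        ms = pd.DataFrame(
            {
                "sample": ["x_0"],
                "population": ["x"],
                "uniqmap_cn1": [90.0],
                "uniqmap_chm13": [91.0],
                "uniqclip_cn1": [5.0],
                "uniqclip_chm13": [5.0],
            }
        )
        with pytest.raises(ValueError, match="missing"):
            rb.mapping_bias_correlation(ms, fst)


class TestFstMatrixUtilities:
    def test_pairwise_matrix_symmetric_zero_diagonal(self, null_quartet):
        _, gm, popmap, _ = null_quartet
        small = gm.subset_sites(np.arange(0, gm.n_sites, 10))
        mat = rb.pairwise_fst_matrix(small, popmap, ["BantuKenya", "Han", "Chimpanzee"])
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 0.0)
        assert mat.loc["BantuKenya", "Chimpanzee"] > mat.loc["BantuKenya", "Han"]

    def test_variant_downsampling_is_seed_deterministic(self, null_quartet):
        _, gm, _, _ = null_quartet
        a = rb.sample_variants_for_fst(gm, fraction=0.1, seed=7)
        b = rb.sample_variants_for_fst(gm, fraction=0.1, seed=7)
        c = rb.sample_variants_for_fst(gm, fraction=0.1, seed=8)
        assert np.array_equal(a.pos, b.pos)
        assert not np.array_equal(a.pos, c.pos)
        freq = a.alt_allele_frequencies()
        maf = np.minimum(freq, 1 - freq)
        assert (maf > 0.01).all()
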