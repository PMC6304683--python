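import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demesweep.panel import (
    MISSING,
    FilterConfig,
    GenotypePanel,
    composite_r2,
    filter_variants,
    hamming_distance_matrix,
    hamming_mds,
    ld_prune,
    reynolds_distance_matrix,
    wc_components,
    wc_fst,
)

from conftest import make_panel, make_popmap


class TestGenotypePanel:
    def test_position_order_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            make_panel(np.zeros((3, 2)), pos=[100, 50, 200])

    def test_dosage_must_match_haplotypes(self):
        hap = np.array([[0, 1, 1, 0], [1, 1, 0, 0]], dtype=np.int8)
        good = hap[:, 0::2] + hap[:, 1::2]
        make_panel(good, haplotypes=hap, phased=True)  # ok
        bad = good.copy()
        bad[0, 0] = 2
        with pytest.raises(ValueError, match="disagree"):
            make_panel(bad, haplotypes=hap, phased=True)

    def test_phased_requires_haplotypes(self):
        with pytest.raises(ValueError, match="requires haplotypes"):
            make_panel(np.zeros((2, 2)), phased=True)


class TestFilterVariants:
    def test_monomorphic_removed(self):
        g = np.array([[0, 0, 0, 0], [0, 1, 2, 1]], dtype=np.int8)
        out = filter_variants(make_panel(g), FilterConfig(maf_min=0.0, call_rate_min=0))
        assert out.n_variants == 1
        assert out.variants["pos"].iloc[0] == 2000

    def test_call_rate_boundary(self):
        # 89/100 called -> below a 0.90 threshold, removed
        g = np.ones((2, 100), dtype=np.int8)
        g[0, :11] = MISSING
        g[:, 99] = 2  # keep polymorphic
        out = filter_variants(make_panel(g), FilterConfig(maf_min=0.0, call_rate_min=0.9))
        assert out.n_variants == 1

    def test_planted_failures_brute_force(self):
        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, size=(10, 50)).astype(np.int8)
        g[2] = 0  # MAF 0
        g[5] = 0
        g[5, 0] = 1  # MAF 0.01, not > 0.01
        g[8, :10] = MISSING  # call rate 0.8
        panel = make_panel(g)
        cfg = FilterConfig(maf_min=0.01, call_rate_min=0.9)
        out = filter_variants(panel, cfg)
        # independent per-variant check
        expected = []
        for v in range(10):
            row = g[v]
            called = row[row != MISSING]
            p = called.sum() / (2 * len(called))
            maf = min(p, 1 - p)
            if maf > 0.01 and len(called) / 50 >= 0.9:
                expected.append(v)
        assert out.n_variants == len(expected) == 7

    def test_idempotent(self, small_panel):
        cfg = FilterConfig(maf_min=0.05, call_rate_min=0.9)
        once = filter_variants(small_panel, cfg)
        twice = filter_variants(once, cfg)
        assert once.variants.equals(twice.variants)
        assert np.array_equal(once.genotypes, twice.genotypes)

    def test_all_removed_raises(self):
        g = np.zeros((3, 4), dtype=np.int8)
        with pytest.raises(ValueError, match="no variants"):
            filter_variants(make_panel(g), FilterConfig())


class TestCompositeR2:
    def test_identical_vectors(self):
        g = np.array([[0, 1, 2, 0, 1], [0, 1, 2, 0, 1]], dtype=np.int8)
        assert composite_r2(make_panel(g), 0, 1) == pytest.approx(1.0)

    def test_hand_value(self):
        g = np.array([[0, 1, 2, 0, 1, 2], [0, 1, 2, 0, 1, 0]], dtype=np.int8)
        panel = make_panel(g)
        # independent oracle: squared Pearson correlation of the dosages
        # (cov = 0.5, var = 2/3 and 0.5^2 -> r^2 = 0.3)
        oracle = np.corrcoef(g[0], g[1])[0, 1] ** 2
        assert oracle == pytest.approx(0.30)
        assert composite_r2(panel, 0, 1) == pytest.approx(oracle)

    def test_orthogonal(self):
        g = np.array([[0, 2, 0, 2], [0, 0, 2, 2]], dtype=np.int8)
        assert composite_r2(make_panel(g), 0, 1) == pytest.approx(0.0)

    def test_zero_variance_missing(self):
        g = np.array([[1, 1, 1, 1], [0, 1, 2, 0]], dtype=np.int8)
        assert np.isnan(composite_r2(make_panel(g), 0, 1))

    def test_symmetry_and_range(self, small_panel):
        for i, j in [(0, 1), (3, 17), (5, 30)]:
            r = composite_r2(small_panel, i, j)
            assert r == composite_r2(small_panel, j, i)
            if np.isfinite(r):
                assert 0.0 <= r <= 1.0 + 1e-12

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_allele_relabel_invariant(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(2, 12)).astype(np.int8)
        panel = make_panel(g)
        flipped = make_panel((2 - g).astype(np.int8))
        a = composite_r2(panel, 0, 1)
        b = composite_r2(flipped, 0, 1)
        assert (np.isnan(a) and np.isnan(b)) or a == pytest.approx(b)


class TestLdPrune:
    def test_duplicate_removed(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(5, 20)).astype(np.int8)
        g[3] = g[1]
        out = ld_prune(make_panel(g), r2_max=0.5, window=10, step=5)
        assert out.n_variants == 4
        assert 4000 not in list(out.variants["pos"])

    def test_independent_unchanged(self):
        rng = np.random.default_rng(42)
        g = rng.integers(0, 3, size=(10, 200)).astype(np.int8)
        out = ld_prune(make_panel(g), r2_max=0.5, window=10, step=5)
        assert out.n_variants == 10

    def test_perfect_ld_pairs(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, size=(50, 30)).astype(np.int8)
        for src, dst in [(0, 10), (5, 20), (12, 33), (25, 40), (31, 44)]:
            g[dst] = g[src]
        panel = make_panel(g)
        out = ld_prune(panel, r2_max=0.99, window=50, step=10)
        # exhaustive oracle: no retained pair with r2 > ceiling
        kept = set(map(int, out.variants["pos"]))
        assert out.n_variants == 45
        idx = [i for i in range(50) if int(panel.variants["pos"][i]) in kept]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                r2 = composite_r2(panel, idx[a], idx[b])
                if np.isfinite(r2):
                    assert r2 <= 0.99 + 1e-9


def _wc_oracle(n1, n2, p1, p2, h1, h2):
    """Direct transcription of the two-population Weir-Cockerham formulas."""
    r = 2
    nbar = (n1 + n2) / 2
    nc = (n1 + n2 - (n1**2 + n2**2) / (n1 + n2)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def _panel_from_counts(self, n_hom_alt_a, n_het_a, n_a, n_hom_alt_b, n_het_b, n_b):
        ga = [2] * n_hom_alt_a + [1] * n_het_a + [0] * (n_a - n_hom_alt_a - n_het_a)
        gb = [2] * n_hom_alt_b + [1] * n_het_b + [0] * (n_b - n_hom_alt_b - n_het_b)
        g = np.array([ga + gb], dtype=np.int8)
        panel = make_panel(g)
        ids_a = [f"s{i}" for i in range(n_a)]
        ids_b = [f"s{i}" for i in range(n_a, n_a + n_b)]
        return panel, ids_a, ids_b

    def test_no_differentiation(self):
        panel, ids_a, ids_b = self._panel_from_counts(10, 30, 50, 10, 30, 50)
        _, fst = wc_fst(panel, ids_a, ids_b)
        assert abs(fst) < 0.02

    def test_fixed_difference(self):
        panel, ids_a, ids_b = self._panel_from_counts(40, 0, 40, 0, 0, 40)
        _, fst = wc_fst(panel, ids_a, ids_b)
        assert fst > 0.95

    def test_against_formula_oracle(self):
        # n=20 each, p_A=0.8 (12 hom + 8 het), p_B=0.3 (2 hom + 8 het)
        panel, ids_a, ids_b = self._panel_from_counts(12, 8, 20, 2, 8, 20)
        comps, fst = wc_fst(panel, ids_a, ids_b)
        a, b, c = _wc_oracle(20, 20, 0.8, 0.3, 8 / 20, 8 / 20)
        assert comps.a[0] == pytest.approx(a)
        assert comps.b[0] == pytest.approx(b)
        assert comps.c[0] == pytest.approx(c)
        assert fst == pytest.approx(a / (a + b + c))

    def test_components_nonneg_sum(self, two_pop_panel):
        panel, popmap = two_pop_panel
        comps = wc_components(
            panel, [popmap.samples_for("A"), popmap.samples_for("B")]
        )
        total = comps.a + comps.b + comps.c
        assert np.all(np.isfinite(total))
        assert np.all(total >= -1e-12)

    def test_ratio_of_sums_not_mean_of_ratios(self, two_pop_panel):
        panel, popmap = two_pop_panel
        comps, fst = wc_fst(
            panel, popmap.samples_for("A"), popmap.samples_for("B")
        )
        with np.errstate(invalid="ignore"):
            per_snp = comps.a / (comps.a + comps.b + comps.c)
        mean_of_ratios = np.nanmean(per_snp)
        assert fst == pytest.approx(
            np.nansum(comps.a) / np.nansum(comps.a + comps.b + comps.c)
        )
        assert abs(fst - mean_of_ratios) > 1e-4  # the two estimators differ


class TestReynolds:
    def test_identical_frequencies_zero(self):
        g = np.array([[0, 1, 2, 0, 1, 2], [2, 1, 0, 2, 1, 0]], dtype=np.int8)
        panel = make_panel(g)
        popmap = make_popmap(
            [(f"s{i}", "A" if i < 3 else "B", "focal") for i in range(6)]
        )
        d = reynolds_distance_matrix(panel, popmap)
        assert d.loc["A", "B"] == pytest.approx(0.0)

    def test_symmetry_zero_diag(self, two_pop_panel):
        panel, popmap = two_pop_panel
        d = reynolds_distance_matrix(panel, popmap)
        assert np.allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
        assert (d.values >= 0).all()

    def test_star_phylogeny_ordering(self):
        # simulated star: A and B drift far, C stays near the ancestor that
        # A/B/C share -> d(A,B) should exceed d(A,C) and d(B,C)
        rng = np.random.default_rng(11)
        anc = rng.uniform(0.2, 0.8, size=400)

        def drift(p, gens, ne, rng):
            p = p.copy()
            for _ in range(gens):
                p = rng.binomial(2 * ne, p) / (2 * ne)
            return p

        pa = drift(anc, 40, 50, rng)
        pb = drift(anc, 40, 50, rng)
        pc = drift(anc, 2, 50, rng)
        g = np.hstack(
            [rng.binomial(2, p[:, None], size=(400, 15)) for p in (pa, pb, pc)]
        ).astype(np.int8)
        panel = make_panel(g)
        popmap = make_popmap(
            [(f"s{i}", "ABC"[i // 15], "focal") for i in range(45)]
        )
        d = reynolds_distance_matrix(panel, popmap)
        assert d.loc["A", "B"] > d.loc["A", "C"]
        assert d.loc["A", "B"] > d.loc["B", "C"]


class TestHammingMds:
    def test_identical_samples_same_coords(self):
        g = np.array(
            [[0, 0, 2], [1, 1, 0], [2, 2, 1], [0, 0, 2], [1, 1, 1]], dtype=np.int8
        )
        coords, _ = hamming_mds(make_panel(g), k=2)
        assert np.allclose(coords[0], coords[1], atol=1e-6)

    def test_equilateral_triangle(self):
        # three samples pairwise equally distant
        g = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        coords, _ = hamming_mds(make_panel(g), k=2)
        d01 = np.sum((coords[0] - coords[1]) ** 2)
        d02 = np.sum((coords[0] - coords[2]) ** 2)
        d12 = np.sum((coords[1] - coords[2]) ** 2)
        assert d01 == pytest.approx(d02, rel=1e-9)
        assert d01 == pytest.approx(d12, rel=1e-9)

    def test_diverged_populations_axis1(self, two_pop_panel):
        panel, popmap = two_pop_panel
        coords, shares = hamming_mds(panel, k=2)
        labels = np.array([0] * 10 + [1] * 10)
        gap = abs(coords[labels == 0, 0].mean() - coords[labels == 1, 0].mean())
        spread = coords[:, 0].std()
        assert gap > spread  # axis 1 separates the populations
        assert shares[0] > shares[1]

    def test_k_clipped_with_warning(self, small_panel, caplog):
        coords, shares = hamming_mds(small_panel, k=50)
        assert coords.shape == (12, 11)

    def test_reconstruction_matches_hamming(self, small_panel):
        # full-rank classical scaling reproduces the (squared-distance) matrix
        d = hamming_distance_matrix(small_panel)
        coords, _ = hamming_mds(small_panel, k=small_panel.n_samples - 1)
        recon = (
            np.sum(coords**2, axis=1)[:, None]
            + np.sum(coords**2, axis=1)[None, :]
            - 2 * coords @ coords.T
        )
        assert np.allclose(recon, d, atol=1e-8)

    def test_eigen_shares_bounded(self, small_panel):
        _, shares = hamming_mds(small_panel, k=5)
        assert shares.sum() <= 1.0 + 1e-9
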