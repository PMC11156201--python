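"""Diversity, FST and SFS estimators against enumeration and
dual-transcription oracles."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from purgescan.popstats import (
    compute_sfs,
    site_pi,
    wc_fst_site,
    windowed_fst,
    windowed_pi,
)
from purgescan.variant_io import CladeMap

from conftest import make_dataset


def brute_force_site_pi(c: int, n: int) -> Fraction:
    """Mean pairwise difference by enumerating all haplotype pairs."""
    haps = [1] * c + [0] * (n - c)
    pairs = list(combinations(range(n), 2))
    diff = sum(1 for i, j in pairs if haps[i] != haps[j])
    return Fraction(diff, len(pairs))


class TestSitePi:
    def test_worked_example(self):
        assert site_pi(2, 4) == pytest.approx(2 / 3)

    def test_monomorphic_is_zero(self):
        assert site_pi(0, 10) == 0.0
        assert site_pi(10, 10) == 0.0

    def test_single_allele_is_missing(self):
        assert np.isnan(site_pi(0, 1))

    def test_matches_pairwise_enumeration_exactly(self):
        for n in range(2, 13):
            for c in range(n + 1):
                expected = brute_force_site_pi(c, n)
                assert Fraction(2 * c * (n - c), n * (n - 1)) == expected
                assert site_pi(c, n) == pytest.approx(float(expected), abs=1e-15)


class TestWindowedPi:
    def test_single_snp_window_value(self):
        # dosages [1,1,0,0]: alt count 2 of 8 alleles -> site pi = 2*2*6/(8*7)
        ds = make_dataset([[1, 1, 0, 0]], pos=[500])
        track = windowed_pi(ds, {"chr1": 10_000}, window_bp=10_000, step_bp=10_000)
        assert track.values[0] == pytest.approx((2 * 2 * 6 / 56) / 10_000)

    def test_example_value_scaled_by_window_length(self):
        # one SNP with site pi = 2/3 in a 10 kb window -> 6.6667e-5 per bp
        ds = make_dataset([[1, 1]], pos=[500])  # c=2, n=4 -> 2/3
        track = windowed_pi(ds, {"chr1": 10_000}, window_bp=10_000, step_bp=10_000)
        assert track.values[0] == pytest.approx(6.6667e-5, rel=1e-3)

    def test_empty_window_is_zero_not_missing(self):
        ds = make_dataset([[1, 0]], pos=[55_000])
        track = windowed_pi(ds, {"chr1": 60_000}, window_bp=10_000, step_bp=10_000)
        assert track.values[0] == 0.0

    def test_window_larger_than_chromosome_truncates(self):
        ds = make_dataset([[1, 0]], pos=[100])
        track = windowed_pi(ds, {"chr1": 5_000}, window_bp=50_000, step_bp=10_000)
        assert len(track) == 1
        assert track.windows.loc[0, "end"] == 5_000

    def test_each_interior_snp_in_window_per_step_windows(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(
            rng.integers(0, 3, size=(30, 4)),
            pos=np.sort(rng.choice(np.arange(100_000, 200_000), 30, replace=False)),
        )
        track = windowed_pi(ds, {"chr1": 400_000}, window_bp=50_000, step_bp=10_000)
        counts = np.zeros(ds.n_sites, dtype=int)
        for row in track.windows.itertuples():
            counts += (ds.pos > row.start) & (ds.pos <= row.end)
        assert np.all(counts == 5)  # window_bp / step_bp

    def test_invariant_to_allele_swap(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(-1, 3, size=(40, 6))
        ds1 = make_dataset(dosage)
        flipped = np.where(dosage != -1, 2 - dosage, -1)
        ds2 = make_dataset(flipped)
        t1 = windowed_pi(ds1, {"chr1": 5_000}, 1_000, 1_000)
        t2 = windowed_pi(ds2, {"chr1": 5_000}, 1_000, 1_000)
        assert np.allclose(t1.values, t2.values, equal_nan=True)

    def test_fourfold_site_list_mode_divides_by_listed_sites(self):
        ds = make_dataset([[1, 1], [1, 1]], pos=[100, 200])  # both pi = 2/3
        site_list = {("chr1", 100), ("chr1", 5_000)}  # one SNP + one monomorphic
        track = windowed_pi(
            ds, {"chr1": 10_000}, mode="nonoverlapping_10kb", site_list=site_list
        )
        assert track.values[0] == pytest.approx((2 / 3) / 2)


def wc84_reference(c1, m1, c2, m2):
    """Independent transcription of the two-population Weir-Cockerham (1984)
    variance components with HWE heterozygosity."""
    n = np.array([m1 / 2, m2 / 2])
    p = np.array([c1 / m1, c2 / m2])
    h = 2 * p * (1 - p)
    r = 2
    nbar = n.mean()
    nc = (r * nbar - (n**2).sum() / (r * nbar)) / (r - 1)
    pbar = (n * p).sum() / (n.sum())
    s2 = (n * (p - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n * h).sum() / n.sum()
    a = nbar / nc * (s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4))
    b = nbar / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2
    return a, b, c


class TestWcFst:
    def test_fixed_difference_is_one(self):
        a, b, c = wc_fst_site([(20, 20), (0, 20)])
        assert a / (a + b + c) == pytest.approx(1.0)

    def test_identical_intermediate_frequencies_give_nonpositive_a(self):
        a, _, _ = wc_fst_site([(10, 20), (10, 20)])
        assert a <= 0

    def test_requires_two_alleles_per_population(self):
        with pytest.raises(ValueError):
            wc_fst_site([(0, 1), (5, 10)])

    @given(
        m1=st.integers(2, 40).map(lambda x: 2 * x),
        m2=st.integers(2, 40).map(lambda x: 2 * x),
        f1=st.floats(0, 1),
        f2=st.floats(0, 1),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_matches_independent_transcription(self, m1, m2, f1, f2):
        c1, c2 = int(round(f1 * m1)), int(round(f2 * m2))
        ours = wc_fst_site([(c1, m1), (c2, m2)])
        ref = wc84_reference(c1, m1, c2, m2)
        assert np.allclose(ours, ref, atol=1e-12)


class TestWindowedFst:
    def clade_map(self, ds, k):
        s2c = {s: ("A" if i < k else "B") for i, s in enumerate(ds.samples)}
        return CladeMap(s2c)

    def test_single_site_window_equals_site_estimate(self):
        ds = make_dataset([[2, 2, 2, 0, 0, 0]], pos=[500])
        cm = self.clade_map(ds, 3)
        track = windowed_fst(ds, cm, ("A", "B"), {"chr1": 1_000}, 1_000, 1_000, min_snps=1)
        a, b, c = wc_fst_site([(6, 6), (0, 6)])
        assert track.values[0] == pytest.approx(a / (a + b + c))

    def test_too_few_snps_is_missing(self):
        ds = make_dataset([[2, 2, 0, 0]], pos=[500])
        cm = self.clade_map(ds, 2)
        track = windowed_fst(ds, cm, ("A", "B"), {"chr1": 1_000}, 1_000, 1_000, min_snps=10)
        assert np.isnan(track.values[0])

    def test_panmictic_mean_near_zero(self):
        rng = np.random.default_rng(7)
        freqs = rng.uniform(0.1, 0.9, size=300)
        dosage = rng.binomial(2, freqs[:, None], size=(300, 20)).astype(np.int8)
        ds = make_dataset(dosage, pos=np.arange(1, 301) * 100)
        cm = self.clade_map(ds, 10)
        track = windowed_fst(ds, cm, ("A", "B"), {"chr1": 31_000}, 31_000, 31_000, min_snps=1)
        assert abs(track.values[0]) < 0.03


class TestSfs:
    def test_counting_example(self):
        # derived counts {1, 1, 2} fully called with n=4 haplotypes
        derived = np.array([[1, 0], [0, 1], [1, 1]], dtype=np.int8)
        sfs = compute_sfs(derived, np.array([0, 1]), projection_n=4)
        assert np.allclose(sfs.counts, [2, 1, 0])

    def test_fixed_classes_excluded(self):
        derived = np.array([[0, 0], [2, 2]], dtype=np.int8)
        sfs = compute_sfs(derived, np.array([0, 1]), projection_n=4)
        assert sfs.total == 0

    def test_projection_mass_conservation(self):
        rng = np.random.default_rng(5)
        derived = rng.integers(0, 3, size=(50, 8)).astype(np.int8)
        full = compute_sfs(derived, np.arange(8), projection_n=16)
        seg = sum(1 for row in derived if 0 < row.sum() < 16)
        assert full.total == pytest.approx(seg)

    def test_projection_with_missing_downsamples(self):
        derived = np.array([[1, -1, 0, 0]], dtype=np.int8)  # 1 of 6 called haplotypes
        sfs = compute_sfs(derived, np.arange(4), projection_n=4)
        # hypergeometric: P(j of 4 | 1 of 6) for j=1..3
        from scipy.stats import hypergeom

        expected = hypergeom.pmf([1, 2, 3], 6, 1, 4)
        assert np.allclose(sfs.counts, expected)

    def test_projection_too_large_fails(self):
        derived = np.array([[1, -1], [1, -1], [0, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="projection"):
            compute_sfs(derived, np.arange(2), projection_n=4)
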