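"""Region detection, significance statistics, FDR and genome-wide calling."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rangercall.alignment_io import ChromTable
from rangercall.coverage import build_coverage
from rangercall.benchmark_synthetics import generate_background, spike_peak
from rangercall.region_caller import (
    bh_fdr,
    call_regions,
    detect_candidate_regions,
    fit_control_scaling,
    poisson_region_threshold,
    region_pvalue_binomial,
    region_pvalue_poisson,
)


def poisson_tail_oracle(lam, h):
    """P(X >= h) by direct summation of the density, independent of scipy."""
    if h <= 0:
        return 1.0
    acc = 0.0
    term = math.exp(-lam)
    for k in range(h):
        acc += term
        term *= lam / (k + 1)
    return 1.0 - acc


def binomial_tail_oracle(k, n):
    """P(X >= k), X ~ Binomial(n, 1/2), exact rational arithmetic."""
    return float(
        sum(Fraction(math.comb(n, j), 2**n) for j in range(k, n + 1))
    )


class TestPoissonThreshold:
    def test_zero_rate_threshold_one(self):
        assert poisson_region_threshold(0.0, 1e-4) == 1

    def test_lambda_one_exact(self):
        h = poisson_region_threshold(1.0, 1e-4)
        assert h == 7
        assert poisson_tail_oracle(1.0, 7) < 1e-4 <= poisson_tail_oracle(1.0, 6)

    def test_monotone_in_rate(self):
        assert poisson_region_threshold(2.0) >= poisson_region_threshold(1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.01, 20.0), st.sampled_from([1e-3, 1e-4, 1e-5]))
    def test_matches_tail_oracle(self, lam, p0):
        h = poisson_region_threshold(lam, p0)
        assert poisson_tail_oracle(lam, h) < p0
        if h > 1:
            assert poisson_tail_oracle(lam, h - 1) >= p0


def brute_force_regions(depth, h, max_gap):
    """Position-by-position scan oracle for detect_candidate_regions."""
    runs = []
    i = 0
    n = len(depth)
    while i < n:
        if depth[i] >= h:
            j = i
            while j < n and depth[j] >= h:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < max_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [(s, e, max(depth[s:e])) for s, e in merged]


class TestDetectRegions:
    def test_gap_not_merged(self):
        depth = np.array([0, 0, 3, 4, 5, 0, 0, 6, 7, 0])
        assert detect_candidate_regions(depth, 3, 1) == [(2, 5, 5), (7, 9, 7)]

    def test_gap_merged(self):
        depth = np.array([0, 0, 3, 4, 5, 0, 0, 6, 7, 0])
        assert detect_candidate_regions(depth, 3, 3) == [(2, 9, 7)]

    def test_all_below_threshold_empty(self):
        assert detect_candidate_regions(np.array([1, 2, 1]), 3, 0) == []

    def test_agrees_with_bruteforce_on_random_profiles(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(1, 201))
            depth = rng.integers(0, 8, size=n)
            h = int(rng.integers(1, 6))
            gap = int(rng.integers(0, 10))
            assert detect_candidate_regions(depth, h, gap) == brute_force_regions(
                list(depth), h, gap
            )


class TestScaling:
    def test_identical_bins_slope_one(self):
        bins = np.array([3.0, 5.0, 2.0, 8.0])
        fit = fit_control_scaling(bins, bins)
        assert fit.method == "regression"
        assert fit.r == pytest.approx(1.0)

    def test_double_control_slope_half(self):
        t = np.array([3.0, 5.0, 2.0, 8.0])
        fit = fit_control_scaling(t, 2 * t)
        assert fit.r == pytest.approx(0.5)

    def test_zero_control_falls_back_to_library_ratio(self):
        t = np.array([3.0, 5.0])
        fit = fit_control_scaling(t, np.zeros(2), total_treat=100, total_ctrl=50)
        assert fit.method == "library_ratio"
        assert fit.r == pytest.approx(2.0)

    def test_excluded_bins_ignored(self):
        t = np.array([1.0, 1.0, 100.0])
        c = np.array([1.0, 1.0, 1.0])
        fit = fit_control_scaling(t, c, excluded_bins=[2])
        assert fit.r == pytest.approx(1.0)


class TestBinomialPvalue:
    def test_zero_treatment_is_one(self):
        assert region_pvalue_binomial(0, 5) == 1.0

    def test_five_five_exact(self):
        assert region_pvalue_binomial(5, 5) == pytest.approx(
            0.623046875, abs=1e-12
        )
        assert binomial_tail_oracle(5, 10) == pytest.approx(638 / 1024, abs=0)

    def test_ten_zero_closed_form(self):
        assert region_pvalue_binomial(10, 0) == pytest.approx(2**-10, rel=1e-9)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 40), st.integers(0, 40))
    def test_matches_exact_oracle(self, kt, kc):
        expected = 1.0 if kt == 0 else binomial_tail_oracle(kt, kt + kc)
        assert region_pvalue_binomial(kt, kc) == pytest.approx(expected, rel=1e-9)


class TestPoissonPvalue:
    def test_zero_count_is_one(self):
        assert region_pvalue_poisson(0, 1.0, 200, 200) == 1.0

    def test_mu_one_count_seven(self):
        p = region_pvalue_poisson(7, 1.0, 200, 200)
        assert p == pytest.approx(poisson_tail_oracle(1.0, 7), rel=1e-9)
        assert p == pytest.approx(8.32e-5, rel=1e-2)

    def test_decreasing_in_count(self):
        ps = [region_pvalue_poisson(k, 2.0, 400, 200) for k in range(1, 10)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


def bh_reference(pvals):
    """Quadratic-time BH definition: q_i = min over p_(j) >= p_i of m*p_(j)/j."""
    m = len(pvals)
    ranked = sorted(pvals)
    out = []
    for p in pvals:
        candidates = [
            m * pj / (j + 1) for j, pj in enumerate(ranked) if pj >= p
        ]
        out.append(min(1.0, min(candidates)))
    return out


class TestBH:
    def test_hand_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_ties_share_q(self):
        assert bh_fdr([0.05] * 10) == pytest.approx([0.05] * 10)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_matches_quadratic_reference(self, pvals):
        assert bh_fdr(pvals) == pytest.approx(bh_reference(pvals), rel=1e-9)


def _profiles(seed, spike=False):
    table = ChromTable({"chr1": 2_000_000}, provenance="precomputed")
    rng = np.random.default_rng([seed, 0])
    treat, _ = generate_background(2_000_000, 4000, seed=rng)
    if spike:
        treat += spike_peak(1_000_000, 100, seed=rng, chrom_len=2_000_000)
    ctrl, _ = generate_background(
        2_000_000, len(treat), seed=np.random.default_rng([seed, 1])
    )
    tp = build_coverage(treat, 200, table)
    cp = build_coverage(ctrl, 200, table)
    return tp, cp


class TestCallRegions:
    def test_spiked_peak_yields_one_region_containing_center(self):
        tp, cp = _profiles(3, spike=True)
        regions, fit, info = call_regions(tp, cp)
        spanning = [r for r in regions if r.start <= 1_000_000 < r.end]
        assert len(spanning) == 1
        assert spanning[0].q_value <= 0.01

    def test_null_background_rarely_survives(self):
        hits = 0
        for seed in range(10):
            tp, cp = _profiles(100 + seed)
            regions, _, _ = call_regions(tp, cp)
            hits += bool(regions)
        assert hits <= 2  # ~2 per 10 Mb allowed by chance

    def test_fdr_zero_empty(self):
        tp, cp = _profiles(3, spike=True)
        regions, _, _ = call_regions(tp, cp, fdr_cutoff=0.0)
        assert regions == []

    def test_nestedness_across_fdr(self):
        tp, cp = _profiles(3, spike=True)
        strict, _, _ = call_regions(tp, cp, fdr_cutoff=0.01)
        loose, _, _ = call_regions(tp, cp, fdr_cutoff=0.05)
        strict_set = {(r.chrom, r.start, r.end) for r in strict}
        loose_set = {(r.chrom, r.start, r.end) for r in loose}
        assert strict_set <= loose_set

    def test_regions_disjoint_sorted(self):
        tp, cp = _profiles(3, spike=True)
        regions, _, _ = call_regions(tp, cp, fdr_cutoff=0.5)
        for a, b in zip(regions, regions[1:]):
            if a.chrom == b.chrom:
                assert a.end <= b.start
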