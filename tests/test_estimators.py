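"""F_hom, F_GRM, ROH detection, F_ROH, expected ROH length, g2, HH correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest

import autozyg as az
from autozyg.estimators import _g2_core
from tests.conftest import make_genotype_matrix, make_map


class TestFhom:
    def test_extremes_and_missing(self):
        gm = make_genotype_matrix(
            [[1, 1, 1, 1], [0, 2, 0, 2], [0, 0, 2, 1]]
        )
        gm.dosages[2, 3] = az.MISSING
        f = az.f_hom(gm)
        assert f["i0"] == 0.0
        assert f["i1"] == 1.0
        assert f["i2"] == pytest.approx(1.0)  # 3 hom / 3 called

    def test_three_hom_one_het_one_missing(self):
        gm = make_genotype_matrix([[0, 2, 0, 1, az.MISSING]])
        assert az.f_hom(gm)["i0"] == pytest.approx(0.75)

    def test_all_missing_individual_is_nan(self):
        gm = make_genotype_matrix([[az.MISSING, az.MISSING], [0, 1]])
        f = az.f_hom(gm)
        assert np.isnan(f["i0"]) and f["i1"] == 0.5


class TestFgrm:
    def test_printed_formula_at_half(self):
        # p = 0.5: het -> -1, either homozygote -> +1
        for x, want in [(1, -1.0), (0, 1.0), (2, 1.0)]:
            gm = make_genotype_matrix([[x]])
            assert az.f_grm(gm, p=np.array([0.5]))["i0"] == pytest.approx(want)

    def test_rare_homozygote_weighted_more(self):
        p = 0.9
        num = lambda x: (x * x - (1 + 2 * p) * x + 2 * p * p) / (2 * p * (1 - p))
        assert num(0) > num(2)  # rare-allele homozygote scores higher
        gm = make_genotype_matrix([[0], [2]])
        f = az.f_grm(gm, p=np.array([0.9]))
        assert f["i0"] == pytest.approx(num(0))
        assert f["i1"] == pytest.approx(num(2))

    def test_hwe_population_mean_zero(self):
        # exact HWE proportions: 1 hom-ref : 2 het : 1 hom-alt at p = 0.5
        gm = make_genotype_matrix([[2], [1], [1], [0]])
        assert az.f_grm(gm).mean() == pytest.approx(0.0)
        # and algebraically for any p: E[num] = 0 under HWE
        for p in (0.1, 0.3, 0.7):
            e = (
                p * p * (4 - (1 + 2 * p) * 2 + 2 * p * p)
                + 2 * p * (1 - p) * (1 - (1 + 2 * p) + 2 * p * p)
                + (1 - p) ** 2 * 2 * p * p
            )
            assert e == pytest.approx(0.0)

    def test_monomorphic_marker_errors(self):
        gm = make_genotype_matrix([[2], [2]])
        with pytest.raises(az.GenotypeError, match="monomorphic"):
            az.f_grm(gm)

    def test_missing_excluded(self):
        gm = make_genotype_matrix([[1, az.MISSING], [1, 1], [0, 0], [2, 2]])
        f = az.f_grm(gm)
        assert f["i0"] == pytest.approx(-1.0)  # only the called locus counts


def _roh_fixture(n_snps=60, spacing_bp=170_000, het_at=()):
    """One chromosome of evenly spaced homozygous SNPs (dosage 2), with
    heterozygous calls at the given indices."""
    bp = (np.arange(n_snps) + 1) * spacing_bp
    d = np.full((1, n_snps), 2, dtype=np.int8)
    for j in het_at:
        d[0, j] = 1
    gm = make_genotype_matrix(d)
    mmap = make_map({1: bp})
    return gm, mmap


class TestDetectROH:
    def test_clean_long_run_detected(self):
        # 40 hom SNPs at 170 kb spacing span 6.63 Mb
        gm, mmap = _roh_fixture(n_snps=40)
        segs = az.detect_roh(gm, mmap)
        assert len(segs) == 1
        assert segs[0].n_snps == 40
        assert segs[0].length_kb == pytest.approx((40 - 1) * 170.0)

    def test_run_below_min_kb_rejected(self):
        # 29 intervals x 170 kb = 4.93 Mb < 5 Mb
        gm, mmap = _roh_fixture(n_snps=30)
        assert az.detect_roh(gm, mmap) == []

    def test_too_few_snps_rejected(self):
        # 14 SNPs spanning 6.1 Mb (min_snps = 15)
        gm, mmap = _roh_fixture(n_snps=14, spacing_bp=470_000)
        assert az.detect_roh(gm, mmap) == []

    def test_gap_splits_run(self):
        # two 4.8 Mb halves separated by a 1.2 Mb gap -> split, neither kept
        bp1 = (np.arange(30) + 1) * 166_000
        bp2 = bp1[-1] + 1_200_000 + (np.arange(30) + 1) * 166_000
        bp = np.concatenate([bp1, bp2])
        gm = make_genotype_matrix(np.full((1, 60), 0, dtype=np.int8))
        mmap = make_map({1: bp})
        assert az.detect_roh(gm, mmap) == []
        # without the gap the same 60 SNPs are one accepted segment
        gm2, mmap2 = _roh_fixture(n_snps=60, spacing_bp=166_000)
        assert len(az.detect_roh(gm2, mmap2)) == 1

    def test_het_call_breaks_run(self):
        gm, mmap = _roh_fixture(n_snps=60, het_at=(30,))
        segs = az.detect_roh(gm, mmap)
        # both flanks are < 5 Mb at 170 kb spacing x ~29 SNPs
        assert segs == []

    def test_density_filter(self):
        # 16 SNPs spanning 6 Mb -> 400 kb/SNP > 275 kb/SNP cap
        gm, mmap = _roh_fixture(n_snps=16, spacing_bp=400_000)
        assert az.detect_roh(gm, mmap) == []

    def test_missing_calls_tolerated_in_windows(self):
        gm, mmap = _roh_fixture(n_snps=40)
        gm.dosages[0, 20] = az.MISSING  # <= 2 missing per window allowed
        segs = az.detect_roh(gm, mmap)
        assert len(segs) == 1 and segs[0].n_snps == 40

    def test_min10mb_subset_of_min5mb(self, small_sim):
        _, gm, mmap, _ = small_sim
        gm2, m2, _ = az.qc_filter(gm, mmap)
        segs5 = az.detect_roh(gm2, m2, az.ROHParams(min_kb=5000))
        segs10 = az.detect_roh(gm2, m2, az.ROHParams(min_kb=10000))
        assert set(segs10) <= set(segs5)

    def test_unsorted_map_errors(self):
        gm = make_genotype_matrix(np.full((1, 3), 2, dtype=np.int8))
        table = pd.DataFrame(
            {"marker": list("abc"), "chrom": ["1"] * 3, "bp": [3, 1, 2]}
        )
        with pytest.raises(az.GenotypeError):
            az.MarkerMap(table)


class TestFroh:
    def test_no_segments_zero(self):
        mmap = make_map({1: [1, 2]}, genome_length_kb=2_434_125)
        f = az.f_roh([], mmap, individuals=["x"])
        assert f["x"] == 0.0

    def test_median_paper_segment(self):
        # one 6,600 kb segment over the full assayed span
        mmap = make_map({1: [1, 2]}, genome_length_kb=2_434_125)
        seg = az.ROHSegment("x", "1", 100, 6_600_100, 36)
        f = az.f_roh([seg], mmap, individuals=["x"])
        assert f["x"] == pytest.approx(0.002712, abs=1e-6)

    def test_full_coverage_is_one(self):
        mmap = make_map({1: [1, 2]}, genome_length_kb=1000.0)
        seg = az.ROHSegment("x", "1", 0, 1_000_000, 20)
        assert az.f_roh([seg], mmap, individuals=["x"])["x"] == pytest.approx(1.0)


class TestExpectedROHLength:
    def test_values_and_monotonicity(self):
        assert az.expected_roh_length_mb(10) == pytest.approx(5.0)
        assert az.expected_roh_length_mb(5) == pytest.approx(10.0)
        gs = np.arange(1, 60)
        vals = [az.expected_roh_length_mb(g) for g in gs]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1.0

    def test_invalid_g(self):
        with pytest.raises(ValueError):
            az.expected_roh_length_mb(0)


def _g2_bruteforce(dosages):
    """Literal loop implementation of the within/between pair ratio."""
    d = np.asarray(dosages)
    h = (d == 1).astype(float)
    n, L = h.shape
    w_sum = b_sum = 0.0
    n_pairs = 0
    for l, k in itertools.permutations(range(L), 2):
        w_sum += h[:, l] @ h[:, k] / n
        tot = 0.0
        for i in range(n):
            for j in range(n):
                if i != j:
                    tot += h[i, l] * h[j, k]
        b_sum += tot / (n * (n - 1))
        n_pairs += 1
    return (w_sum / n_pairs) / (b_sum / n_pairs) - 1


class TestG2:
    def test_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        d = rng.choice([0, 1, 2], size=(8, 6), p=[0.3, 0.4, 0.3]).astype(np.int8)
        gm = make_genotype_matrix(d)
        res = az.g2_estimate(gm, n_boot=5, n_perm=5, seed=1)
        assert res.g2 == pytest.approx(_g2_bruteforce(d), rel=1e-10)

    def test_fast_and_pairwise_paths_agree_on_complete_data(self):
        rng = np.random.default_rng(1)
        d = rng.choice([0, 1, 2], size=(20, 15), p=[0.3, 0.4, 0.3])
        het = d == 1
        valid = np.ones_like(het, dtype=bool)
        assert _g2_core(het, valid) == pytest.approx(
            _g2_core(het, valid, pairwise_complete=True), rel=1e-12
        )

    def test_null_data_small_g2(self):
        """Unrelated individuals, unlinked loci: g2 within 3 bootstrap SD of 0."""
        rng = np.random.default_rng(2)
        p = rng.uniform(0.2, 0.8, size=300)
        d = (rng.random((250, 300, 2)) < p[None, :, None]).sum(axis=2)
        gm = make_genotype_matrix(d.astype(np.int8))
        res = az.g2_estimate(gm, n_boot=200, n_perm=99, seed=3)
        assert abs(res.g2) < 3 * res.bootstrap_sd

    def test_inbred_population_positive_g2(self, small_sim):
        _, gm, mmap, truth = small_sim
        gm2, _, _ = az.qc_filter(gm, mmap)
        res = az.g2_estimate(gm2, n_boot=100, n_perm=199, seed=4)
        assert truth.var() > 0
        assert res.g2 > 0
        assert res.permutation_p < 0.05

    def test_degenerate_duplicate_individuals_flagged(self):
        row = np.array([1, 1, 0, 2, 1], dtype=np.int8)
        gm = make_genotype_matrix(np.vstack([row, row, row]))
        res = az.g2_estimate(gm, n_boot=10, n_perm=10, seed=5)
        # within == between for identical individuals -> g2 == 0 exactly
        assert res.g2 == pytest.approx(0.0, abs=1e-12)

    def test_zero_het_loci_dropped_with_warning(self):
        d = np.array([[1, 0], [1, 2], [0, 0], [1, 2]], dtype=np.int8)
        with pytest.warns(UserWarning, match="no observed heterozygotes"):
            with pytest.raises(az.GenotypeError):
                az.g2_estimate(make_genotype_matrix(d), 5, 5, 0)

    def test_seed_reproducibility(self, small_sim):
        _, gm, _, _ = small_sim
        sub = gm.subset(individuals=np.arange(60), markers=np.arange(120))
        a = az.g2_estimate(sub, n_boot=30, n_perm=30, seed=9)
        b = az.g2_estimate(sub, n_boot=30, n_perm=30, seed=9)
        assert (a.g2, a.bootstrap_sd, a.permutation_p) == (
            b.g2, b.bootstrap_sd, b.permutation_p
        )


class TestHHCorrelation:
    def test_duplicated_panel(self):
        rng = np.random.default_rng(6)
        half = rng.choice([0, 1, 2], size=(50, 40), p=[0.3, 0.4, 0.3])
        dup = np.hstack([half, half]).astype(np.int8)
        gm = make_genotype_matrix(dup)
        # the split aligned with the duplication correlates exactly 1
        a = az.f_hom(gm.subset(markers=np.arange(40)))
        b = az.f_hom(gm.subset(markers=np.arange(40, 80)))
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0)
        # and random splits still pick up the duplication-induced signal
        out = az.hh_correlation(gm, n_splits=30, seed=0)
        assert out["F_hom"][0] > 0.2

    def test_no_inbreeding_variance_near_zero(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.3, 0.7, 200)
        d = (rng.random((150, 200, 2)) < p[None, :, None]).sum(axis=2)
        out = az.hh_correlation(make_genotype_matrix(d.astype(np.int8)),
                                n_splits=30, seed=1)
        assert abs(out["F_hom"][0]) < 0.15
        assert abs(out["F_GRM"][0]) < 0.15

    def test_correlation_grows_with_marker_count(self, small_sim):
        """Identity disequilibrium makes HH correlation rise with panel size."""
        _, gm, mmap, _ = small_sim
        gm2, _, _ = az.qc_filter(gm, mmap)
        rng = np.random.default_rng(8)
        small = gm2.subset(markers=rng.choice(gm2.n_markers, 80, replace=False))
        big = gm2
        r_small = az.hh_correlation(small, n_splits=25, seed=2)["F_hom"][0]
        r_big = az.hh_correlation(big, n_splits=25, seed=2)["F_hom"][0]
        assert r_big > r_small
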