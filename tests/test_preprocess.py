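import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtri
from scipy.stats import rankdata

from gxeherit import SimulationConfig, simulate_genotypes
from gxeherit.errors import (
    DegenerateInputError,
    DomainError,
    InvalidConfigError,
    RankDeficiencyError,
)
from gxeherit.preprocess import (
    exposure_outcome_assoc,
    hwe_chi2_pvalue,
    hwe_exact_pvalue,
    log_transform,
    quartile_by_sex,
    rank_int,
    variant_qc,
)
from gxeherit.types import GenotypeMatrix


def _matrix(columns):
    """Build a GenotypeMatrix from a list of per-variant dosage lists."""
    dosages = np.array(columns, dtype=float).T
    m = dosages.shape[1]
    variants = pd.DataFrame(
        {
            "snp": [f"v{j}" for j in range(m)],
            "chrom": 1,
            "bp": np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)


def _hwe_genotypes(n_aa, n_ab, n_bb):
    return [2] * n_aa + [1] * n_ab + [0] * n_bb


def hwe_exact_oracle(n_het, n_hom_rare, n_hom_common):
    """Full enumeration with exact log-factorial probabilities."""
    n = n_het + n_hom_rare + n_hom_common
    rare = 2 * n_hom_rare + n_het

    def log_prob(h):
        hr = (rare - h) // 2
        hc = n - h - hr
        return (
            math.lgamma(n + 1)
            - math.lgamma(hr + 1) - math.lgamma(hc + 1) - math.lgamma(h + 1)
            + h * math.log(2)
            + math.lgamma(rare + 1) + math.lgamma(2 * n - rare + 1)
            - math.lgamma(2 * n + 1)
        )

    hs = [h for h in range(rare % 2, min(rare, 2 * n - rare) + 1, 2)]
    probs = {h: math.exp(log_prob(h)) for h in hs}
    obs = probs[n_het]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


class TestHweExact:
    @pytest.mark.parametrize(
        "het,hom_r,hom_c",
        [(80, 10, 10), (50, 25, 25), (10, 1, 89), (0, 5, 95), (21, 10, 69)],
    )
    def test_matches_enumeration_oracle(self, het, hom_r, hom_c):
        assert hwe_exact_pvalue(het, hom_r, hom_c) == pytest.approx(
            hwe_exact_oracle(het, hom_r, hom_c), rel=1e-9
        )

    def test_extreme_heterozygote_excess_is_significant(self):
        # (AA, Aa, aa) = (10, 80, 10): far more hets than HWE allows
        assert hwe_exact_pvalue(80, 10, 10) < 1e-6

    def test_equilibrium_counts_not_significant(self):
        # p=0.5, n=100: (25, 50, 25) is the modal configuration
        assert hwe_exact_pvalue(50, 25, 25) > 0.5

    def test_chi2_variant_agrees_roughly(self):
        p_exact = hwe_exact_pvalue(80, 10, 10)
        p_chi2 = hwe_chi2_pvalue(80, 10, 10)
        assert p_chi2 < 1e-6 and p_exact < 1e-6

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            hwe_exact_pvalue(-1, 5, 5)


class TestVariantQC:
    def test_maf_threshold_is_strict_below(self):
        # MAFs 0.04, 0.05, 0.30 from allele counts in 50 samples
        n = 50
        cols = []
        for maf in (0.04, 0.05, 0.30):
            n_alt = int(round(2 * n * maf))
            col = [0] * n
            for i in range(n_alt):  # spread alt alleles as hets: HWE-safe
                col[i] = 1
            cols.append(col)
        g = _matrix(cols)
        filtered, report = variant_qc(g, hwe_p_min=1e-10)
        assert report.n_removed_maf == 1
        assert report.n_retained == 2
        assert "v0" not in report.retained_ids

    def test_missingness_filter_first(self):
        col = [1.0] * 47 + [np.nan] * 3  # 6% missing
        g = _matrix([col])
        _, report = variant_qc(g, miss_max=0.05)
        assert report.n_removed_missingness == 1
        assert report.n_retained == 0

    def test_hwe_filter(self):
        g = _matrix([_hwe_genotypes(10, 80, 10)])
        filtered, report = variant_qc(g, maf_min=0.05, hwe_p_min=1e-6)
        assert report.n_removed_hwe == 1

    def test_counts_sum(self):
        cfg = SimulationConfig(n_samples=300, n_variants=50, seed=2,
                               maf_range=(0.02, 0.5))
        g = simulate_genotypes(cfg)
        _, report = variant_qc(g)
        assert (
            report.n_input
            - report.n_removed_missingness
            - report.n_removed_maf
            - report.n_removed_hwe
            == report.n_retained
        )

    def test_idempotent(self):
        cfg = SimulationConfig(n_samples=300, n_variants=60, seed=3,
                               maf_range=(0.02, 0.5))
        g = simulate_genotypes(cfg)
        once, r1 = variant_qc(g)
        twice, r2 = variant_qc(once)
        assert r2.n_retained == r1.n_retained
        assert list(r2.retained_ids) == list(r1.retained_ids)

    def test_empty_result_is_not_a_crash(self):
        g = _matrix([[0] * 20, [0] * 20])  # monomorphic, MAF 0
        filtered, report = variant_qc(g)
        assert report.n_retained == 0
        assert filtered.n_variants == 0

    def test_bad_threshold_rejected(self):
        g = _matrix([[1] * 20])
        with pytest.raises(InvalidConfigError):
            variant_qc(g, miss_max=1.5)


class TestLogTransform:
    def test_log_identity(self):
        np.testing.assert_allclose(log_transform(np.array([1.0])), [0.0])

    def test_log_e(self):
        np.testing.assert_allclose(log_transform(np.array([np.e])), [1.0])

    def test_log_ratio(self):
        out = log_transform(np.array([2.0, 4.0]))
        assert out[1] - out[0] == pytest.approx(np.log(2))

    def test_nonpositive_names_index(self):
        with pytest.raises(DomainError, match="index 2"):
            log_transform(np.array([1.0, 2.0, -3.0]))

    def test_missing_passes_through(self):
        out = log_transform(np.array([1.0, np.nan]))
        assert np.isnan(out[1])


class TestRankInt:
    def test_three_point_oracle(self):
        out = rank_int(np.array([10.0, 20.0, 30.0]))
        expected = [ndtri(1 / 6), 0.0, ndtri(5 / 6)]
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert out[0] == pytest.approx(-0.9674, abs=1e-4)

    def test_median_of_odd_tie_free_is_zero(self):
        out = rank_int(np.array([5.0, 1.0, 9.0, 3.0, 7.0]))
        assert out[np.argsort([5, 1, 9, 3, 7])[2]] == pytest.approx(0.0)

    def test_ties_get_average_rank(self):
        out = rank_int(np.array([5.0, 5.0, 9.0]))
        # tied pair at average rank 1.5 -> Phi^-1((1.5-0.5)/3)
        assert out[0] == out[1] == pytest.approx(ndtri(1 / 3))

    def test_missing_stays_missing(self):
        out = rank_int(np.array([1.0, np.nan, 3.0]))
        assert np.isnan(out[1])
        assert not np.isnan(out[[0, 2]]).any()

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            rank_int(np.array([2.0, 2.0, 2.0]))

    @given(st.lists(st.floats(-1e6, 1e6), min_size=5, max_size=60, unique=True))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_ranks_and_mean_zero(self, values):
        x = np.array(values)
        out = rank_int(x)
        order = np.argsort(x)
        assert np.all(np.diff(out[order]) > 0)
        assert abs(out.mean()) < 1e-9

    def test_matches_direct_formula(self, rng):
        x = rng.normal(size=200)
        out = rank_int(x)
        expected = ndtri((rankdata(x) - 0.5) / 200)
        np.testing.assert_allclose(out, expected)


class TestQuartileBySex:
    def test_equal_groups_within_one_sex(self):
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8, 10, 20, 30, 40, 50, 60, 70, 80],
                          dtype=float)
        sex = np.array([0] * 8 + [1] * 8)
        labels = quartile_by_sex(values, sex)
        for s in (0, 1):
            counts = np.bincount(labels[sex == s], minlength=5)[1:]
            assert list(counts) == [2, 2, 2, 2]

    def test_boundary_value_goes_to_lower_group(self):
        # stratum 1..8: type-7 Q1 cut = 2.75 -> value 2 in Q1;
        # median cut = 4.5; Q3 cut = 6.25 -> value 6 not above Q3
        values = np.array([1, 2, 3, 4, 5, 6, 7, 8] * 2, dtype=float)
        sex = np.array([0] * 8 + [1] * 8)
        labels = quartile_by_sex(values, sex)
        assert labels[1] == 1  # value 2
        cuts = np.quantile(values[:8], [0.25, 0.5, 0.75])
        assert cuts[0] == pytest.approx(2.75)
        # a value exactly on a cut is assigned to the group below it
        v = np.array([1, 2.75, 3, 4, 5, 6, 7, 8] * 2, dtype=float)
        labels2 = quartile_by_sex(v, sex)
        assert labels2[1] == 1

    def test_pooled_quartile_share(self, rng):
        values = np.concatenate([rng.uniform(0, 100, 500), rng.uniform(0, 100, 500)])
        sex = np.array([0] * 500 + [1] * 500)
        labels = quartile_by_sex(values, sex)
        share = np.mean(labels == 1)
        assert share == pytest.approx(0.25, abs=0.02)

    def test_single_sex_rejected(self):
        with pytest.raises(InvalidConfigError):
            quartile_by_sex(np.arange(8.0), np.zeros(8))

    def test_small_stratum_rejected(self):
        values = np.arange(8.0)
        sex = np.array([0, 0, 0, 0, 0, 1, 1, 1])
        with pytest.raises(InvalidConfigError):
            quartile_by_sex(values, sex)


class TestExposureOutcomeAssoc:
    def test_recovers_strong_effect(self, rng):
        n = 500
        e = rng.normal(size=n)
        age = rng.normal(50, 5, size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = 2.0 * e + 1e-8 * rng.normal(size=n)
        beta, se, p = exposure_outcome_assoc(y, e, age, sex)
        assert beta == pytest.approx(2.0, abs=1e-6)
        assert p < 1e-100

    def test_null_p_values_roughly_uniform(self, rng):
        pvals = []
        for _ in range(200):
            n = 100
            e = rng.normal(size=n)
            age = rng.normal(size=n)
            sex = rng.integers(0, 2, size=n).astype(float)
            y = rng.normal(size=n)
            _, _, p = exposure_outcome_assoc(y, e, age, sex)
            pvals.append(p)
        pvals = np.array(pvals)
        assert abs(np.mean(pvals) - 0.5) < 0.08
        assert np.mean(pvals < 0.05) < 0.12

    def test_collinear_design_rejected(self, rng):
        n = 50
        e = rng.normal(size=n)
        sex = rng.integers(0, 2, size=n).astype(float)
        y = rng.normal(size=n)
        with pytest.raises(RankDeficiencyError):
            exposure_outcome_assoc(y, e, e, sex)  # age duplicates exposure

    def test_too_few_observations_rejected(self):
        x = np.arange(4.0)
        with pytest.raises(DegenerateInputError):
            exposure_outcome_assoc(x, x + 1, x + 2, np.array([0, 1, 0, 1.0]))
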