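"""Variant QC and phenotype/exposure transforms applied before the scan.

Filters run in a fixed order (missingness -> MAF -> HWE) and each variant
is counted under the first filter it fails, so the QC report is
deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import chi2, rankdata, t as t_dist

from .errors import DegenerateInputError, DomainError, InvalidConfigError, RankDeficiencyError
from .types import GenotypeMatrix, VariantQCReport

__all__ = [
    "hwe_exact_pvalue",
    "hwe_chi2_pvalue",
    "variant_qc",
    "log_transform",
    "rank_int",
    "quartile_by_sex",
    "exposure_outcome_assoc",
]


def hwe_exact_pvalue(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy-Weinberg test p-value (mid-p off).

    Enumerates all heterozygote counts compatible with the observed
    allele counts and sums the probabilities of outcomes no more likely
    than the observed one.
    """
    if min(n_het, n_hom_rare, n_hom_common) < 0:
        raise DomainError("genotype counts must be non-negative")
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * n_hom_rare + n_het
    if 2 * n_hom_common + n_het < rare:  # ensure 'rare' really is the minor allele
        rare = 2 * n_hom_common + n_het
    # feasible het counts share the parity of the rare-allele count
    het_min = rare % 2
    het_max = min(rare, 2 * n - rare)
    hets = np.arange(het_min, het_max + 1, 2)
    # unnormalized probabilities via the standard recurrence:
    # P(h+2)/P(h) = 4*hom_r(h)*hom_c(h) / ((h+2)*(h+1))
    log_p = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i - 1]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        log_p[i] = log_p[i - 1] + np.log(4.0 * hom_r * hom_c) - np.log(
            (h + 2.0) * (h + 1.0)
        )
    p = np.exp(log_p - log_p.max())
    p /= p.sum()
    obs = np.searchsorted(hets, n_het)
    if obs >= len(hets) or hets[obs] != n_het:
        raise DomainError("observed heterozygote count incompatible with allele counts")
    # 1e-12 slack absorbs float round-off in the tie comparison
    return float(min(1.0, p[p <= p[obs] * (1 + 1e-12)].sum()))


def hwe_chi2_pvalue(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """1-df chi-square Hardy-Weinberg test (fast alternative)."""
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    p = (2 * n_hom_rare + n_het) / (2.0 * n)
    q = 1.0 - p
    exp = np.array([n * q * q, 2 * n * p * q, n * p * p])
    obs = np.array([n_hom_common, n_het, n_hom_rare])
    if np.any(exp == 0):
        return 1.0
    stat = np.sum((obs - exp) ** 2 / exp)
    return float(chi2.sf(stat, df=1))


def _hwe_pvalues(dosages: np.ndarray, method: str) -> np.ndarray:
    test = hwe_exact_pvalue if method == "exact" else hwe_chi2_pvalue
    m = dosages.shape[1]
    out = np.empty(m)
    for j in range(m):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        n_hom_a1 = int(np.sum(col == 2))
        n_het = int(np.sum(col == 1))
        n_hom_a2 = int(np.sum(col == 0))
        if n_hom_a1 + n_het + n_hom_a2 != col.size:
            raise DomainError(
                f"variant column {j} has non-integer dosages; HWE test needs hard calls"
            )
        if n_hom_a1 <= n_hom_a2:
            out[j] = test(n_het, n_hom_a1, n_hom_a2)
        else:
            out[j] = test(n_het, n_hom_a2, n_hom_a1)
    return out


def variant_qc(genotypes: GenotypeMatrix,
               miss_max: float = 0.05,
               maf_min: float = 0.05,
               hwe_p_min: float = 1e-6,
               hwe_method: str = "exact") -> tuple:
    """Remove variants failing missingness, MAF or HWE criteria.

    Thresholds follow the convention: remove when missing rate >
    ``miss_max``, MAF strictly below ``maf_min``, or HWE p strictly
    below ``hwe_p_min``. MAF is computed on non-missing calls. Returns
    the filtered matrix and a :class:`VariantQCReport`; an empty
    retained set is a valid result, not an error.
    """
    for name, val in (("miss_max", miss_max), ("maf_min", maf_min),
                      ("hwe_p_min", hwe_p_min)):
        if not (0.0 < val < 1.0):
            raise InvalidConfigError(f"{name} must be in (0, 1)")
    m = genotypes.n_variants
    miss = genotypes.missing_rate()
    fail_miss = miss > miss_max

    freq = genotypes.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    fail_maf = (maf < maf_min) & ~fail_miss

    survivors = ~(fail_miss | fail_maf)
    fail_hwe = np.zeros(m, dtype=bool)
    idx = np.where(survivors)[0]
    if idx.size:
        pvals = _hwe_pvalues(genotypes.dosages[:, idx], hwe_method)
        fail_hwe[idx] = pvals < hwe_p_min

    retained = ~(fail_miss | fail_maf | fail_hwe)
    report = VariantQCReport(
        n_input=m,
        n_removed_missingness=int(fail_miss.sum()),
        n_removed_maf=int(fail_maf.sum()),
        n_removed_hwe=int(fail_hwe.sum()),
        n_retained=int(retained.sum()),
        retained_ids=list(genotypes.variants.loc[retained, "snp"]),
    )
    return genotypes.subset_variants(np.where(retained)[0]), report


def log_transform(values: np.ndarray) -> np.ndarray:
    """Natural log, elementwise; missing (NaN) passes through."""
    values = np.asarray(values, dtype=np.float64)
    ok = ~np.isnan(values)
    bad = np.where(ok & (values <= 0))[0]
    if bad.size:
        raise DomainError(
            f"log_transform requires positive values; first offender at index {bad[0]}"
        )
    out = np.full_like(values, np.nan)
    out[ok] = np.log(values[ok])
    return out


def rank_int(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform (gaussianization).

    Ties get average ranks; probability points are ``(rank - 0.5) / n``
    over the ``n`` non-missing entries; missing stays missing.
    """
    values = np.asarray(values, dtype=np.float64)
    ok = ~np.isnan(values)
    x = values[ok]
    if np.unique(x).size < 2:
        raise DegenerateInputError("rank_int needs at least 2 distinct values")
    ranks = rankdata(x, method="average")
    out = np.full_like(values, np.nan)
    out[ok] = ndtri((ranks - 0.5) / x.size)
    return out


def quartile_by_sex(values: np.ndarray, sex: np.ndarray) -> np.ndarray:
    """Within-sex quartile labels 1-4, then pooled across sexes.

    Cut points are type-7 quantiles at 0.25/0.5/0.75 within each sex
    stratum; a value exactly on a cut point goes to the lower group
    (the "<= threshold" convention).
    """
    values = np.asarray(values, dtype=np.float64)
    sex = np.asarray(sex)
    strata = np.unique(sex[~pd.isna(sex)])
    if strata.size < 2:
        raise InvalidConfigError("both sexes must be present")
    labels = np.full(values.shape, -1, dtype=int)
    for s in strata:
        in_s = (sex == s) & ~np.isnan(values)
        if in_s.sum() < 4:
            raise InvalidConfigError(
                f"sex stratum {s!r} has fewer than 4 observations"
            )
        cuts = np.quantile(values[in_s], [0.25, 0.5, 0.75])  # type-7 default
        labels[in_s] = np.searchsorted(cuts, values[in_s], side="left") + 1
    return labels


def exposure_outcome_assoc(phenotype: np.ndarray,
                           exposure: np.ndarray,
                           age: np.ndarray,
                           sex: np.ndarray) -> tuple:
    """OLS of phenotype on [1, exposure, age, sex]; t test on exposure.

    Returns ``(beta, se, p)`` for the exposure coefficient; rows with any
    missing value are dropped.
    """
    cols = [np.asarray(v, dtype=np.float64) for v in (phenotype, exposure, age, sex)]
    ok = ~np.any([np.isnan(c) for c in cols], axis=0)
    y, e, a, s = (c[ok] for c in cols)
    n = y.size
    if n <= 4:
        raise DegenerateInputError("need more than 4 complete observations")
    X = np.column_stack([np.ones(n), e, a, s])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError("design matrix [1, exposure, age, sex] is rank deficient")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - X.shape[1]
    sigma2 = resid @ resid / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se = float(np.sqrt(sigma2 * xtx_inv[1, 1]))
    tstat = beta[1] / se
    p = float(2.0 * t_dist.sf(abs(tstat), df))
    return float(beta[1]), se, p


def rank_int_variable(var, tag: str = "rank_int"):
    """Apply :func:`rank_int` to a LifestyleVariable, recording provenance."""
    return var.with_transform(rank_int(var.raw), tag)
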