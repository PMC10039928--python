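"""Interaction-heritability estimation from chi-square summary statistics.

Two estimators are provided, both consuming the per-variant interaction
chi-squares and a per-variant LD score / tagging value:

* ``ldsc_fit`` — weighted least-squares regression of chi2 on LD scores,
  E[chi2_j] = intercept + (N * h2 / M) * l2_j, with iteratively updated
  heteroskedasticity weights and a delete-one-block jackknife for
  standard errors.

* ``sumher_fit`` — a likelihood-based tagging estimator: chi2_j is
  modelled as e_j * chi-square(1) with e_j = a + (N * h2 / M) * tau_j;
  (h2, a) maximize the summed log-likelihood. Under the equal-per-SNP
  (GCTA) model tau equals the LD score. A free intercept ``a`` is kept
  for comparability with the regression estimator.

Both report an unconstrained h2 (negatives allowed, flagged), a one-sided
normal p-value against h2 > 0, and jackknife SEs over contiguous,
position-ordered blocks.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    DomainError,
    UnidentifiableModelError,
)
from .types import HeritabilityEstimate

DEFAULT_N_BLOCKS = 200
MIN_SNPS = 50


def _prepare(sumstats: pd.DataFrame, scores: pd.DataFrame, value_col: str,
             chi2_col: str = "CHI2") -> pd.DataFrame:
    merged = sumstats.merge(scores[["SNP", value_col]], on="SNP", how="inner")
    merged = merged.dropna(subset=[chi2_col, value_col])
    merged = merged.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    if len(merged) < MIN_SNPS:
        raise DegenerateInputError(
            f"only {len(merged)} variants after joining sumstats with scores; "
            f"need at least {MIN_SNPS}"
        )
    return merged


def _make_blocks(m: int, n_blocks: int) -> list:
    if n_blocks > m:
        n_blocks = max(2, m // 2)
        warnings.warn(
            f"fewer variants than jackknife blocks; reducing to {n_blocks} blocks",
            stacklevel=3,
        )
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    return [np.arange(edges[b], edges[b + 1]) for b in range(n_blocks)]


def _jackknife_se(estimates: np.ndarray) -> float:
    b = estimates.shape[0]
    mean = estimates.mean()
    return float(np.sqrt((b - 1) / b * np.sum((estimates - mean) ** 2)))


def _one_sided_p(h2: float, se: float) -> float:
    if se == 0 or not np.isfinite(se):
        return 1.0 if h2 <= 0 else np.nextafter(0, 1)
    with np.errstate(over="ignore"):
        z = h2 / se
    return float(max(norm.sf(z), np.nextafter(0, 1)))


# ---------------------------------------------------------------------------
# LD-score regression


def _wls_line(x: np.ndarray, y: np.ndarray) -> tuple:
    """Two-pass weighted least squares with LDSC-style weights.

    Weights start at 1/max(l2, 1) and are updated once to
    1/[max(l2, 1) * 2 * fitted^2] using the first-pass fitted values.
    Returns (slope, intercept).
    """
    w = 1.0 / np.maximum(x, 1.0)

    def solve(wv: np.ndarray) -> tuple:
        sw = wv.sum()
        mx = (wv * x).sum() / sw
        my = (wv * y).sum() / sw
        sxx = (wv * (x - mx) ** 2).sum()
        if sxx <= 0:
            raise UnidentifiableModelError(
                "LD scores have zero weighted variance; slope not identifiable"
            )
        slope = (wv * (x - mx) * (y - my)).sum() / sxx
        return slope, my - slope * mx

    slope, intercept = solve(w)
    fitted = np.maximum(intercept + slope * x, 1e-6)
    w = 1.0 / (np.maximum(x, 1.0) * 2.0 * fitted**2)
    return solve(w)


def ldsc_fit(sumstats: pd.DataFrame,
             ldscores: pd.DataFrame,
             n_samples: int,
             n_blocks: int = DEFAULT_N_BLOCKS,
             gc_applied: bool = False) -> HeritabilityEstimate:
    """LD-score regression of interaction chi2 on LD scores.

    ``h2 = slope * M / N`` where M is the number of variants entering the
    regression. SEs for h2 and the intercept come from a delete-one-block
    jackknife over ``n_blocks`` contiguous position-ordered blocks.
    """
    data = _prepare(sumstats, ldscores, "L2")
    x = data["L2"].to_numpy(dtype=np.float64)
    y = data["CHI2"].to_numpy(dtype=np.float64)
    m = len(data)
    n = float(n_samples)
    blocks = _make_blocks(m, n_blocks)

    slope, intercept = _wls_line(x, y)
    h2 = slope * m / n

    h2_reps = np.empty(len(blocks))
    int_reps = np.empty(len(blocks))
    all_idx = np.arange(m)
    for b, blk in enumerate(blocks):
        keep = np.setdiff1d(all_idx, blk, assume_unique=True)
        s_b, i_b = _wls_line(x[keep], y[keep])
        h2_reps[b] = s_b * m / n  # M fixed at the full panel size
        int_reps[b] = i_b
    se = _jackknife_se(h2_reps)
    if se == 0:
        se = np.nextafter(0, 1)  # noiseless synthetic input; keep se > 0

    return HeritabilityEstimate(
        method="ldsc",
        h2_gxe=float(h2),
        se=se,
        p_value=_one_sided_p(h2, se),
        intercept=float(intercept),
        n_samples=int(n_samples),
        n_snps=m,
        n_blocks=len(blocks),
        gc_applied=gc_applied,
    )


# ---------------------------------------------------------------------------
# likelihood-based tagging estimator


def _sumher_nll(params: np.ndarray, tau: np.ndarray, chi2: np.ndarray,
                n_over_m: float) -> float:
    h2, a = params
    e = a + n_over_m * h2 * tau
    bad = e <= 1e-10
    if bad.any():
        # finite, increasing penalty keeps L-BFGS-B gradients usable
        return 1e10 * (1.0 + float(np.sum(1e-10 - e[bad])))
    return float(0.5 * np.sum(np.log(e) + chi2 / e))


def sumher_loglik(h2: float, a: float, tau: np.ndarray, chi2: np.ndarray,
                  n_samples: float, m: int) -> float:
    """Summed log-likelihood sum_j [-0.5 ln e_j - chi2_j / (2 e_j)]."""
    return -_sumher_nll(np.array([h2, a]), tau, chi2, n_samples / m)


def _sumher_mle(tau: np.ndarray, chi2: np.ndarray, n_over_m: float,
                x0: Sequence[float] = (0.0, 1.0)) -> tuple:
    res = minimize(
        _sumher_nll,
        x0=np.asarray(x0, dtype=np.float64),
        args=(tau, chi2, n_over_m),
        method="L-BFGS-B",
        bounds=[(-10.0, 10.0), (1e-8, 100.0)],
    )
    if not res.success and not np.isfinite(res.fun):
        raise ConvergenceError(
            f"tagging-likelihood optimizer failed: {res.message}",
            last_iterate=tuple(res.x),
        )
    # never report a fit worse than the null start
    if _sumher_nll(np.array([0.0, 1.0]), tau, chi2, n_over_m) < res.fun:
        return 0.0, 1.0, True
    boundary = bool(
        np.isclose(res.x[1], 1e-8) or np.isclose(abs(res.x[0]), 10.0)
        or np.isclose(res.x[1], 100.0)
    )
    return float(res.x[0]), float(res.x[1]), boundary


def sumher_fit(sumstats: pd.DataFrame,
               tagging: pd.DataFrame,
               n_samples: int,
               n_blocks: int = DEFAULT_N_BLOCKS,
               gc_applied: bool = False) -> HeritabilityEstimate:
    """Maximum-likelihood h2 under the scaled-chi-square tagging model."""
    data = _prepare(sumstats, tagging, "TAU")
    tau = data["TAU"].to_numpy(dtype=np.float64)
    y = data["CHI2"].to_numpy(dtype=np.float64)
    m = len(data)
    n_over_m = float(n_samples) / m
    blocks = _make_blocks(m, n_blocks)

    h2, a, boundary = _sumher_mle(tau, y, n_over_m)

    h2_reps = np.empty(len(blocks))
    all_idx = np.arange(m)
    for b, blk in enumerate(blocks):
        keep = np.setdiff1d(all_idx, blk, assume_unique=True)
        # warm start from the full fit; n_over_m kept at full-panel scale
        h2_b, _, _ = _sumher_mle(tau[keep], y[keep], n_over_m, x0=(h2, a))
        h2_reps[b] = h2_b
    se = _jackknife_se(h2_reps)
    if se == 0:
        se = np.nextafter(0, 1)

    return HeritabilityEstimate(
        method="sumher_gcta",
        h2_gxe=h2,
        se=se,
        p_value=_one_sided_p(h2, se),
        intercept=a,
        n_samples=int(n_samples),
        n_snps=m,
        n_blocks=len(blocks),
        gc_applied=gc_applied,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# combination and thresholds


def sum_heritabilities(estimates: Iterable[HeritabilityEstimate]) -> tuple:
    """Sum h2 across exposures; SE combined assuming independence.

    The independence assumption is a stated caveat: if the exposures are
    correlated the summed heritability overstates the joint contribution.
    """
    estimates = list(estimates)
    if not estimates:
        raise DegenerateInputError("need at least one estimate to sum")
    methods = {e.method for e in estimates}
    if len(methods) > 1:
        warnings.warn(f"summing estimates from mixed methods: {sorted(methods)}",
                      stacklevel=2)
    total = float(sum(e.h2_gxe for e in estimates))
    total_se = float(np.sqrt(sum(e.se**2 for e in estimates)))
    return total, total_se


def bonferroni_threshold(base_alpha: float, k_tests: int) -> float:
    """base_alpha / k. Comparisons should use the unrounded value."""
    if k_tests < 1:
        raise DomainError("k_tests must be >= 1")
    if not (0 < base_alpha <= 1):
        raise DomainError("base_alpha must be in (0, 1]")
    return base_alpha / k_tests


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return float(f"{x:.{digits}g}")


def estimates_to_frame(named: Iterable[tuple]) -> pd.DataFrame:
    """Report table: ``EXPOSURE N H2_PCT SE_PCT P INTERCEPT METHOD GC_APPLIED``."""
    rows = []
    for name, est in named:
        rows.append(
            {
                "EXPOSURE": name,
                "N": est.n_samples,
                "H2_PCT": 100.0 * est.h2_gxe,
                "SE_PCT": 100.0 * est.se,
                "P": est.p_value,
                "INTERCEPT": est.intercept,
                "METHOD": est.method,
                "GC_APPLIED": est.gc_applied,
            }
        )
    return pd.DataFrame(rows)
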