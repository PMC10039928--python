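"""Genomic-inflation diagnostics and genomic-control correction.

The inflation factor is the sample median of the per-variant chi-square
statistics divided by the constant 0.45656. That constant is used
verbatim by the procedure this implements; note it differs slightly from
the exact chi-square(1 df) median 0.4549364, so a perfectly null scan
yields lambda ~ 0.9965 rather than 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DomainError
from .types import InflationReport

#: Divisor applied to the median chi-square when estimating lambda.
GC_NULL_MEDIAN = 0.45656

#: LDSC-intercept threshold above which genomic control is applied.
INTERCEPT_THRESHOLD = 1.1


def gc_lambda(chi2: np.ndarray) -> float:
    """Median chi-square divided by 0.45656 (even length: mean of middle two)."""
    chi2 = np.asarray(chi2, dtype=np.float64)
    chi2 = chi2[~np.isnan(chi2)]
    if chi2.size == 0:
        raise DomainError("gc_lambda needs a non-empty chi-square vector")
    if np.any(chi2 < 0):
        raise DomainError("chi-square statistics must be non-negative")
    return float(np.median(chi2) / GC_NULL_MEDIAN)


def apply_gc(chi2: np.ndarray, lambda_gc: float) -> np.ndarray:
    """Divide every chi-square by lambda (elementwise)."""
    if not (lambda_gc > 0):
        raise DomainError("lambda must be positive")
    return np.asarray(chi2, dtype=np.float64) / lambda_gc


def gc_decision(ldsc_intercept: float) -> bool:
    """Apply genomic control iff the LDSC intercept is strictly above 1.1."""
    if not np.isfinite(ldsc_intercept):
        raise DomainError("intercept must be finite")
    return bool(ldsc_intercept > INTERCEPT_THRESHOLD)


def inflation_report(chi2: np.ndarray,
                     ldsc_intercept: float | None = None) -> InflationReport:
    lam = gc_lambda(chi2)
    rep = InflationReport(
        lambda_gc=lam,
        median_chi2=lam * GC_NULL_MEDIAN,
        ldsc_intercept=ldsc_intercept,
        gc_applied=False if ldsc_intercept is None else gc_decision(ldsc_intercept),
    )
    return rep


def qq_points(p_values: np.ndarray) -> pd.DataFrame:
    """Expected vs observed -log10 p pairs for a Q-Q plot.

    Observed p sorted ascending; expected quantile for rank i (1-based)
    is ``(i - 0.5) / m``.
    """
    p = np.asarray(p_values, dtype=np.float64)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise DomainError("qq_points needs at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        raise DomainError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    m = obs.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    return pd.DataFrame(
        {
            "EXPECTED_NEGLOG10P": -np.log10(expected),
            "OBSERVED_NEGLOG10P": -np.log10(obs),
        }
    )
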