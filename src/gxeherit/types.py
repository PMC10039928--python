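"""Core data containers shared across modules.

Genotype dosages are stored dense as float64 with NaN marking missing
calls; variant metadata travels alongside as a DataFrame so that every
downstream table (summary statistics, LD scores, clump reports) can be
joined on ``snp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidConfigError

VARIANT_COLUMNS = ("snp", "chrom", "bp", "a1", "a2")


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with per-variant metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` array of A1-allele counts in
        ``{0, 1, 2}``; ``NaN`` encodes a missing call.
    variants
        DataFrame with columns ``snp, chrom, bp, a1, a2`` (one row per
        dosage column, same order).
    sample_ids
        Optional sample identifiers; generated as ``S000001...`` if absent.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise InvalidConfigError("dosages must be a 2-D samples x variants array")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise InvalidConfigError(f"variant table missing columns: {missing}")
        if len(self.variants) != self.dosages.shape[1]:
            raise InvalidConfigError(
                f"variant table has {len(self.variants)} rows for "
                f"{self.dosages.shape[1]} dosage columns"
            )
        if self.sample_ids is None:
            self.sample_ids = np.array(
                [f"S{i + 1:06d}" for i in range(self.dosages.shape[0])]
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """A1 allele frequency per variant, computed on non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def subset_variants(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index],
            variants=self.variants.iloc[index].reset_index(drop=True),
            sample_ids=self.sample_ids,
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            dosages=self.dosages[index, :],
            variants=self.variants,
            sample_ids=self.sample_ids[index],
        )


@dataclass
class LifestyleVariable:
    """One exposure vector with kind tag and transform provenance.

    ``raw`` keeps the values as collected (NaN = missing); ``transformed``
    is what enters the interaction scan. Fresh instances start with
    ``transformed`` equal to ``raw`` and ``transform_tag='none'``.
    """

    name: str
    kind: str  # 'continuous' | 'ordinal' | 'binary'
    raw: np.ndarray
    transformed: Optional[np.ndarray] = None
    transform_tag: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "ordinal", "binary"):
            raise InvalidConfigError(f"unknown exposure kind {self.kind!r}")
        self.raw = np.asarray(self.raw, dtype=np.float64)
        if self.transformed is None:
            self.transformed = self.raw.copy()
        else:
            self.transformed = np.asarray(self.transformed, dtype=np.float64)
        raw_ok = ~np.isnan(self.raw)
        if np.any(raw_ok & np.isnan(self.transformed)):
            raise InvalidConfigError(
                "transformed must be defined wherever raw is non-missing"
            )

    @property
    def n(self) -> int:
        return self.raw.shape[0]

    def with_transform(self, values: np.ndarray, tag: str) -> "LifestyleVariable":
        return replace(self, transformed=np.asarray(values, dtype=np.float64),
                       transform_tag=tag)


@dataclass
class HeritabilityEstimate:
    """Summary-statistic interaction-heritability estimate.

    ``h2_gxe`` is the unconstrained proportion of phenotypic variance;
    negative values are allowed and flagged rather than truncated.
    """

    method: str  # 'ldsc' | 'sumher_gcta'
    h2_gxe: float
    se: float
    p_value: float
    intercept: float
    n_samples: int
    n_snps: int
    n_blocks: int
    gc_applied: bool = False
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.se <= 0 and np.isfinite(self.se):
            raise InvalidConfigError("se must be positive")

    @property
    def negative(self) -> bool:
        return self.h2_gxe < 0

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "h2_gxe": float(self.h2_gxe),
            "se": float(self.se),
            "p_value": float(self.p_value),
            "intercept": float(self.intercept),
            "n_samples": int(self.n_samples),
            "n_snps": int(self.n_snps),
            "n_blocks": int(self.n_blocks),
            "gc_applied": bool(self.gc_applied),
            "boundary": bool(self.boundary),
            "negative": bool(self.negative),
        }


@dataclass
class InflationReport:
    """Genomic-inflation diagnostics for one scan."""

    lambda_gc: float
    median_chi2: float
    ldsc_intercept: Optional[float] = None
    gc_applied: bool = False

    def to_dict(self) -> dict:
        return {
            "lambda_gc": float(self.lambda_gc),
            "median_chi2": float(self.median_chi2),
            "ldsc_intercept": (
                None if self.ldsc_intercept is None else float(self.ldsc_intercept)
            ),
            "gc_applied": bool(self.gc_applied),
        }


@dataclass
class VariantQCReport:
    """Per-filter removal counts; each variant counted once, in filter order."""

    n_input: int
    n_removed_missingness: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int
    retained_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_missingness + self.n_removed_maf + self.n_removed_hwe
        )
        if self.n_input - removed != self.n_retained:
            raise InvalidConfigError("QC report counts are inconsistent")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": [
                    "n_input",
                    "n_removed_missingness",
                    "n_removed_maf",
                    "n_removed_hwe",
                    "n_retained",
                ],
                "value": [
                    self.n_input,
                    self.n_removed_missingness,
                    self.n_removed_maf,
                    self.n_removed_hwe,
                    self.n_retained,
                ],
            }
        )
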