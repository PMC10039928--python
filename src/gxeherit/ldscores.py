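"""Per-variant LD scores and equal-weight (GCTA-model) tagging.

The LD score of variant j is the sum, over all variants k within a
physical window around j (including j itself), of the bias-adjusted
squared dosage correlation

    r2_adj = r2 - (1 - r2) / (n_panel - 2)

The self term contributes exactly 1. Under the equal-expected-
heritability-per-SNP (GCTA) model the tagging value of a variant equals
its LD score, so the tagging table is an identity view.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, DomainError
from .types import GenotypeMatrix

LDSCORE_COLUMNS = ["CHR", "SNP", "BP", "L2"]


def ld_score(panel: GenotypeMatrix, window_kb: float = 1000.0,
             chunk: int = 512,
             exclude_region: tuple | None = None) -> pd.DataFrame:
    """Windowed LD scores from a genotype reference panel.

    Positions must be sorted within each chromosome. Monomorphic panel
    variants get ``L2 = NaN`` (and contribute 0 to their neighbours).
    Missing dosages are mean-imputed before standardization.
    ``exclude_region`` is an optional ``(chrom, start_bp, end_bp)`` triple
    dropping a position range (e.g. an MHC-like block) from the panel
    entirely before scoring.
    """
    if exclude_region is not None:
        c, lo, hi = exclude_region
        v = panel.variants
        keep = ~((v["chrom"] == c) & (v["bp"] >= lo) & (v["bp"] <= hi))
        panel = panel.subset_variants(np.where(keep.to_numpy())[0])
    n = panel.n_samples
    if n < 3:
        raise DomainError("LD-score adjustment needs at least 3 panel samples")
    window_bp = float(window_kb) * 1000.0

    v = panel.variants
    bp = v["bp"].to_numpy(dtype=np.float64)
    chrom = v["chrom"].to_numpy()
    for c in np.unique(chrom):
        if not np.all(np.diff(bp[chrom == c]) >= 0):
            raise DomainError(f"positions not sorted on chromosome {c}")

    D = panel.dosages
    mean = np.nanmean(D, axis=0)
    Z = np.where(np.isnan(D), mean, D)
    sd = Z.std(axis=0)
    poly = sd > 0
    Z = Z - mean
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(poly, Z / np.where(poly, sd, 1.0), 0.0)

    m = panel.n_variants
    l2 = np.full(m, np.nan)
    adj = float(n - 2)
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        cbp = bp[idx]
        for start in range(0, idx.size, chunk):
            stop = min(start + chunk, idx.size)
            lo = np.searchsorted(cbp, cbp[start:stop] - window_bp, side="left")
            hi = np.searchsorted(cbp, cbp[start:stop] + window_bp, side="right")
            wlo, whi = lo.min(), hi.max()
            block = Z[:, idx[wlo:whi]]
            corr = (Z[:, idx[start:stop]].T @ block) / n
            r2 = corr**2
            r2_adj = r2 - (1.0 - r2) / adj
            for i in range(stop - start):
                j = idx[start + i]
                if not poly[j]:
                    continue
                sl = slice(lo[i] - wlo, hi[i] - wlo)
                terms = r2_adj[i, sl]
                # polymorphic neighbours only; self term pinned to exactly 1
                mask = poly[idx[wlo:whi]][sl]
                self_pos = (start + i) - (wlo + sl.start)
                total = terms[mask].sum() - terms[self_pos] + 1.0
                l2[j] = total

    return pd.DataFrame(
        {
            "CHR": chrom,
            "SNP": v["snp"].to_numpy(),
            "BP": v["bp"].to_numpy(),
            "L2": l2,
        }
    )


def ld_score_bruteforce(panel: GenotypeMatrix, window_kb: float = 1000.0) -> pd.DataFrame:
    """Direct double loop over variant pairs; validation oracle."""
    n = panel.n_samples
    if n < 3:
        raise DomainError("LD-score adjustment needs at least 3 panel samples")
    window_bp = float(window_kb) * 1000.0
    D = panel.dosages
    mean = np.nanmean(D, axis=0)
    X = np.where(np.isnan(D), mean, D)
    v = panel.variants
    bp = v["bp"].to_numpy(dtype=np.float64)
    chrom = v["chrom"].to_numpy()
    m = panel.n_variants
    l2 = np.full(m, np.nan)
    for j in range(m):
        if X[:, j].std() == 0:
            continue
        total = 1.0
        for k in range(m):
            if k == j or chrom[k] != chrom[j] or abs(bp[k] - bp[j]) > window_bp:
                continue
            if X[:, k].std() == 0:
                continue
            r = np.corrcoef(X[:, j], X[:, k])[0, 1]
            r2 = r * r
            total += r2 - (1.0 - r2) / (n - 2)
        l2[j] = total
    return pd.DataFrame({"CHR": chrom, "SNP": v["snp"].to_numpy(),
                         "BP": v["bp"].to_numpy(), "L2": l2})


def gcta_tagging(ldscores: pd.DataFrame) -> pd.DataFrame:
    """Tagging values under the equal-per-SNP model: tau_j = l2_j."""
    if len(ldscores) == 0:
        raise DegenerateInputError("empty LD-score table")
    return pd.DataFrame({"SNP": ldscores["SNP"].to_numpy(),
                         "TAU": ldscores["L2"].to_numpy(dtype=np.float64)})


def write_ldscores(table: pd.DataFrame, path) -> None:
    table[LDSCORE_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ldscores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    missing = [c for c in LDSCORE_COLUMNS if c not in df.columns]
    if missing:
        raise DomainError(f"LD-score file missing column(s): {missing}")
    return df[LDSCORE_COLUMNS]
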