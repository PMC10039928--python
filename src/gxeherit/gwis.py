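"""Per-variant interaction scan.

For each variant j the fitted model is

    phenotype ~ 1 + G_j + G_j*E + E + covariates

and the reported statistic is the interaction coefficient (its SE,
t = beta/SE with residual degrees of freedom, two-sided p from the t
distribution, and chi2 = t^2). The shared columns [1, E, covariates] are
residualized out once (Frisch-Waugh-Lovell), which reproduces the
full-design OLS coefficient, SE and p exactly as long as the residual df
of the full design is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .errors import DegenerateInputError, RankDeficiencyError, SumstatsParseError
from .types import GenotypeMatrix, LifestyleVariable

SUMSTATS_COLUMNS = [
    "SNP", "CHR", "BP", "A1", "A2", "N", "BETA_GXE", "SE", "T", "P", "CHI2", "STATUS",
]

_VAR_EPS = 1e-12


@dataclass
class GwisDesign:
    """Fixed column layout of the per-variant regression."""

    covariate_names: Sequence[str] = field(default_factory=list)

    @property
    def n_columns_base(self) -> int:
        # intercept + G + GxE + E + covariates
        return 4 + len(self.covariate_names)


def _two_column_stats(gr: np.ndarray, xr: np.ndarray, yr: np.ndarray,
                      df: int) -> tuple:
    """OLS of yr on [gr, xr] (already residualized); stats for the xr column."""
    a = gr @ gr
    b = gr @ xr
    c = xr @ xr
    det = a * c - b * b
    if a < _VAR_EPS or c < _VAR_EPS or det <= _VAR_EPS * a * c:
        return None
    t1 = gr @ yr
    t2 = xr @ yr
    beta_g = (c * t1 - b * t2) / det
    beta_x = (a * t2 - b * t1) / det
    rss = yr @ yr - beta_g * t1 - beta_x * t2
    sigma2 = max(rss, 0.0) / df
    se = np.sqrt(sigma2 * a / det)
    return beta_g, beta_x, se


def fit_interaction_scan(genotypes: GenotypeMatrix,
                         exposure: LifestyleVariable,
                         phenotype: np.ndarray,
                         covariates: Optional[np.ndarray] = None,
                         design: Optional[GwisDesign] = None) -> pd.DataFrame:
    """Scan every variant, returning a summary-statistics table.

    Rows with missing phenotype, exposure or covariate values are
    dropped globally; per-variant genotype missingness is handled as
    complete-case within each variant (``N`` reports the rows used).
    Monomorphic variants and zero-variance interaction columns get
    ``STATUS='degenerate'`` with statistics set to missing.
    """
    phenotype = np.asarray(phenotype, dtype=np.float64)
    e = exposure.transformed
    n_total = phenotype.shape[0]
    if genotypes.n_samples != n_total or e.shape[0] != n_total:
        raise DegenerateInputError("genotypes, exposure and phenotype sizes differ")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
    if design is None:
        ncov = 0 if covariates is None else covariates.shape[1]
        design = GwisDesign(covariate_names=[f"COV{i + 1}" for i in range(ncov)])

    keep = ~np.isnan(phenotype) & ~np.isnan(e)
    if covariates is not None:
        keep &= ~np.isnan(covariates).any(axis=1)
    y = phenotype[keep]
    ev = e[keep]
    G = genotypes.dosages[keep, :]
    shared_cols = [np.ones(keep.sum()), ev]
    if covariates is not None:
        shared_cols.extend(covariates[keep].T)
    S = np.column_stack(shared_cols)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise RankDeficiencyError(
            "shared design [1, E, covariates] is collinear; fix covariates first"
        )

    p_full = design.n_columns_base
    # hat-matrix-free residualizer for the complete-genotype fast path
    Q, _ = np.linalg.qr(S)

    def residualize_inplace(mat: np.ndarray, buf: np.ndarray) -> np.ndarray:
        # mat <- mat - Q (Q^T mat); buf reused to avoid fresh page-faulted allocs
        np.matmul(Q, Q.T @ mat, out=buf)
        mat -= buf
        return mat

    yr = y - Q @ (Q.T @ y)

    m = genotypes.n_variants
    out_beta = np.full(m, np.nan)
    out_se = np.full(m, np.nan)
    out_n = np.zeros(m, dtype=int)
    status = np.full(m, "ok", dtype=object)

    has_nan = np.isnan(G).any(axis=0)
    complete = np.where(~has_nan)[0]
    partial = np.where(has_nan)[0]

    if complete.size:
        # G is a private copy (boolean row indexing copies), safe to mutate
        Gc = G if complete.size == G.shape[1] else G[:, complete]
        raw_var = Gc.var(axis=0)
        GEc = Gc * ev[:, None]
        buf = np.empty_like(GEc)
        Gr = residualize_inplace(Gc, buf)
        XEr = residualize_inplace(GEc, buf)
        del buf
        df = y.size - p_full
        a = np.einsum("ij,ij->j", Gr, Gr)
        b = np.einsum("ij,ij->j", Gr, XEr)
        c = np.einsum("ij,ij->j", XEr, XEr)
        t1 = Gr.T @ yr
        t2 = XEr.T @ yr
        det = a * c - b * b
        bad = (raw_var < _VAR_EPS) | (a < _VAR_EPS) | (c < _VAR_EPS) | (
            det <= _VAR_EPS * np.maximum(a * c, _VAR_EPS)
        )
        good = ~bad
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_g = (c * t1 - b * t2) / det
            beta_x = (a * t2 - b * t1) / det
            rss = yr @ yr - beta_g * t1 - beta_x * t2
            sigma2 = np.maximum(rss, 0.0) / df
            se = np.sqrt(sigma2 * a / det)
        out_beta[complete[good]] = beta_x[good]
        out_se[complete[good]] = se[good]
        out_n[complete] = y.size
        status[complete[bad]] = "degenerate"
        out_n[complete[bad]] = y.size

    for j in partial:
        g = G[:, j]
        ok = ~np.isnan(g)
        n_used = int(ok.sum())
        out_n[j] = n_used
        df = n_used - p_full
        if df < 1 or np.var(g[ok]) < _VAR_EPS:
            status[j] = "degenerate"
            continue
        Sj = S[ok]
        Qj, _ = np.linalg.qr(Sj)
        yj = y[ok] - Qj @ (Qj.T @ y[ok])
        gj = g[ok] - Qj @ (Qj.T @ g[ok])
        xj = g[ok] * ev[ok]
        xj = xj - Qj @ (Qj.T @ xj)
        res = _two_column_stats(gj, xj, yj, df)
        if res is None:
            status[j] = "degenerate"
            continue
        out_beta[j] = res[1]
        out_se[j] = res[2]

    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = out_beta / out_se
    dfs = out_n - p_full
    pvals = np.full(m, np.nan)
    okstat = ~np.isnan(tstat)
    pvals[okstat] = 2.0 * t_dist.sf(np.abs(tstat[okstat]), dfs[okstat])
    # p is reported in (0, 1]; clip the underflow end only
    pvals[okstat] = np.clip(pvals[okstat], np.nextafter(0, 1), 1.0)

    v = genotypes.variants
    return pd.DataFrame(
        {
            "SNP": v["snp"].to_numpy(),
            "CHR": v["chrom"].to_numpy(),
            "BP": v["bp"].to_numpy(),
            "A1": v["a1"].to_numpy(),
            "A2": v["a2"].to_numpy(),
            "N": out_n,
            "BETA_GXE": out_beta,
            "SE": out_se,
            "T": tstat,
            "P": pvals,
            "CHI2": tstat**2,
            "STATUS": status,
        }
    )


def fit_interaction_full_ols(genotypes: GenotypeMatrix,
                             exposure: LifestyleVariable,
                             phenotype: np.ndarray,
                             covariates: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Reference implementation: explicit full-design OLS per variant.

    Slow; used to validate the residualized scan.
    """
    phenotype = np.asarray(phenotype, dtype=np.float64)
    e = exposure.transformed
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=np.float64)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
    keep = ~np.isnan(phenotype) & ~np.isnan(e)
    if covariates is not None:
        keep &= ~np.isnan(covariates).any(axis=1)
    y0 = phenotype[keep]
    e0 = e[keep]
    G0 = genotypes.dosages[keep, :]
    cov0 = None if covariates is None else covariates[keep]

    rows = []
    p_full = 4 + (0 if cov0 is None else cov0.shape[1])
    for j in range(genotypes.n_variants):
        g = G0[:, j]
        ok = ~np.isnan(g)
        y, ev, gv = y0[ok], e0[ok], g[ok]
        n_used = int(ok.sum())
        cols = [np.ones(n_used), gv, gv * ev, ev]
        if cov0 is not None:
            cols.extend(cov0[ok].T)
        X = np.column_stack(cols)
        df = n_used - p_full
        if df < 1 or np.linalg.matrix_rank(X) < X.shape[1]:
            rows.append((n_used, np.nan, np.nan, np.nan, np.nan, "degenerate"))
            continue
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sigma2 = resid @ resid / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * xtx_inv[2, 2])
        tt = beta[2] / se
        p = 2.0 * t_dist.sf(abs(tt), df)
        rows.append((n_used, beta[2], se, tt, max(p, np.nextafter(0, 1)), "ok"))

    v = genotypes.variants
    arr = pd.DataFrame(
        rows, columns=["N", "BETA_GXE", "SE", "T", "P", "STATUS"]
    )
    arr.insert(0, "A2", v["a2"].to_numpy())
    arr.insert(0, "A1", v["a1"].to_numpy())
    arr.insert(0, "BP", v["bp"].to_numpy())
    arr.insert(0, "CHR", v["chrom"].to_numpy())
    arr.insert(0, "SNP", v["snp"].to_numpy())
    arr["CHI2"] = arr["T"] ** 2
    return arr[SUMSTATS_COLUMNS]


def write_sumstats(results: pd.DataFrame, path) -> None:
    """Write the TSV sumstats dialect; missing statistics become ``NA``."""
    if len(results) == 0:
        raise SumstatsParseError("refusing to write an empty sumstats table")
    missing = [c for c in SUMSTATS_COLUMNS if c not in results.columns]
    if missing:
        raise SumstatsParseError(f"results table missing columns: {missing}")
    results[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsParseError(
            f"sumstats file {path} missing required column(s): {missing}"
        )
    if len(df) == 0:
        raise SumstatsParseError(f"sumstats file {path} has no rows")
    return df[SUMSTATS_COLUMNS]


def write_ldsc_z(results: pd.DataFrame, path) -> None:
    """LDSC-style ``SNP A1 A2 N Z`` export, Z = sign(beta) * sqrt(chi2)."""
    z = np.sign(results["BETA_GXE"]) * np.sqrt(results["CHI2"])
    pd.DataFrame(
        {
            "SNP": results["SNP"],
            "A1": results["A1"],
            "A2": results["A2"],
            "N": results["N"],
            "Z": z,
        }
    ).to_csv(path, sep="\t", index=False, na_rep="NA")
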