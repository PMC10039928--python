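"""Genotype-exposure-phenotype cohort simulation with known truth.

Genotypes are built from latent AR(1) Gaussian haplotypes so that
within-block linkage disequilibrium has a closed form, Hardy-Weinberg
equilibrium holds by construction, and no external reference panel is
needed. Phenotypes are assembled from additive, exposure-main-effect and
genotype-by-exposure components whose *realized* sample variances are
rescaled exactly to the configured fractions, which makes downstream
parameter-recovery tests sharp at small n.
"""

from __future__ import annotations

import json
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import InvalidConfigError
from .types import GenotypeMatrix, LifestyleVariable

_BP_SPACING = 1000  # fixed 1 kb spacing on one synthetic chromosome


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``exposure_kind`` is one of ``'continuous'``, ``'ordinal:<k>'`` or
    ``'binary:<prevalence>'``. ``within_block_rho`` is the AR(1)
    correlation of the latent haplotype Gaussians across adjacent
    variants inside a block.
    """

    n_samples: int
    n_variants: int
    block_size: int = 50
    within_block_rho: float = 0.0
    maf_range: tuple = (0.05, 0.5)
    h2_additive: float = 0.0
    h2_gxe: float = 0.0
    var_exposure_main: float = 0.0
    n_causal_additive: int = 0
    n_causal_gxe: int = 0
    exposure_kind: str = "continuous"
    n_covariates: int = 0
    noise_exposure_scale: float = 0.0  # >0 => heteroskedastic noise, inflates scan
    gxe_subset_of_additive: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_variants < 1:
            raise InvalidConfigError("n_samples and n_variants must be positive")
        if self.block_size < 1:
            raise InvalidConfigError("block_size must be positive")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise InvalidConfigError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for name in ("h2_additive", "h2_gxe", "var_exposure_main"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if self.h2_additive + self.h2_gxe + self.var_exposure_main >= 1.0:
            raise InvalidConfigError(
                "h2_additive + h2_gxe + var_exposure_main must be < 1"
            )
        if self.n_causal_additive > self.n_variants or self.n_causal_gxe > self.n_variants:
            raise InvalidConfigError("causal counts must not exceed n_variants")
        if self.noise_exposure_scale < 0:
            raise InvalidConfigError("noise_exposure_scale must be >= 0")
        parse_exposure_kind(self.exposure_kind)  # validates


def parse_exposure_kind(kind: str) -> tuple:
    """Split an exposure-kind string into ``(base, parameter)``."""
    if kind == "continuous":
        return ("continuous", None)
    m = re.fullmatch(r"ordinal:(\d+)", kind)
    if m:
        k = int(m.group(1))
        if k < 2:
            raise InvalidConfigError("ordinal exposure needs k >= 2 levels")
        return ("ordinal", k)
    m = re.fullmatch(r"binary:([0-9.eE+-]+)", kind)
    if m:
        p = float(m.group(1))
        if not (0.0 < p < 1.0):
            raise InvalidConfigError("binary prevalence must be in (0, 1)")
        return ("binary", p)
    raise InvalidConfigError(f"unknown exposure_kind {kind!r}")


@dataclass
class CohortTruth:
    """Generating-side record: causal indices, effects, realized fractions."""

    causal_additive: np.ndarray
    causal_gxe: np.ndarray
    beta_additive: np.ndarray
    beta_gxe: np.ndarray
    gamma_exposure: float
    realized_h2_additive: float
    realized_h2_gxe: float
    realized_var_exposure: float
    realized_var_noise: float

    def to_dict(self) -> dict:
        return {
            "causal_additive": [int(i) for i in self.causal_additive],
            "causal_gxe": [int(i) for i in self.causal_gxe],
            "beta_additive": [float(b) for b in self.beta_additive],
            "beta_gxe": [float(b) for b in self.beta_gxe],
            "gamma_exposure": float(self.gamma_exposure),
            "realized_h2_additive": float(self.realized_h2_additive),
            "realized_h2_gxe": float(self.realized_h2_gxe),
            "realized_var_exposure": float(self.realized_var_exposure),
            "realized_var_noise": float(self.realized_var_noise),
        }


@dataclass
class Cohort:
    genotypes: GenotypeMatrix
    exposure: LifestyleVariable
    covariates: Optional[np.ndarray]
    phenotype: np.ndarray
    truth: CohortTruth
    config: SimulationConfig = field(repr=False, default=None)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    # independent named streams off one master seed, so adding an operation
    # never perturbs the draws of another; crc32 is stable across processes
    key = zlib.crc32(stream.encode())
    seq = np.random.SeedSequence(config.seed, spawn_key=(key,))
    return np.random.default_rng(seq)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw an LD-structured dosage matrix.

    Per block, each sample carries two independent latent Gaussian
    haplotype processes with AR(1) correlation ``within_block_rho``
    across variants; the allele is present where the latent value falls
    below the normal quantile of the variant's MAF, and dosage is the
    haplotype sum. HWE holds by construction.
    """
    rng = _rng(config, "genotypes")
    n, m = config.n_samples, config.n_variants
    rho = config.within_block_rho
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=m)
    thresholds = norm.ppf(mafs)

    dosages = np.empty((n, m), dtype=np.float64)
    innov_scale = np.sqrt(1.0 - rho**2)
    for start in range(0, m, config.block_size):
        stop = min(start + config.block_size, m)
        width = stop - start
        z = rng.standard_normal((n, 2, width))
        if rho > 0:
            z[:, :, 1:] *= innov_scale
            for j in range(1, width):
                z[:, :, j] += rho * z[:, :, j - 1]
        hap = z < thresholds[start:stop]  # latent below quantile => allele present
        dosages[:, start:stop] = hap.sum(axis=1)

    variants = pd.DataFrame(
        {
            "snp": [f"snp{j + 1}" for j in range(m)],
            "chrom": np.ones(m, dtype=int),
            "bp": np.arange(1, m + 1, dtype=int) * _BP_SPACING,
            "a1": "A",
            "a2": "G",
        }
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)


def simulate_exposure(config: SimulationConfig,
                      missing_mask: Optional[np.ndarray] = None) -> LifestyleVariable:
    """Draw an exposure independent of genotypes.

    continuous -> standard normal; ordinal:k -> k equiprobable integer
    levels 0..k-1; binary:p -> Bernoulli(p). ``missing_mask`` (boolean)
    injects missingness after the draw.
    """
    rng = _rng(config, "exposure")
    base, param = parse_exposure_kind(config.exposure_kind)
    n = config.n_samples
    if base == "continuous":
        values = rng.standard_normal(n)
    elif base == "ordinal":
        values = rng.integers(0, param, size=n).astype(np.float64)
    else:
        values = (rng.random(n) < param).astype(np.float64)
    if missing_mask is not None:
        missing_mask = np.asarray(missing_mask, dtype=bool)
        if missing_mask.shape != (n,):
            raise InvalidConfigError("missing_mask must have shape (n_samples,)")
        values = values.copy()
        values[missing_mask] = np.nan
    return LifestyleVariable(name="exposure", kind=base, raw=values)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise InvalidConfigError("cannot standardize a constant vector")
    return (x - x.mean()) / sd


def _rescale_to_variance(u: np.ndarray, target: float) -> np.ndarray:
    """Scale u so its sample variance (ddof=0) equals target exactly."""
    if target == 0.0:
        return np.zeros_like(u)
    v = u.var()
    if v == 0:
        raise InvalidConfigError(
            "component has zero variance but a positive variance fraction was requested"
        )
    return u * np.sqrt(target / v)


def simulate_phenotype(genotypes: GenotypeMatrix,
                       exposure: LifestyleVariable,
                       config: SimulationConfig) -> Cohort:
    """Assemble the phenotype from additive, GxE and exposure components.

    Causal genotype columns and the exposure are standardized; raw
    per-variant effects are i.i.d. normal; each component vector is then
    rescaled so its realized sample variance equals the configured
    fraction exactly, and Gaussian noise fills the remainder.
    """
    if genotypes.n_samples != exposure.n:
        raise InvalidConfigError("genotypes and exposure row counts differ")
    rng = _rng(config, "phenotype")
    n, m = genotypes.n_samples, genotypes.n_variants

    causal_add = np.sort(rng.choice(m, size=config.n_causal_additive, replace=False))
    if config.gxe_subset_of_additive:
        if config.n_causal_gxe > config.n_causal_additive:
            raise InvalidConfigError(
                "gxe_subset_of_additive requires n_causal_gxe <= n_causal_additive"
            )
        causal_gxe = np.sort(rng.choice(causal_add, size=config.n_causal_gxe,
                                        replace=False))
    else:
        causal_gxe = np.sort(rng.choice(m, size=config.n_causal_gxe, replace=False))

    e_tilde = _standardize(exposure.raw)

    def component(indices: np.ndarray, interact: bool) -> tuple:
        if indices.size == 0:
            return np.zeros(n), np.zeros(0)
        g = genotypes.dosages[:, indices]
        g = (g - g.mean(axis=0)) / g.std(axis=0)
        if interact:
            g = g * e_tilde[:, None]
        beta = rng.standard_normal(indices.size)
        return g @ beta, beta

    u_add_raw, beta_add = component(causal_add, interact=False)
    u_gxe_raw, beta_gxe = component(causal_gxe, interact=True)

    if config.h2_additive > 0 and causal_add.size == 0:
        raise InvalidConfigError("h2_additive > 0 requires n_causal_additive > 0")
    if config.h2_gxe > 0 and causal_gxe.size == 0:
        raise InvalidConfigError("h2_gxe > 0 requires n_causal_gxe > 0")

    u_add = _rescale_to_variance(u_add_raw, config.h2_additive)
    u_gxe = _rescale_to_variance(u_gxe_raw, config.h2_gxe)
    if config.var_exposure_main > 0:
        u_env = _rescale_to_variance(e_tilde, config.var_exposure_main)
        gamma = np.sqrt(config.var_exposure_main)
    else:
        u_env = np.zeros(n)
        gamma = 0.0
    # record the effects actually applied, after exact rescaling
    if beta_add.size and u_add_raw.var() > 0 and config.h2_additive > 0:
        beta_add = beta_add * np.sqrt(config.h2_additive / u_add_raw.var())
    elif config.h2_additive == 0:
        beta_add = np.zeros_like(beta_add)
    if beta_gxe.size and u_gxe_raw.var() > 0 and config.h2_gxe > 0:
        beta_gxe = beta_gxe * np.sqrt(config.h2_gxe / u_gxe_raw.var())
    elif config.h2_gxe == 0:
        beta_gxe = np.zeros_like(beta_gxe)

    var_noise = 1.0 - (config.h2_additive + config.h2_gxe + config.var_exposure_main)
    eps = rng.standard_normal(n)
    if config.noise_exposure_scale > 0:
        eps = eps * np.sqrt(1.0 + config.noise_exposure_scale * e_tilde**2)
    eps = _rescale_to_variance(eps, var_noise)

    phenotype = u_add + u_gxe + u_env + eps

    covariates = None
    if config.n_covariates > 0:
        covariates = rng.standard_normal((n, config.n_covariates))

    truth = CohortTruth(
        causal_additive=causal_add,
        causal_gxe=causal_gxe,
        beta_additive=beta_add,
        beta_gxe=beta_gxe,
        gamma_exposure=gamma,
        realized_h2_additive=float(u_add.var()),
        realized_h2_gxe=float(u_gxe.var()),
        realized_var_exposure=float(u_env.var()),
        realized_var_noise=float(eps.var()),
    )
    return Cohort(genotypes=genotypes, exposure=exposure, covariates=covariates,
                  phenotype=phenotype, truth=truth, config=config)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Convenience: genotypes + exposure + phenotype in one call."""
    genotypes = simulate_genotypes(config)
    exposure = simulate_exposure(config)
    return simulate_phenotype(genotypes, exposure, config)


# ---------------------------------------------------------------------------
# on-disk formats


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Variant-metadata columns followed by one dosage column per sample."""
    df = genotypes.variants.copy()
    dose = pd.DataFrame(genotypes.dosages.T, columns=list(genotypes.sample_ids))
    pd.concat([df, dose], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    meta = df[list(("snp", "chrom", "bp", "a1", "a2"))]
    sample_cols = [c for c in df.columns if c not in meta.columns]
    return GenotypeMatrix(
        dosages=df[sample_cols].to_numpy(dtype=np.float64).T,
        variants=meta,
        sample_ids=np.array(sample_cols),
    )


def write_plink(genotypes: GenotypeMatrix, prefix) -> None:
    """Write PLINK 1 bed/bim/fam (SNP-major). A1 is the counted allele."""
    prefix = Path(prefix)
    n = genotypes.n_samples
    bim = genotypes.variants
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, v in bim.iterrows():
            fh.write(f"{v.chrom}\t{v.snp}\t0\t{v.bp}\t{v.a1}\t{v.a2}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid in genotypes.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")
    # 2-bit codes, dosage of A1: 0b00 -> 2 copies, 0b10 -> 1, 0b11 -> 0, 0b01 missing
    code = np.full(genotypes.dosages.shape, 0b01, dtype=np.uint8)
    d = genotypes.dosages
    code[d == 2] = 0b00
    code[d == 1] = 0b10
    code[d == 0] = 0b11
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        for j in range(genotypes.n_variants):
            col = np.zeros(n_bytes * 4, dtype=np.uint8)
            col[:n] = code[:, j]
            packed = (
                col[0::4] | (col[1::4] << 2) | (col[2::4] << 4) | (col[3::4] << 6)
            )
            fh.write(packed.tobytes())


def read_plink(prefix) -> GenotypeMatrix:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep="\t", header=None,
        names=["chrom", "snp", "cm", "bp", "a1", "a2"],
    )
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    n = len(fam)
    m = len(bim)
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "rb") as fh:
        magic = fh.read(3)
        if magic != bytes([0x6C, 0x1B, 0x01]):
            raise InvalidConfigError("not a SNP-major PLINK bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    raw = raw.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = raw & 0b11
    codes[:, 1::4] = (raw >> 2) & 0b11
    codes[:, 2::4] = (raw >> 4) & 0b11
    codes[:, 3::4] = (raw >> 6) & 0b11
    codes = codes[:, :n]
    dosages = np.empty((n, m), dtype=np.float64)
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages[:, :] = lut[codes].T
    variants = bim[["snp", "chrom", "bp", "a1", "a2"]]
    return GenotypeMatrix(dosages=dosages, variants=variants,
                          sample_ids=fam[1].astype(str).to_numpy())


def write_pheno_tsv(path, sample_ids: np.ndarray, columns: dict) -> None:
    """Phenotype/exposure/covariate table with header ``IID <name>...``."""
    df = pd.DataFrame({"IID": sample_ids})
    for name, values in columns.items():
        df[name] = values
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_pheno_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    if "IID" not in df.columns:
        raise InvalidConfigError("phenotype table must have an IID column")
    return df


def write_truth(truth: CohortTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)


def read_truth(path) -> CohortTruth:
    with open(path) as fh:
        d = json.load(fh)
    return CohortTruth(
        causal_additive=np.array(d["causal_additive"], dtype=int),
        causal_gxe=np.array(d["causal_gxe"], dtype=int),
        beta_additive=np.array(d["beta_additive"], dtype=float),
        beta_gxe=np.array(d["beta_gxe"], dtype=float),
        gamma_exposure=d["gamma_exposure"],
        realized_h2_additive=d["realized_h2_additive"],
        realized_h2_gxe=d["realized_h2_gxe"],
        realized_var_exposure=d["realized_var_exposure"],
        realized_var_noise=d["realized_var_noise"],
    )
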