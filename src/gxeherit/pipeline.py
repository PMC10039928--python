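"""End-to-end orchestration: simulate/ingest -> QC -> scan -> inflation
decision -> heritability -> clump -> report.

The stage order for genomic control follows the procedure: a preliminary
LD-score regression supplies the intercept; if it exceeds 1.1 the
chi-squares are divided by lambda and both heritability fits are re-run
on the corrected statistics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineStageError
from .gwis import fit_interaction_scan
from .heritability import bonferroni_threshold, ldsc_fit, sumher_fit
from .inflation import apply_gc, gc_decision, gc_lambda, qq_points
from .ldscores import gcta_tagging, ld_score
from .preprocess import variant_qc
from .synthetic_cohort import SimulationConfig, simulate_exposure, simulate_genotypes, simulate_phenotype
from .types import GenotypeMatrix, InflationReport

GENOME_WIDE_ALPHA = 5e-8
SUGGESTIVE_P = 5e-6
HERITABILITY_ALPHA = 0.05


@dataclass
class Clump:
    index_snp: str
    index_p: float
    chrom: int
    bp_span: tuple
    members: list  # list of (snp_id, r2_with_index)


@dataclass
class ClumpResult:
    clumps: List[Clump] = field(default_factory=list)

    @property
    def n_clumps(self) -> int:
        return len(self.clumps)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.clumps:
            rows.append(
                {
                    "INDEX_SNP": c.index_snp,
                    "INDEX_P": c.index_p,
                    "CHR": c.chrom,
                    "BP_START": c.bp_span[0],
                    "BP_END": c.bp_span[1],
                    "N_MEMBERS": len(c.members),
                    "MEMBERS": ",".join(s for s, _ in c.members) or ".",
                }
            )
        return pd.DataFrame(
            rows,
            columns=["INDEX_SNP", "INDEX_P", "CHR", "BP_START", "BP_END",
                     "N_MEMBERS", "MEMBERS"],
        )


def ld_clump(results: pd.DataFrame,
             panel: GenotypeMatrix,
             p1: float = SUGGESTIVE_P,
             p2: float = SUGGESTIVE_P,
             r2: float = 0.01,
             kb: float = 1000.0) -> ClumpResult:
    """Greedy LD clumping of a scan result.

    Sort by p ascending (ties broken by chromosome, then position); take
    the best unassigned variant with p <= p1 as an index; absorb every
    unassigned variant with p <= p2 within +-kb and squared dosage
    correlation >= r2; repeat until no index candidate remains.
    """
    snp_to_col = {s: j for j, s in enumerate(panel.variants["snp"])}
    usable = results.dropna(subset=["P"]).copy()
    usable = usable[usable["SNP"].isin(snp_to_col)]
    order = usable.sort_values(["P", "CHR", "BP"], kind="mergesort")

    D = panel.dosages
    assigned: set = set()
    clumps: List[Clump] = []
    candidates = order[order["P"] <= p2]
    cand_rows = list(candidates.itertuples(index=False))

    for row in cand_rows:
        if row.SNP in assigned or row.P > p1:
            continue
        gi = D[:, snp_to_col[row.SNP]]
        members = []
        lo_bp, hi_bp = row.BP, row.BP
        for other in cand_rows:
            if other.SNP in assigned or other.SNP == row.SNP:
                continue
            if other.CHR != row.CHR or abs(other.BP - row.BP) > kb * 1000.0:
                continue
            gk = D[:, snp_to_col[other.SNP]]
            ok = ~np.isnan(gi) & ~np.isnan(gk)
            if gi[ok].std() == 0 or gk[ok].std() == 0:
                continue
            r = np.corrcoef(gi[ok], gk[ok])[0, 1]
            if r * r >= r2:
                members.append((other.SNP, float(r * r)))
                assigned.add(other.SNP)
                lo_bp = min(lo_bp, other.BP)
                hi_bp = max(hi_bp, other.BP)
        assigned.add(row.SNP)
        clumps.append(
            Clump(index_snp=row.SNP, index_p=float(row.P), chrom=int(row.CHR),
                  bp_span=(int(lo_bp), int(hi_bp)), members=members)
        )
    return ClumpResult(clumps=clumps)


# ---------------------------------------------------------------------------
# full pipeline


def _config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: dict) -> dict:
    """Run the full synthetic analysis described by ``config``.

    Expected keys: ``seed``; ``simulate`` (SimulationConfig fields minus
    exposure-specific ones); ``exposures`` (list of dicts with ``name``,
    ``exposure_kind`` and optional per-exposure SimulationConfig
    overrides); optional ``qc``, ``ldscore``, ``heritability``, ``clump``
    sections. Returns a plain-dict report, every number reproducible
    from config + seed.
    """
    seed = int(config.get("seed", 0))
    sim_base = dict(config.get("simulate", {}))
    exposures = config.get("exposures", [{"name": "exposure", "exposure_kind": "continuous"}])
    qc_cfg = dict(config.get("qc", {}))
    ld_cfg = dict(config.get("ldscore", {}))
    h2_cfg = dict(config.get("heritability", {}))
    clump_cfg = dict(config.get("clump", {}))
    k = len(exposures)

    gw_threshold = bonferroni_threshold(GENOME_WIDE_ALPHA, k)
    h2_threshold = bonferroni_threshold(HERITABILITY_ALPHA, k)

    report = {
        "provenance": {
            "seed": seed,
            "config_hash": _config_hash(config),
            "version": __version__,
        },
        "thresholds": {
            "suggestive_p": SUGGESTIVE_P,
            "genome_wide_p": gw_threshold,
            "heritability_p": h2_threshold,
            "k_exposures": k,
        },
        "exposures": {},
    }

    for i, exp_cfg in enumerate(exposures):
        name = exp_cfg.get("name", f"exposure{i + 1}")
        sim_kwargs = {**sim_base,
                      **{kk: vv for kk, vv in exp_cfg.items() if kk != "name"}}
        sim_kwargs.setdefault("seed", seed)
        sim_kwargs["seed"] = int(sim_kwargs["seed"]) + i  # per-exposure stream
        sim = SimulationConfig(**sim_kwargs)
        try:
            genotypes = simulate_genotypes(sim)
            exposure = simulate_exposure(sim)
            cohort = simulate_phenotype(genotypes, exposure, sim)
        except Exception as err:  # pragma: no cover - defensive
            raise PipelineStageError("simulate", name, err) from err

        try:
            genotypes_qc, qc_report = variant_qc(cohort.genotypes, **qc_cfg)
        except Exception as err:
            raise PipelineStageError("qc", name, err) from err

        try:
            scan = fit_interaction_scan(
                genotypes_qc, cohort.exposure, cohort.phenotype, cohort.covariates
            )
        except Exception as err:
            raise PipelineStageError("gwis", name, err) from err

        try:
            scores = ld_score(genotypes_qc, **ld_cfg)
            tagging = gcta_tagging(scores)
        except Exception as err:
            raise PipelineStageError("ldscore", name, err) from err

        try:
            n_eff = int(scan["N"].max())
            prelim = ldsc_fit(scan, scores, n_eff, **h2_cfg)
            lam = gc_lambda(scan["CHI2"].to_numpy())
            do_gc = gc_decision(prelim.intercept)
            final_scan = scan
            if do_gc:
                final_scan = scan.copy()
                final_scan["CHI2"] = apply_gc(scan["CHI2"].to_numpy(), lam)
            ldsc_est = ldsc_fit(final_scan, scores, n_eff, gc_applied=do_gc, **h2_cfg)
            sumher_est = sumher_fit(final_scan, tagging, n_eff, gc_applied=do_gc,
                                    **h2_cfg)
            inflation = InflationReport(
                lambda_gc=lam,
                median_chi2=float(np.median(scan["CHI2"].dropna())),
                ldsc_intercept=prelim.intercept,
                gc_applied=do_gc,
            )
        except Exception as err:
            raise PipelineStageError("heritability", name, err) from err

        try:
            clumps = ld_clump(final_scan, genotypes_qc, **clump_cfg)
        except Exception as err:
            raise PipelineStageError("clump", name, err) from err

        report["exposures"][name] = {
            "qc": {
                "n_input": qc_report.n_input,
                "n_retained": qc_report.n_retained,
            },
            "inflation": inflation.to_dict(),
            "ldsc": ldsc_est.to_dict(),
            "sumher_gcta": sumher_est.to_dict(),
            "clumps": clumps.to_frame().to_dict(orient="list"),
            "truth": cohort.truth.to_dict(),
            "_scan": final_scan,  # stripped on serialization
        }

    return report


def serialize_report(report: dict, path) -> None:
    """Write the report as YAML, dropping in-memory tables."""
    slim = json.loads(json.dumps(_strip_tables(report), default=_jsonify))
    with open(path, "w") as fh:
        yaml.safe_dump(slim, fh, sort_keys=True)


def _strip_tables(report: dict) -> dict:
    out = {kk: vv for kk, vv in report.items() if kk != "exposures"}
    out["exposures"] = {}
    for name, section in report.get("exposures", {}).items():
        out["exposures"][name] = {kk: vv for kk, vv in section.items()
                                  if not kk.startswith("_")}
    return out


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")


def export_plot_data(report: dict, out_dir) -> dict:
    """Write Manhattan / QQ / heritability-bar tables per exposure.

    Returns the mapping of logical table name to file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    bar_rows = []
    for name, section in report.get("exposures", {}).items():
        scan = section.get("_scan")
        if scan is not None:
            manhattan = scan[["CHR", "BP", "P"]]
            mpath = out_dir / f"{name}.manhattan.tsv"
            manhattan.to_csv(mpath, sep="\t", index=False, na_rep="NA")
            written[f"{name}.manhattan"] = str(mpath)
            pvals = scan["P"].dropna().to_numpy()
            if pvals.size:
                qpath = out_dir / f"{name}.qq.tsv"
                qq_points(pvals).to_csv(qpath, sep="\t", index=False)
                written[f"{name}.qq"] = str(qpath)
        for method in ("ldsc", "sumher_gcta"):
            est = section[method]
            bar_rows.append(
                {
                    "EXPOSURE": name,
                    "METHOD": method,
                    "H2_PCT": 100.0 * est["h2_gxe"],
                    "NEGLOG10_P": -np.log10(max(est["p_value"], 1e-300)),
                }
            )
    if bar_rows:
        bpath = out_dir / "heritability_bars.tsv"
        pd.DataFrame(bar_rows).to_csv(bpath, sep="\t", index=False)
        written["heritability_bars"] = str(bpath)
    return written


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
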