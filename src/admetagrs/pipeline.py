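"""End-to-end MetaGRS pipeline on a synthetic study.

Orchestrates the full analysis the package implements: synthesize an
LD-blocked panel with K correlated base GWASs and a liability-threshold
cohort; run genotype and summary-statistics QC; clump and score each
trait at the 13 p-value thresholds; reduce to per-trait PCA-GRSs; train
the elastic-net MetaGRS on the training split; and evaluate reference /
AD-GRS / MetaGRS models with Cox and logistic regressions, overall and
stratified by APOE-e4 carriage, optionally with the APOE-like region
excluded from the AD score.

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate as ev
from .geno_io import GenotypeMatrix, SummaryStats
from .metagrs import DEFAULT_ALPHA_GRID, MetaGRSModel, compute_metagrs, fit_metagrs
from .pcagrs import PCAGRSModel, apply_pca_grs, fit_pca_grs
from .qc import QCReport, genotype_pca, harmonize, qc_cascade, sumstats_qc
from .scoring import THRESHOLDS, ThresholdGRSMatrix, compute_grs, ld_clump
from .synthdata import CohortPhenotypes, SimConfig, simulate_base_gwas, simulate_genotypes, simulate_target_cohort

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Everything the end-to-end run produced, for inspection and tests."""

    geno: GenotypeMatrix
    pheno_train: pd.DataFrame
    pheno_test: pd.DataFrame
    qc_reports: list[QCReport]
    sumstats: dict[str, SummaryStats]
    pca_models: dict[str, PCAGRSModel]
    pcagrs_train: pd.DataFrame
    pcagrs_test: pd.DataFrame
    meta_model: MetaGRSModel
    metagrs_test: np.ndarray
    ad_grs_test: np.ndarray
    evaluation: pd.DataFrame
    cox_results: dict[str, dict[str, ev.CoxResult | None]]
    logistic_results: dict[str, dict[str, ev.LogisticResult | None]]


def _attach_pcs(pheno: pd.DataFrame, geno: GenotypeMatrix, n_pcs: int = 5) -> pd.DataFrame:
    pcs = genotype_pca(geno, n_pcs=n_pcs)
    out = pheno.copy()
    for i in range(n_pcs):
        out[f"PC{i + 1}"] = pcs[:, i]
    return out


def _trait_scores(
    geno_train: GenotypeMatrix,
    geno_test: GenotypeMatrix,
    ss: SummaryStats,
    r2_max: float,
    window_kb: float,
    thresholds,
) -> tuple[PCAGRSModel, np.ndarray, np.ndarray, SummaryStats]:
    """Clump in the training panel, score both cohorts, fit/apply PCA-GRS."""
    clumped = ld_clump(geno_train, ss, r2_max=r2_max, window_kb=window_kb)
    grs_train = compute_grs(geno_train, clumped, thresholds=thresholds)
    grs_test = compute_grs(geno_test, clumped, thresholds=thresholds)
    model = fit_pca_grs(grs_train)
    return model, apply_pca_grs(model, grs_train), apply_pca_grs(model, grs_test), clumped


def run_pipeline(
    cfg: SimConfig,
    train_frac: float = 0.6,
    thresholds=THRESHOLDS,
    clump_r2: float = 0.1,
    clump_window_kb: float = 250.0,
    folds: int = 20,
    alpha_grid=DEFAULT_ALPHA_GRID,
    n_lambda: int = 10,
    apoe_covariates: bool = False,
    exclude_apoe_region: bool = False,
    n_pcs: int = 5,
) -> PipelineResult:
    """Run the complete synthetic study.

    The panel is simulated once and split into training and testing
    cohorts (the base GWASs share the panel; marginal effects still carry
    estimation noise at ``n_base``). ``exclude_apoe_region`` removes a
    window around the major locus from the AD summary statistics before
    scoring, mirroring the APOE-region sensitivity analysis.
    """
    # --- synthesize ---------------------------------------------------
    geno, arch = simulate_genotypes(cfg)
    sumstats_raw = simulate_base_gwas(geno, arch, cfg)
    cohort = simulate_target_cohort(geno, arch, cfg)

    geno = GenotypeMatrix(
        geno.dosages,
        geno.variants,
        geno.samples.merge(
            cohort.table[["sample_id", "status", "age", "event"]], on="sample_id"
        ),
    )

    # --- genotype QC ---------------------------------------------------
    geno_qc, qc_reports = qc_cascade(geno)
    pheno = cohort.table.merge(geno_qc.samples[["sample_id"]], on="sample_id")

    # --- sumstats QC + harmonization ----------------------------------
    sumstats: dict[str, SummaryStats] = {}
    for ss in sumstats_raw:
        ss1, _ = sumstats_qc(ss)
        ss2, _ = harmonize(geno_qc, ss1)
        sumstats[ss.trait] = ss2

    # --- train/test split ---------------------------------------------
    rng = np.random.default_rng(cfg.seed + 3)
    n = geno_qc.n_samples
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    idx_train, idx_test = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    g_train, g_test = geno_qc.subset_samples(idx_train), geno_qc.subset_samples(idx_test)
    ph_train = pheno.iloc[idx_train].reset_index(drop=True)
    ph_test = pheno.iloc[idx_test].reset_index(drop=True)
    ph_train = _attach_pcs(ph_train, g_train, n_pcs)
    ph_test = _attach_pcs(ph_test, g_test, n_pcs)

    # --- per-trait threshold scores and PCA-GRS ------------------------
    pca_models: dict[str, PCAGRSModel] = {}
    sc_train: dict[str, np.ndarray] = {}
    sc_test: dict[str, np.ndarray] = {}
    for trait, ss in sumstats.items():
        ss_used = ss
        if exclude_apoe_region and trait == "AD":
            major = geno.variants.iloc[arch.major_index]
            ss_used, _ = ev.exclude_region(
                ss, chrom=int(major["chrom"]),
                start=int(major["pos"]) - 250_000, end=int(major["pos"]) + 250_000,
            )
        model, s_tr, s_te, _ = _trait_scores(
            g_train, g_test, ss_used, clump_r2, clump_window_kb, thresholds
        )
        pca_models[trait] = model
        sc_train[trait], sc_test[trait] = s_tr, s_te
    pcagrs_train = pd.DataFrame(sc_train)
    pcagrs_test = pd.DataFrame(sc_test)

    # --- MetaGRS -------------------------------------------------------
    meta_model = fit_metagrs(
        pcagrs_train,
        ph_train,
        folds=folds,
        alpha_grid=alpha_grid,
        n_lambda=n_lambda,
        seed=cfg.seed,
        apoe_covariates=apoe_covariates,
    )
    metagrs_test = compute_metagrs(meta_model, pcagrs_test)
    ad_std = (pcagrs_test["AD"] - pcagrs_test["AD"].mean()) / pcagrs_test["AD"].std()
    ad_grs_test = ad_std.to_numpy()

    # --- evaluation ----------------------------------------------------
    cov = ["age", "sex"] + [f"PC{i + 1}" for i in range(n_pcs)]
    if apoe_covariates:
        cov = cov + ["e2_dosage", "e4_dosage"]
    e4 = ph_test["e4_dosage"]
    strata_masks = {
        "all": np.ones(len(ph_test), dtype=bool),
        "e4_carriers": ((e4 >= 1) & e4.notna()).to_numpy(),
        "e4_non_carriers": ((e4 == 0) & e4.notna()).to_numpy(),
    }
    scores = {"reference": None, "AD-GRS": ad_grs_test, "MetaGRS": metagrs_test}

    cox_results: dict[str, dict] = {}
    logistic_results: dict[str, dict] = {}
    for name, score in scores.items():
        cox_results[name] = {}
        logistic_results[name] = {}
        for stratum, mask in strata_masks.items():
            ph = ph_test[mask].reset_index(drop=True)
            if len(ph) == 0 or ph["event"].sum() == 0 or ph["status"].nunique() < 2:
                cox_results[name][stratum] = None
                logistic_results[name][stratum] = None
                continue
            s = None if score is None else score[mask]
            cox_results[name][stratum] = ev.fit_cox(s, ph, covariates=cov)
            logistic_results[name][stratum] = ev.fit_logistic_eval(s, ph, covariates=cov)

    evaluation = ev.compare_models(
        {
            name: {stratum: cox_results[name][stratum] for stratum in strata_masks}
            for name in scores
        }
    )
    return PipelineResult(
        geno=geno_qc,
        pheno_train=ph_train,
        pheno_test=ph_test,
        qc_reports=qc_reports,
        sumstats=sumstats,
        pca_models=pca_models,
        pcagrs_train=pcagrs_train,
        pcagrs_test=pcagrs_test,
        meta_model=meta_model,
        metagrs_test=metagrs_test,
        ad_grs_test=ad_grs_test,
        evaluation=evaluation,
        cox_results=cox_results,
        logistic_results=logistic_results,
    )
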