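"""Synthetic genotype / GWAS / cohort generator.

Emulates the statistical structure the MetaGRS analysis assumes: an
LD-blocked diploid genotype panel, K genetically correlated base GWASs
(marginal effect estimates with sampling noise), and a target cohort with
a liability-threshold binary disease carrying one major-effect two-allele
locus (APOE-like e4, plus a protective e2 allele kept in the sample table)
and a Weibull proportional-hazards age of onset with right censoring.

Genotypes come from a Gaussian copula: two latent haplotype chains per
sample, AR(1)-like within each LD block, dichotomized at the MAF quantile
and summed to a diploid dosage. Dichotomization attenuates correlation, so
the latent correlation of each adjacent pair is calibrated (bivariate-normal
orthant probability via Owen's T, vectorized bisection) to make the
*genotype* correlation hit ``ld_rho``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import owens_t

from .geno_io import GenotypeMatrix, SummaryStats

__all__ = [
    "SimConfig",
    "TrueArchitecture",
    "CohortPhenotypes",
    "simulate_genotypes",
    "simulate_architecture",
    "simulate_base_gwas",
    "simulate_target_cohort",
]

#: APOE-like haplotype allele frequencies (e2, e3, e4); European-like values
E2_FREQ = 0.08
E4_FREQ = 0.15


def _default_rg(k: int, off: float = 0.25) -> np.ndarray:
    rg = np.full((k, k), off)
    np.fill_diagonal(rg, 1.0)
    return rg


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults mirror a mid-sized AD case-control genotyping study fed by
    modern public GWAS: a few thousand target samples, tens of thousands
    of effective base-GWAS samples per trait, a polygenic liability with
    h2 = 0.4 on top of a strong APOE-like locus, and roughly balanced
    cases/controls (ascertained cohorts, not population prevalence).
    """

    n_target: int = 2000
    n_base: int = 50_000
    m_variants: int = 5000
    n_blocks: int = 100
    ld_rho: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    k_traits: int = 6
    h2: float = 0.4
    rg: np.ndarray | None = None
    prevalence: float = 0.5
    major_locus_effect: float = 0.5
    e2_effect: float | None = None  # default: -0.4 x major_locus_effect
    censor_rate: float = 0.3
    weibull_shape: float = 4.0
    hazard_per_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rg is None:
            self.rg = _default_rg(self.k_traits)
        if self.e2_effect is None:
            self.e2_effect = -0.4 * self.major_locus_effect
        self.rg = np.asarray(self.rg, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_target <= 0 or self.m_variants <= 0 or self.n_blocks <= 0:
            raise ValueError("n_target, m_variants and n_blocks must be positive")
        if self.m_variants < self.n_blocks:
            raise ValueError("m_variants must be >= n_blocks")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be a sub-interval of (0, 0.5]")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie strictly in (0, 1)")
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must lie in [0, 1)")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        rg = self.rg
        if rg.shape != (self.k_traits, self.k_traits):
            raise ValueError("rg must be k_traits x k_traits")
        if not np.allclose(rg, rg.T) or not np.allclose(np.diag(rg), 1.0):
            raise ValueError("rg must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(rg).min() < -1e-8:
            raise ValueError("rg must be positive semidefinite")


@dataclass
class TrueArchitecture:
    """Ground-truth genetic architecture behind a simulated panel.

    ``effects[j, k]`` is the causal liability effect of variant j on trait k
    on the standardized-genotype scale; the major (APOE-e4-like) locus effect
    is carried separately and applies to trait 0 ("AD") only.
    """

    effects: np.ndarray  # (m_variants, k_traits)
    major_index: int
    block_of: np.ndarray  # (m_variants,) block id per variant


@dataclass
class CohortPhenotypes:
    """Per-sample outcome table for the target cohort.

    ``status`` is case/control, ``age`` the age at onset (cases with event)
    or at last visit / censoring, ``event`` the onset-observed indicator;
    ``e2_dosage``/``e4_dosage`` are APOE-like allele counts; ``liability``
    and ``genetic_liability`` retain the ground truth for oracle checks.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _bvn_orthant(c1: np.ndarray, c2: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """P(Z1 < c1, Z2 < c2) for standard bivariate normals, vectorized.

    Uses the classical Owen's-T decomposition; valid for |rho| < 1.
    """
    c1 = np.asarray(c1, float)
    c2 = np.asarray(c2, float)
    rho = np.asarray(rho, float)
    eps = 1e-12
    denom = np.sqrt(np.clip(1.0 - rho**2, eps, None))
    # guard h=0: replace by tiny value with the sign convention handled below
    h = np.where(np.abs(c1) < eps, eps, c1)
    k = np.where(np.abs(c2) < eps, eps, c2)
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    beta = np.where((h * k > 0) | ((h * k == 0) & (h + k >= 0)), 0.0, 0.5)
    phi = stats.norm.cdf
    return 0.5 * (phi(h) + phi(k)) - owens_t(h, a_h) - owens_t(k, a_k) - beta


def _binary_corr(p1: np.ndarray, p2: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Correlation of 1{Z1<q(p1)}, 1{Z2<q(p2)} under latent correlation rho."""
    c1 = stats.norm.ppf(p1)
    c2 = stats.norm.ppf(p2)
    p11 = _bvn_orthant(c1, c2, rho)
    return (p11 - p1 * p2) / np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))


def _calibrate_latent_rho(p1: np.ndarray, p2: np.ndarray, target: float, iters: int = 40) -> np.ndarray:
    """Latent rho per pair so the dichotomized correlation hits ``target``.

    Monotone in rho, so a vectorized bisection on [0, 0.9995] suffices;
    pairs whose MAFs make the target unattainable are capped at the bound.
    """
    if target <= 0:
        return np.zeros_like(np.asarray(p1, float))
    lo = np.zeros_like(np.asarray(p1, float))
    hi = np.full_like(lo, 0.9995)
    if _binary_corr(p1, p2, hi).max() <= 0:  # pragma: no cover - defensive
        return hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        achieved = _binary_corr(p1, p2, mid)
        go_up = achieved < target
        lo = np.where(go_up, mid, lo)
        hi = np.where(go_up, hi, mid)
    return 0.5 * (lo + hi)


def _block_sizes(m: int, n_blocks: int) -> np.ndarray:
    base = m // n_blocks
    sizes = np.full(n_blocks, base)
    sizes[: m - base * n_blocks] += 1
    return sizes


def _variant_metadata(block_of: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """GRCh37-style coordinates: blocks spread over chr1..22, 5 kb spacing
    within a block and a 1 Mb gap between blocks on the same chromosome."""
    n_blocks = int(block_of.max()) + 1
    n_chrom = min(22, n_blocks)
    chrom_of_block = (np.arange(n_blocks) * n_chrom) // n_blocks + 1
    chrom = np.empty(block_of.size, int)
    pos = np.empty(block_of.size, int)
    next_pos = {c: 1_000_000 for c in range(1, n_chrom + 1)}
    for b in range(n_blocks):
        idx = np.flatnonzero(block_of == b)
        c = int(chrom_of_block[b])
        start = next_pos[c]
        chrom[idx] = c
        pos[idx] = start + 5_000 * np.arange(idx.size)
        next_pos[c] = start + 5_000 * idx.size + 1_000_000
    alleles = np.array(["A", "C", "G", "T"])
    a1 = rng.integers(0, 4, size=block_of.size)
    shift = rng.integers(1, 4, size=block_of.size)
    a2 = (a1 + shift) % 4
    return pd.DataFrame(
        {
            "snp": [f"rs{100000 + j}" for j in range(block_of.size)],
            "chrom": chrom,
            "pos": pos,
            "a1": alleles[a1],
            "a2": alleles[a2],
        }
    )


def _draw_mafs(cfg: SimConfig, block_of: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Block-level MAF with small within-block jitter.

    Similar MAFs within a block keep the target genotype correlation
    attainable (binary variables with very different margins cannot be
    highly correlated).
    """
    lo, hi = cfg.maf_range
    n_blocks = int(block_of.max()) + 1
    block_maf = rng.uniform(lo, hi, size=n_blocks)
    jitter = 1.0 + rng.uniform(-0.15, 0.15, size=block_of.size)
    return np.clip(block_maf[block_of] * jitter, lo, hi)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, TrueArchitecture]:
    """Simulate the diploid panel and its true genetic architecture.

    Returns the panel (with APOE-like e4 dosages already substituted at the
    major locus) and the :class:`TrueArchitecture` used by the GWAS and
    cohort generators. Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    m, n = cfg.m_variants, cfg.n_target

    sizes = _block_sizes(m, cfg.n_blocks)
    block_of = np.repeat(np.arange(cfg.n_blocks), sizes)
    mafs = _draw_mafs(cfg, block_of, rng)

    # pair-calibrated latent AR(1) chain, restarted at block boundaries
    new_block = np.empty(m, bool)
    new_block[0] = True
    new_block[1:] = block_of[1:] != block_of[:-1]
    rho_pair = np.zeros(m)
    inside = ~new_block
    if inside.any() and cfg.ld_rho > 0:
        j = np.flatnonzero(inside)
        rho_pair[j] = _calibrate_latent_rho(mafs[j - 1], mafs[j], cfg.ld_rho)

    def latent_chain() -> np.ndarray:
        z = np.empty((n, m))
        innov = rng.standard_normal((n, m))
        z[:, 0] = innov[:, 0]
        for j in range(1, m):
            if new_block[j]:
                z[:, j] = innov[:, j]
            else:
                r = rho_pair[j]
                z[:, j] = r * z[:, j - 1] + np.sqrt(1 - r * r) * innov[:, j]
        return z

    thresh = stats.norm.ppf(mafs)
    hap1 = latent_chain() < thresh
    hap2 = latent_chain() < thresh
    dosages = (hap1.astype(float) + hap2.astype(float))

    variants = _variant_metadata(block_of, rng)

    # the APOE-like major locus: middle variant of the last block on the
    # "chr19-analogue" (or the global middle if few blocks); its panel
    # column is replaced by e4 allele counts drawn from a 3-allele model
    major_index = _pick_major_index(variants)
    e2, e4 = _draw_apoe(n, rng)
    dosages[:, major_index] = e4
    variants.loc[major_index, "snp"] = "rs_apoe_e4"

    samples = pd.DataFrame(
        {"sample_id": [f"S{i:05d}" for i in range(n)], "sex": rng.integers(1, 3, size=n)}
    )
    samples["e2_dosage"] = e2
    samples["e4_dosage"] = e4

    effects = _draw_effects(cfg, rng)
    effects[major_index, :] = 0.0  # the major locus acts through major_locus_effect
    arch = TrueArchitecture(effects=effects, major_index=major_index, block_of=block_of)
    return GenotypeMatrix(dosages, variants, samples), arch


def _pick_major_index(variants: pd.DataFrame) -> int:
    chroms = variants["chrom"].to_numpy()
    target_chrom = 19 if (chroms == 19).any() else chroms[len(chroms) // 2]
    idx = np.flatnonzero(chroms == target_chrom)
    return int(idx[idx.size // 2])


def _draw_apoe(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Two APOE haplotypes per sample from allele frequencies (e2, e3, e4)."""
    probs = [E2_FREQ, 1.0 - E2_FREQ - E4_FREQ, E4_FREQ]
    haps = rng.choice(3, size=(n, 2), p=probs)
    e2 = (haps == 0).sum(axis=1)
    e4 = (haps == 2).sum(axis=1)
    return e2, e4


def _draw_effects(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-variant causal effects, MVN across traits with covariance
    h2/m * rg, on the standardized-genotype scale (infinitesimal model)."""
    if cfg.h2 == 0:
        return np.zeros((cfg.m_variants, cfg.k_traits))
    cov = cfg.rg * (cfg.h2 / cfg.m_variants)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(cfg.k_traits))
    return rng.standard_normal((cfg.m_variants, cfg.k_traits)) @ chol.T


# ---------------------------------------------------------------------------
# base GWAS
# ---------------------------------------------------------------------------


def simulate_base_gwas(
    geno: GenotypeMatrix,
    arch: TrueArchitecture,
    cfg: SimConfig,
    seed: int | None = None,
) -> list[SummaryStats]:
    """Marginal GWAS summary statistics for each of the ``k_traits`` traits.

    The true *marginal* per-allele effect at SNP j folds in LD with its
    block neighbours (``beta_marg = (R @ u) / sd_j`` with u the causal
    effects on the standardized scale), so clumping has realistic leakage
    to work against. Estimates add sampling noise with the standard
    standardized-trait approximation ``se = 1/sqrt(2 n_base maf (1-maf))``
    and carry two-sided Wald p-values.
    """
    if cfg.n_base <= 0:
        raise ValueError("n_base must be positive")
    if arch.effects.shape != (geno.n_variants, cfg.k_traits):
        raise ValueError("architecture does not match the genotype panel")
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)

    X = geno.dosages
    freqs = geno.allele_freq()
    sd = np.sqrt(np.maximum(2 * freqs * (1 - freqs), 1e-12))
    se = 1.0 / np.sqrt(2 * cfg.n_base * np.maximum(freqs * (1 - freqs), 1e-12))

    # true effects incl. the major locus (trait 0, standardized scale)
    u = arch.effects.copy()
    u[arch.major_index, 0] += cfg.major_locus_effect * sd[arch.major_index]

    # blockwise marginal effects: R (empirical, within-block) @ u
    Z = (X - 2 * freqs) / sd
    beta_marg_std = np.empty_like(u)
    for b in np.unique(arch.block_of):
        idx = np.flatnonzero(arch.block_of == b)
        R = np.corrcoef(Z[:, idx], rowvar=False)
        R = np.atleast_2d(R)
        beta_marg_std[idx] = R @ u[idx]
    beta_marg = beta_marg_std / sd[:, None]

    out: list[SummaryStats] = []
    for k in range(cfg.k_traits):
        beta_hat = beta_marg[:, k] + rng.standard_normal(geno.n_variants) * se
        z = beta_hat / se
        p = np.clip(2 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny, 1.0)
        tbl = pd.DataFrame(
            {
                "SNP": geno.variants["snp"],
                "CHR": geno.variants["chrom"],
                "BP": geno.variants["pos"],
                "A1": geno.variants["a1"],
                "A2": geno.variants["a2"],
                "BETA": beta_hat,
                "SE": se,
                "P": p,
                "EAF": freqs,
            }
        )
        trait = "AD" if k == 0 else f"trait{k}"
        out.append(SummaryStats(tbl, trait=trait))
    return out


# ---------------------------------------------------------------------------
# target cohort
# ---------------------------------------------------------------------------


def simulate_target_cohort(
    geno: GenotypeMatrix,
    arch: TrueArchitecture,
    cfg: SimConfig,
    seed: int | None = None,
) -> CohortPhenotypes:
    """Liability-threshold disease with Weibull-PH age of onset.

    Liability = polygenic genetic value (trait 0) + APOE-like e4/e2 shifts
    + Gaussian noise scaled so the *polygenic* heritability is ``h2``.
    Case status thresholds the liability at the (1 - prevalence) empirical
    quantile. The onset hazard's linear predictor is proportional to the
    *genetic* liability (``hazard_per_sd`` per SD), so a cohort with no
    genetic signal has no onset signal. Controls carry their age at last
    visit and censored cases an age uniformly before onset.
    """
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    n = geno.n_samples
    X = geno.dosages
    freqs = geno.allele_freq()
    sd = np.sqrt(np.maximum(2 * freqs * (1 - freqs), 1e-12))
    Z = (X - 2 * freqs) / sd

    g_poly = Z @ arch.effects[:, 0]
    e2 = geno.samples["e2_dosage"].to_numpy()
    e4 = geno.samples["e4_dosage"].to_numpy()
    g = g_poly + cfg.major_locus_effect * e4 + cfg.e2_effect * e2

    var_poly = float(np.var(g_poly))
    if cfg.h2 > 0 and var_poly > 0:
        var_eps = var_poly * (1 - cfg.h2) / cfg.h2
    else:
        var_eps = 1.0
    liability = g + rng.standard_normal(n) * np.sqrt(var_eps)

    cut = np.quantile(liability, 1 - cfg.prevalence)
    status = (liability > cut).astype(int)

    g_sd = g.std()
    eta = cfg.hazard_per_sd * (g - g.mean()) / g_sd if g_sd > 0 else np.zeros(n)

    # Weibull PH onset mapped onto an age-like scale: baseline scale chosen
    # so the median onset sits near 75 years at eta = 0
    shape = cfg.weibull_shape
    u_draw = rng.uniform(size=n)
    base_scale = 75.0 / np.log(2) ** (1 / shape)
    onset = base_scale * (-np.log(u_draw) / np.exp(eta)) ** (1 / shape)
    onset = np.clip(onset, 40.0, 105.0)

    censored = rng.uniform(size=n) < cfg.censor_rate
    event = (status == 1) & ~censored
    age = np.where(
        status == 1,
        np.where(event, onset, onset * rng.uniform(0.7, 1.0, size=n)),
        np.clip(rng.normal(75.0, 8.0, size=n), 40.0, 105.0),
    )

    table = pd.DataFrame(
        {
            "sample_id": geno.samples["sample_id"].to_numpy(),
            "status": status,
            "age": age,
            "event": event.astype(int),
            "sex": geno.samples["sex"].to_numpy(),
            "e2_dosage": e2,
            "e4_dosage": e4,
            "liability": liability,
            "genetic_liability": g,
        }
    )
    return CohortPhenotypes(table)
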