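"""Quality-control cascade for genotypes and GWAS summary statistics.

Variant filters (MAF, Hardy-Weinberg exact test, missingness), sample
filters (call rate, heterozygosity outliers), method-of-moments
relatedness pruning, allele harmonization between a genotype panel and
summary statistics, summary-statistics hygiene (frequency, indels,
duplicates, strand-ambiguous SNPs), and genotype principal components
for population structure. Every step returns a :class:`QCReport`
recording what was removed and why, in application order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix, SummaryStats

__all__ = [
    "QCReport",
    "variant_qc",
    "hwe_exact",
    "sample_qc",
    "relatedness_filter",
    "harmonize",
    "sumstats_qc",
    "genotype_pca",
    "qc_cascade",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class QCReport:
    """Ordered record of a QC step: per-filter removal counts + parameters."""

    step: str
    removed: dict[str, int] = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    n_in: int = 0
    n_out: int = 0

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "removed": dict(self.removed),
            "params": dict(self.params),
            "n_in": self.n_in,
            "n_out": self.n_out,
        }

    def check(self) -> None:
        if sum(self.removed.values()) != self.n_in - self.n_out:
            raise AssertionError(f"QC bookkeeping broken in step {self.step!r}")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test (Wigginton et al. style).

    Conditional on the allele counts, sums the probabilities of all
    heterozygote counts (of the right parity) no more probable than the
    observed one. Plain exact test, no mid-p, matching PLINK defaults.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("at least one sample required")

    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # possible het counts share the parity of the rare-allele count
    het_min = n_rare % 2
    het_max = min(n_rare, 2 * n - n_rare)

    # recurrence on unnormalized probabilities, anchored at the mode
    hets = np.arange(het_min, het_max + 1, 2)
    probs = np.empty(hets.size)
    probs[0] = 1.0
    for i in range(1, hets.size):
        h = hets[i]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        # P(h) / P(h-2) = 4 * rh(h-2) * ch(h-2) / (h * (h-1))
        probs[i] = probs[i - 1] * 4.0 * (rare_hom + 1) * (common_hom + 1) / (h * (h - 1.0))
        if probs[i] > 1e250:  # renormalize on the fly to avoid overflow
            probs[: i + 1] /= probs[i]
    probs /= probs.sum()

    obs = int(np.flatnonzero(hets == n_Aa)[0]) if n_Aa in hets else None
    if obs is None:
        raise ValueError("heterozygote count inconsistent with allele-count parity")
    p_obs = probs[obs]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_pvalues(dosages: np.ndarray, restrict: np.ndarray | None = None) -> np.ndarray:
    X = dosages if restrict is None else dosages[restrict]
    m = X.shape[1]
    out = np.ones(m)
    for j in range(m):
        col = X[:, j]
        col = col[np.isfinite(col)]
        if col.size == 0:
            continue
        n_aa = int((col == 2).sum())  # A1 hom
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 0).sum())
        out[j] = hwe_exact(n_AA, n_Aa, n_aa)
    return out


# ---------------------------------------------------------------------------
# variant and sample filters
# ---------------------------------------------------------------------------


def variant_qc(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-6,
    miss_max: float = 0.05,
    hwe_controls_only: bool = True,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop variants failing MAF, missingness or the HWE exact test.

    Filters attribute each removal to the first rule that fires, in the
    order missingness -> MAF -> HWE. HWE is evaluated in controls only
    when a case/control ``status`` column is present (standard practice,
    configurable), otherwise in all samples.
    """
    X = geno.dosages
    n, m = X.shape
    miss_frac = np.isnan(X).mean(axis=0)
    freq = geno.allele_freq()
    maf = np.minimum(freq, 1 - freq)

    restrict = None
    if hwe_controls_only and "status" in geno.samples.columns:
        ctrl = geno.samples["status"].to_numpy() == 0
        if ctrl.sum() >= 3:
            restrict = ctrl
    hwe_p = _hwe_pvalues(X, restrict)

    fail_miss = miss_frac > miss_max
    fail_maf = ~fail_miss & (maf < maf_min)
    fail_hwe = ~fail_miss & ~fail_maf & (hwe_p < hwe_alpha)
    keep = ~(fail_miss | fail_maf | fail_hwe)
    if not keep.any():
        raise ValueError("variant QC removed every variant (empty panel)")

    report = QCReport(
        step="variant_qc",
        removed={
            "missing": int(fail_miss.sum()),
            "maf": int(fail_maf.sum()),
            "hwe": int(fail_hwe.sum()),
        },
        params={
            "maf_min": maf_min,
            "hwe_alpha": hwe_alpha,
            "miss_max": miss_max,
            "hwe_controls_only": restrict is not None,
        },
        n_in=m,
        n_out=int(keep.sum()),
    )
    report.check()
    return geno.subset_variants(keep), report


def sample_qc(
    geno: GenotypeMatrix,
    miss_max: float = 0.01,
    het_sd: float = 3.0,
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop samples with low call rate, then heterozygosity outliers.

    Heterozygosity rate = fraction of non-missing calls that are
    heterozygous; outliers deviate more than ``het_sd`` SDs from the
    post-call-rate-filter mean. A zero SD (e.g. identical samples) means
    no outliers.
    """
    X = geno.dosages
    n = X.shape[0]
    called = np.isfinite(X)
    call_rate = called.mean(axis=1)
    fail_miss = call_rate < 1 - miss_max

    keep1 = ~fail_miss
    het_rate = np.where(
        called[keep1].sum(axis=1) > 0,
        (X[keep1] == 1).sum(axis=1) / np.maximum(called[keep1].sum(axis=1), 1),
        0.0,
    )
    mu, sd = het_rate.mean(), het_rate.std()
    fail_het = np.zeros(n, bool)
    if sd > 0:
        fail_het[np.flatnonzero(keep1)] = np.abs(het_rate - mu) > het_sd * sd

    keep = keep1 & ~fail_het
    if keep.sum() < 3:
        raise ValueError("fewer than 3 samples survive sample QC")
    report = QCReport(
        step="sample_qc",
        removed={"call_rate": int(fail_miss.sum()), "heterozygosity": int(fail_het.sum())},
        params={"miss_max": miss_max, "het_sd": het_sd},
        n_in=n,
        n_out=int(keep.sum()),
    )
    report.check()
    return geno.subset_samples(keep), report


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------


def ld_thin(geno: GenotypeMatrix, r2_max: float = 0.2, window: int = 50) -> np.ndarray:
    """Indices of an LD-thinned variant subset (greedy, left to right)."""
    X = geno.dosages
    freq = geno.allele_freq()
    Xi = np.where(np.isnan(X), 2 * freq, X)
    sd = Xi.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(Xi)
    Z[:, ok] = (Xi[:, ok] - Xi[:, ok].mean(axis=0)) / sd[ok]
    kept: list[int] = []
    for j in np.flatnonzero(ok):
        recent = [k for k in kept[-window:]]
        if recent:
            r = Z[:, recent].T @ Z[:, j] / X.shape[0]
            if (r**2 > r2_max).any():
                continue
        kept.append(j)
    return np.asarray(kept, dtype=int)


def pi_hat(geno: GenotypeMatrix, variant_idx: np.ndarray | None = None) -> np.ndarray:
    """Pairwise relatedness via the standardized-genotype moment estimator.

    Returns the genetic relationship matrix G with G_ik = mean_j z_ij z_kj
    over polymorphic variants; the off-diagonal estimates twice the kinship
    coefficient, i.e. the PI-HAT scale (1 for duplicates/MZ twins, 0.5 for
    parent-offspring, ~0 for unrelateds). Missing dosages are mean-imputed.
    """
    X = geno.dosages if variant_idx is None else geno.dosages[:, variant_idx]
    freq = np.nanmean(X, axis=0) / 2
    ok = (freq > 0) & (freq < 1)
    X = X[:, ok]
    freq = freq[ok]
    sd = np.sqrt(2 * freq * (1 - freq))
    Z = (np.where(np.isnan(X), 2 * freq, X) - 2 * freq) / sd
    m = Z.shape[1]
    grm = Z @ Z.T / m
    return grm  # diagonal ~ 1 + F; off-diagonal ~ 2*kinship = PI-HAT


def relatedness_filter(
    geno: GenotypeMatrix,
    kin_max: float = 0.125,
    thin_r2: float = 0.2,
    fwer: float = 0.05,
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove one member of each pair with estimated relatedness > kin_max.

    Relatedness is the moment-estimator PI-HAT on an LD-thinned subset;
    for a flagged pair the member with the lower call rate goes (ties:
    the later sample in input order).

    The estimator's sampling noise scales as 1/sqrt(m_thinned), so on a
    small marker panel unrelated pairs would routinely cross ``kin_max``
    by chance. A pair is therefore flagged only when its estimate also
    exceeds a Bonferroni-corrected zero-relatedness detection bound
    (family-wise error ``fwer`` over all pairs); with the marker counts
    of genome-wide panels the bound sits below ``kin_max`` and the filter
    reduces to the plain threshold.
    """
    from scipy import stats as _st

    idx = ld_thin(geno, r2_max=thin_r2)
    rel = pi_hat(geno, idx)
    n = geno.n_samples
    call_rate = np.isfinite(geno.dosages).mean(axis=1)

    n_pairs = max(n * (n - 1) // 2, 1)
    iu = np.triu_indices(n, 1)
    off = rel[iu]
    # robust spread of the null (unrelated) pairs; residual LD inflates it
    # beyond the 1/sqrt(m) normal-theory value, so calibrate empirically
    sd_emp = 1.4826 * np.median(np.abs(off - np.median(off)))
    noise_bound = _st.norm.isf(fwer / n_pairs) * max(sd_emp, 1e-12)
    thresh = max(kin_max, noise_bound)

    flagged = [(i, j) for i, j in zip(*iu) if rel[i, j] > thresh]
    drop: set[int] = set()
    for i, j in flagged:
        if i in drop or j in drop:
            continue
        if call_rate[i] < call_rate[j]:
            drop.add(i)
        else:  # ties drop the later sample
            drop.add(j)
    keep = np.ones(n, bool)
    keep[list(drop)] = False
    report = QCReport(
        step="relatedness_filter",
        removed={"related": len(drop)},
        params={
            "kin_max": kin_max,
            "thin_r2": thin_r2,
            "n_thinned_variants": int(len(idx)),
            "noise_bound": float(noise_bound),
            "effective_threshold": float(thresh),
        },
        n_in=n,
        n_out=int(keep.sum()),
    )
    report.check()
    return geno.subset_samples(keep), report


# ---------------------------------------------------------------------------
# harmonization and sumstats hygiene
# ---------------------------------------------------------------------------


def harmonize(geno: GenotypeMatrix, ss: SummaryStats) -> tuple[SummaryStats, QCReport]:
    """Align summary-statistics alleles to the genotype panel.

    For each SNP shared by id: exact allele match is kept as-is; swapped
    alleles flip the sign of beta ("recode"); a complementary (or swapped
    complementary) match is strand-flipped (with sign flip when also
    swapped); anything else is dropped as a mismatch. SNPs absent from
    either side are dropped.
    """
    panel = geno.variants.set_index("snp")
    t = ss.table
    in_panel = t["SNP"].isin(panel.index)
    n_absent = int((~in_panel).sum())
    t = t[in_panel].copy()

    pa1 = panel.loc[t["SNP"], "a1"].to_numpy()
    pa2 = panel.loc[t["SNP"], "a2"].to_numpy()
    ea = t["A1"].to_numpy()
    oa = t["A2"].to_numpy()
    cea = np.array([_COMPLEMENT.get(a, "?") for a in ea])
    coa = np.array([_COMPLEMENT.get(a, "?") for a in oa])

    match = (ea == pa1) & (oa == pa2)
    swap = (ea == pa2) & (oa == pa1)
    flip = (cea == pa1) & (coa == pa2) & ~match & ~swap
    flip_swap = (cea == pa2) & (coa == pa1) & ~match & ~swap & ~flip
    mismatch = ~(match | swap | flip | flip_swap)

    beta = t["BETA"].to_numpy().copy()
    beta[swap | flip_swap] *= -1
    eaf = t["EAF"].to_numpy().copy() if "EAF" in t else None
    if eaf is not None:
        eaf[swap | flip_swap] = 1 - eaf[swap | flip_swap]

    out = t.copy()
    out["BETA"] = beta
    if eaf is not None:
        out["EAF"] = eaf
    out["A1"] = pa1
    out["A2"] = pa2
    out = out[~mismatch]

    report = QCReport(
        step="harmonize",
        removed={"absent_from_panel": n_absent, "allele_mismatch": int(mismatch.sum())},
        params={
            "recoded": int(swap.sum()),
            "strand_flipped": int(flip.sum()),
            "flipped_and_recoded": int(flip_swap.sum()),
        },
        n_in=len(ss.table),
        n_out=len(out),
    )
    report.check()
    return ss.replace_table(out), report


def sumstats_qc(ss: SummaryStats, maf_min: float = 0.01) -> tuple[SummaryStats, QCReport]:
    """Summary-statistics hygiene filters.

    Removes (in order) non-SNP alleles (indels / multi-character), all
    copies of duplicated ids, strand-ambiguous A/T and C/G SNPs, and SNPs
    whose reported frequency implies MAF < ``maf_min``. The MAF rule is
    skipped (and logged) when no EAF column exists.
    """
    t = ss.table
    n_in = len(t)
    bases = {"A", "C", "G", "T"}
    is_snp = t["A1"].isin(bases) & t["A2"].isin(bases) & (t["A1"] != t["A2"])
    n_indel = int((~is_snp).sum())
    t = t[is_snp]

    dup = t["SNP"].duplicated(keep=False)
    n_dup = int(dup.sum())
    t = t[~dup]

    ambiguous = t.apply(lambda r: _COMPLEMENT.get(r["A1"]) == r["A2"], axis=1) if len(t) else pd.Series([], dtype=bool)
    n_amb = int(ambiguous.sum())
    t = t[~ambiguous.to_numpy()] if len(t) else t

    maf_skipped = "EAF" not in t.columns
    if maf_skipped:
        n_maf = 0
    else:
        maf = np.minimum(t["EAF"], 1 - t["EAF"])
        low = (maf < maf_min).fillna(False)
        n_maf = int(low.sum())
        t = t[~low.to_numpy()]

    report = QCReport(
        step="sumstats_qc",
        removed={"indel_or_nonacgt": n_indel, "duplicate_id": n_dup, "ambiguous": n_amb, "low_maf": n_maf},
        params={"maf_min": maf_min, "maf_rule_skipped_no_eaf": maf_skipped},
        n_in=n_in,
        n_out=len(t),
    )
    report.check()
    return ss.replace_table(t), report


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------


def genotype_pca(geno: GenotypeMatrix, n_pcs: int = 5) -> np.ndarray:
    """Per-sample PCs of the column-standardized dosage matrix.

    Monomorphic columns are excluded; missing dosages are mean-imputed.
    The sign of each PC is fixed so its variant-loading vector has a
    non-negative sum (first nonzero loading positive on a tie), making
    scores deterministic across runs and BLAS builds.
    """
    X = geno.dosages
    freq = np.nanmean(X, axis=0) / 2
    Xi = np.where(np.isnan(X), 2 * freq, X)
    sd = Xi.std(axis=0)
    poly = sd > 0
    Z = (Xi[:, poly] - Xi[:, poly].mean(axis=0)) / sd[poly]
    rank = min(Z.shape)
    if n_pcs > rank:
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank {rank}")
    n = Z.shape[0]
    if n <= Z.shape[1]:
        # Gram-matrix route: eigenvectors of Z Z^T give the scores directly
        evals, evecs = np.linalg.eigh(Z @ Z.T)
        order = np.argsort(evals)[::-1][:n_pcs]
        svals = np.sqrt(np.clip(evals[order], 0, None))
        scores = evecs[:, order] * svals
        with np.errstate(invalid="ignore", divide="ignore"):
            loadings = (Z.T @ evecs[:, order]) / np.where(svals > 0, svals, 1.0)
    else:
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        scores = U[:, :n_pcs] * S[:n_pcs]
        loadings = Vt[:n_pcs].T
    for k in range(n_pcs):
        load = loadings[:, k]
        s = load.sum()
        if s < 0 or (s == 0 and np.any(load) and load[np.flatnonzero(load)[0]] < 0):
            scores[:, k] *= -1
    return scores


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------


def qc_cascade(
    geno: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_alpha: float = 1e-6,
    miss_max: float = 0.05,
    sample_miss_max: float = 0.01,
    het_sd: float = 3.0,
    kin_max: float = 0.125,
) -> tuple[GenotypeMatrix, list[QCReport]]:
    """Full genotype QC in the fixed order:

    variant filters -> sample filters -> variant call-rate re-pass ->
    relatedness pruning. Applying the cascade twice is idempotent.
    """
    reports: list[QCReport] = []
    g, r = variant_qc(geno, maf_min=maf_min, hwe_alpha=hwe_alpha, miss_max=miss_max)
    reports.append(r)
    g, r = sample_qc(g, miss_max=sample_miss_max, het_sd=het_sd)
    reports.append(r)
    # removing samples can push variant missingness over the bound
    g, r = variant_qc(g, maf_min=maf_min, hwe_alpha=hwe_alpha, miss_max=miss_max)
    r.step = "variant_qc_repass"
    reports.append(r)
    g, r = relatedness_filter(g, kin_max=kin_max)
    reports.append(r)
    return g, reports
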