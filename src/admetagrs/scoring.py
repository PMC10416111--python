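"""LD clumping and pruning-and-thresholding (P+T) risk scores.

For one trait, ``GRS_i(t) = sum_j beta_j * x_ij * 1{p_j < t}`` over the
clumped index SNPs, evaluated at the 13 canonical p-value thresholds.
The indicator is a strict inequality; missing dosages are imputed with
twice the effect-allele frequency of the scored sample set (the PLINK
``--score`` convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geno_io import GenotypeMatrix, SummaryStats

__all__ = ["THRESHOLDS", "ThresholdGRSMatrix", "ld_clump", "compute_grs", "standardize_scores"]

#: the 13 canonical p-value thresholds, strictly increasing
THRESHOLDS: tuple[float, ...] = (
    5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
)


@dataclass
class ThresholdGRSMatrix:
    """Samples x thresholds raw (or standardized) P+T score matrix."""

    trait: str
    thresholds: tuple[float, ...]
    scores: np.ndarray  # (n_samples, n_thresholds)
    snp_counts: np.ndarray  # per-threshold count of scored SNPs
    means: np.ndarray | None = None  # standardization moments, once applied
    sds: np.ndarray | None = None
    zero_sd: np.ndarray | None = None  # flags for degenerate columns

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, float)
        if t.ndim != 1 or (np.diff(t) <= 0).any():
            raise ValueError("thresholds must be strictly increasing")
        self.thresholds = tuple(t)
        self.scores = np.asarray(self.scores, float)
        if self.scores.shape[1] != t.size:
            raise ValueError("score matrix width must equal threshold count")
        self.snp_counts = np.asarray(self.snp_counts, int)

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    def to_frame(self, sample_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(self.scores, columns=[f"t={t:g}" for t in self.thresholds])
        if sample_ids is not None:
            df.insert(0, "sample_id", np.asarray(sample_ids))
        return df


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------


def ld_clump(
    geno: GenotypeMatrix,
    ss: SummaryStats,
    r2_max: float = 0.1,
    window_kb: float = 250.0,
) -> SummaryStats:
    """Greedy LD clumping of harmonized summary statistics.

    SNPs are visited in ascending p (ties broken by chromosome, then
    position, then id); a SNP becomes an index SNP unless it lies within
    ``window_kb`` of an already-chosen index SNP on the same chromosome
    with genotypic r-squared above ``r2_max``. r2 is computed in the
    target panel itself (mean-imputed missing calls). Returns the index
    SNPs only, in the original sumstats row order.
    """
    panel_pos = {s: i for i, s in enumerate(geno.variants["snp"])}
    t = ss.table
    shared = t["SNP"].isin(panel_pos.keys())
    if not shared.any():
        raise ValueError("no SNPs shared between panel and summary statistics")
    t = t[shared]

    order = t.sort_values(["P", "CHR", "BP", "SNP"], kind="mergesort")
    X = geno.dosages
    freq = geno.allele_freq()
    cols = {}

    def zcol(j: int) -> np.ndarray:
        if j not in cols:
            x = X[:, j]
            x = np.where(np.isnan(x), 2 * freq[j], x)
            sd = x.std()
            cols[j] = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        return cols[j]

    n = X.shape[0]
    window = window_kb * 1000.0
    index_rows: list = []
    kept_by_chrom: dict[int, list[tuple[int, int]]] = {}  # chrom -> [(pos, panel_j)]
    for row in order.itertuples():
        chrom, pos = int(row.CHR), int(row.BP)
        j = panel_pos[row.SNP]
        clumped = False
        for kpos, kj in kept_by_chrom.get(chrom, ()):
            if abs(kpos - pos) <= window:
                r = float(zcol(kj) @ zcol(j)) / n
                if r * r > r2_max:
                    clumped = True
                    break
        if not clumped:
            kept_by_chrom.setdefault(chrom, []).append((pos, j))
            index_rows.append(row.Index)
    return ss.replace_table(t.loc[t.index.isin(index_rows)])


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def compute_grs(
    geno: GenotypeMatrix,
    ss: SummaryStats,
    thresholds: tuple[float, ...] = THRESHOLDS,
) -> ThresholdGRSMatrix:
    """Raw P+T scores at every threshold for one trait.

    Only SNPs present in the panel are scored; by the nesting of the
    strict-inequality indicator, the SNP set at a smaller threshold is a
    subset of that at any larger one.
    """
    t = np.asarray(thresholds, float)
    if t.ndim != 1 or (np.diff(t) <= 0).any():
        raise ValueError("thresholds must be strictly increasing")

    tbl = ss.table
    panel_pos = {s: i for i, s in enumerate(geno.variants["snp"])}
    shared = tbl["SNP"].isin(panel_pos.keys())
    tbl = tbl[shared]

    j_idx = np.array([panel_pos[s] for s in tbl["SNP"]], dtype=int)
    beta = tbl["BETA"].to_numpy()
    pval = tbl["P"].to_numpy()

    X = geno.dosages[:, j_idx]
    freq = geno.allele_freq()[j_idx]
    X = np.where(np.isnan(X), 2 * freq, X)

    n = geno.n_samples
    scores = np.zeros((n, t.size))
    counts = np.zeros(t.size, int)
    for a, thr in enumerate(t):
        mask = pval < thr
        counts[a] = int(mask.sum())
        if counts[a]:
            scores[:, a] = X[:, mask] @ beta[mask]
    return ThresholdGRSMatrix(trait=ss.trait, thresholds=tuple(t), scores=scores, snp_counts=counts)


def standardize_scores(
    mat: ThresholdGRSMatrix,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
) -> ThresholdGRSMatrix:
    """Center/scale each threshold column to zero mean, unit SD.

    External ``means``/``sds`` (train -> test transfer) are applied when
    given instead of recomputing. Zero-SD columns map to all zeros and
    are flagged in ``zero_sd``.
    """
    if (means is None) != (sds is None):
        raise ValueError("provide both means and sds, or neither")
    if means is None:
        means = mat.scores.mean(axis=0)
        sds = mat.scores.std(axis=0)
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    zero = sds <= 0
    safe = np.where(zero, 1.0, sds)
    z = (mat.scores - means) / safe
    z[:, zero] = 0.0
    return replace(mat, scores=z, means=means, sds=sds, zero_sd=zero)
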