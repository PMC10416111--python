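"""Principal-component GRS across p-value thresholds.

Rather than letting the phenotype pick a "best" p-value threshold, the
first principal component of the 13 standardized threshold scores serves
as the trait's final GRS. Because the thresholds nest, their scores are
highly collinear and PC1 typically captures most of the variance; the PC
loadings amount to a fixed per-SNP reweighting that transfers to a test
cohort.

Eigensolver sign is arbitrary, so PC1 is oriented to correlate
non-negatively with the mean of the standardized threshold scores:
higher PCA-GRS always means higher genetic burden.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import ThresholdGRSMatrix, standardize_scores

__all__ = ["PCAGRSModel", "fit_pca_grs", "apply_pca_grs", "pcagrs_correlation_matrix"]


@dataclass
class PCAGRSModel:
    """Fitted PCA-GRS for one trait: training moments + PC1 loadings."""

    trait: str
    thresholds: tuple[float, ...]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # unit norm over the thresholds; 0 for degenerate cols
    explained_variance_ratio: np.ndarray
    orientation: float = 1.0  # sign already folded into loadings; kept for audit

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "trait": self.trait,
                    "thresholds": list(self.thresholds),
                    "means": self.means.tolist(),
                    "sds": self.sds.tolist(),
                    "loadings": self.loadings.tolist(),
                    "explained_variance_ratio": self.explained_variance_ratio.tolist(),
                    "orientation": self.orientation,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAGRSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            trait=d["trait"],
            thresholds=tuple(d["thresholds"]),
            means=np.asarray(d["means"]),
            sds=np.asarray(d["sds"]),
            loadings=np.asarray(d["loadings"]),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"]),
            orientation=d["orientation"],
        )


def fit_pca_grs(train: ThresholdGRSMatrix) -> PCAGRSModel:
    """Fit PC1 of the standardized threshold scores on the training cohort.

    Zero-SD (degenerate) columns — typically stringent thresholds that
    admit no SNP — are excluded from the decomposition and recorded with
    zero loading. Raises if every column is degenerate or n < 2.
    """
    if train.n_samples < 2:
        raise ValueError("need at least 2 samples to fit a PCA-GRS")
    std = standardize_scores(train) if train.means is None else train
    active = ~std.zero_sd
    if not active.any():
        raise ValueError("all threshold columns are degenerate (zero SD)")

    Z = std.scores[:, active]
    cov = np.cov(Z, rowvar=False, ddof=0)
    cov = np.atleast_2d(cov)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    v1 = evecs[:, order[0]]

    pc1 = Z @ v1
    ref = Z.mean(axis=1)
    orient = np.sign(np.dot(pc1 - pc1.mean(), ref - ref.mean()))
    if orient == 0:  # tie: keep eigensolver orientation, pinned positive sum
        orient = 1.0 if v1.sum() >= 0 else -1.0
    v1 = v1 * orient

    loadings = np.zeros(len(std.thresholds))
    loadings[active] = v1
    evr = evals / evals.sum() if evals.sum() > 0 else np.full_like(evals, np.nan)
    return PCAGRSModel(
        trait=train.trait,
        thresholds=std.thresholds,
        means=std.means,
        sds=std.sds,
        loadings=loadings,
        explained_variance_ratio=evr,
        orientation=float(orient),
    )


def apply_pca_grs(
    model: PCAGRSModel,
    mat: ThresholdGRSMatrix,
    use_train_moments: bool = False,
) -> np.ndarray:
    """Project a cohort's threshold scores onto the fitted PC1 loadings.

    By default the cohort's columns are standardized with its *own*
    moments (per-cohort standardization); ``use_train_moments=True``
    transfers the training moments instead.
    """
    if tuple(mat.thresholds) != tuple(model.thresholds):
        diff = [
            (a, b)
            for a, b in zip(mat.thresholds, model.thresholds)
            if a != b
        ] or [("n=%d" % len(mat.thresholds), "n=%d" % len(model.thresholds))]
        raise ValueError(f"threshold mismatch between model and scores: {diff}")
    if mat.means is None:
        if use_train_moments:
            mat = standardize_scores(mat, means=model.means, sds=model.sds)
        else:
            mat = standardize_scores(mat)
    return mat.scores @ model.loadings


def pcagrs_correlation_matrix(scores: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Pairwise Pearson correlations among per-trait PCA-GRS columns."""
    df = pd.DataFrame(scores)
    corr = df.corr(method="pearson")
    return corr
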