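"""Elastic-net combination of per-trait PCA-GRSs into a MetaGRS.

An elastic-net logistic regression of case status on the K standardized
PCA-GRSs — adjusting for sex, the first five genotype PCs and optionally
APOE e2/e4 dosages — supplies per-trait weights gamma_k. The covariates
are adjustment controls, not selectable features, so only the trait
scores are penalized. The mixing parameter alpha and the strength lambda
are chosen jointly by stratified 20-fold cross-validation maximizing the
validation AUC, followed by a refit on the full training cohort. The
score itself is the covariate-free weighted sum

    MetaGRS_i = sum_k gamma_k * standardized PCA_GRS_ik .
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "MetaGRSModel",
    "fit_metagrs",
    "compute_metagrs",
    "univariate_coefficients",
    "DEFAULT_ALPHA_GRID",
]

DEFAULT_ALPHA_GRID: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0)


@dataclass
class MetaGRSModel:
    """Fitted elastic-net meta-score combiner."""

    traits: list[str]
    gamma: np.ndarray  # one weight per trait, standardized-score scale
    covariate_names: list[str]
    covariate_coefs: np.ndarray
    intercept: float
    alpha: float  # L1/L2 mixing in (0, 1]
    lam: float  # penalty strength
    cv_table: pd.DataFrame  # columns alpha, lam, mean_auc
    score_means: np.ndarray  # training moments of each PCA-GRS
    score_sds: np.ndarray
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "traits": self.traits,
                    "gamma": self.gamma.tolist(),
                    "covariate_names": self.covariate_names,
                    "covariate_coefs": self.covariate_coefs.tolist(),
                    "intercept": self.intercept,
                    "alpha": self.alpha,
                    "lambda": self.lam,
                    "cv_table": self.cv_table.to_dict(orient="list"),
                    "score_means": self.score_means.tolist(),
                    "score_sds": self.score_sds.tolist(),
                    "seed": self.seed,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "MetaGRSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            traits=d["traits"],
            gamma=np.asarray(d["gamma"]),
            covariate_names=d["covariate_names"],
            covariate_coefs=np.asarray(d["covariate_coefs"]),
            intercept=d["intercept"],
            alpha=d["alpha"],
            lam=d["lambda"],
            cv_table=pd.DataFrame(d["cv_table"]),
            score_means=np.asarray(d["score_means"]),
            score_sds=np.asarray(d["score_sds"]),
            seed=d["seed"],
        )


def _design(scores_std: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    n = scores_std.shape[0]
    return np.column_stack([np.ones(n), scores_std, covariates])


def elastic_net_logistic(
    D: np.ndarray,
    y: np.ndarray,
    penalty: np.ndarray,
    mix: float,
    start: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Penalized logistic regression via IRLS + coordinate descent.

    Minimizes ``-loglik/n + sum_j penalty_j (mix |b_j| + (1-mix)/2 b_j^2)``
    (the glmnet objective with a per-coefficient penalty vector; zeros
    leave the intercept and adjustment covariates unpenalized). Each
    outer step forms the usual weighted working response, then cycles
    soft-threshold coordinate updates until stable. Warm ``start``
    vectors make a descending lambda path cheap.
    """
    n, p = D.shape
    beta = np.zeros(p) if start is None else np.asarray(start, float).copy()
    eta = D @ beta
    l1 = penalty * mix
    l2 = penalty * (1.0 - mix)
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.clip(mu * (1.0 - mu), 1e-5, None)
        z = eta + (y - mu) / w
        wxx = (w[:, None] * D * D).sum(axis=0) / n
        resid = z - eta
        beta_outer = beta.copy()
        for _sweep in range(200):
            max_step = 0.0
            for j in range(p):
                xj = D[:, j]
                rho = float(w @ (xj * resid)) / n + wxx[j] * beta[j]
                bj = np.sign(rho) * max(abs(rho) - l1[j], 0.0) / (wxx[j] + l2[j])
                step = bj - beta[j]
                if step != 0.0:
                    resid -= xj * step
                    beta[j] = bj
                    max_step = max(max_step, abs(step))
            if max_step < tol:
                break
        eta = D @ beta
        if np.max(np.abs(beta - beta_outer)) < tol * 10:
            break
    return beta


def _fit_enet(
    D: np.ndarray,
    y: np.ndarray,
    k_traits: int,
    lam: float,
    mix: float,
    start: np.ndarray | None = None,
) -> np.ndarray:
    penalty = np.zeros(D.shape[1])
    penalty[1 : 1 + k_traits] = lam  # intercept and covariates unpenalized
    return elastic_net_logistic(D, y, penalty, mix, start=start)


def _lambda_path(
    scores_std: np.ndarray, y: np.ndarray, mix: float, n_lambda: int, lam_min_ratio: float
) -> np.ndarray:
    """glmnet-style geometric path from the smallest lambda zeroing all
    trait weights down to ``lam_min_ratio`` times that."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(scores_std.T @ resid).max() / (n * max(mix, 1e-3))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max * 1.001, lam_max * lam_min_ratio, n_lambda)


def fit_metagrs(
    pcagrs_scores: pd.DataFrame,
    pheno: pd.DataFrame,
    covariate_names: list[str] | None = None,
    folds: int = 20,
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID,
    n_lambda: int = 10,
    lam_min_ratio: float = 1e-3,
    seed: int = 0,
    apoe_covariates: bool = False,
) -> MetaGRSModel:
    """Train the elastic-net MetaGRS combiner.

    Parameters
    ----------
    pcagrs_scores
        Samples x traits DataFrame of per-trait PCA-GRS values (raw scale;
        standardized internally with stored training moments).
    pheno
        Per-sample table with ``status`` plus the covariate columns
        (``sex``, ``PC1``..``PC5`` by default; ``e2_dosage``/``e4_dosage``
        appended when ``apoe_covariates``).
    folds, alpha_grid, n_lambda, lam_min_ratio
        Candidate grid: every alpha in ``alpha_grid`` crossed with a
        data-driven geometric lambda path. Selection maximizes the mean
        validation AUC over stratified folds; ties prefer the larger
        lambda, then the smaller alpha. Final weights come from a refit
        on all training samples.
    """
    if pcagrs_scores.isna().any().any():
        raise ValueError("PCA-GRS matrix contains missing values")
    traits = list(pcagrs_scores.columns)
    y = pheno["status"].to_numpy().astype(float)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("case/control outcome has a single class")
    if folds > counts.min():
        raise ValueError(f"folds={folds} exceeds the minority class count {counts.min()}")
    if len(y) < 2 * folds:
        raise ValueError("need at least 2 samples per fold")

    if covariate_names is None:
        covariate_names = ["sex"] + [f"PC{i}" for i in range(1, 6)]
        covariate_names = [c for c in covariate_names if c in pheno.columns]
    if apoe_covariates:
        covariate_names = covariate_names + ["e2_dosage", "e4_dosage"]
    C = pheno[covariate_names].to_numpy().astype(float)

    S = pcagrs_scores.to_numpy().astype(float)
    mu, sd = S.mean(axis=0), S.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (S - mu) / sd
    k = len(traits)

    # candidates grouped per alpha along a descending lambda path so each
    # fit can warm-start from its predecessor
    paths = {mix: _lambda_path(Z, y, mix, n_lambda, lam_min_ratio) for mix in alpha_grid}
    candidates = [(mix, float(lam)) for mix in alpha_grid for lam in paths[mix]]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Z, y))
    for _, val in splits:
        if np.unique(y[val]).size < 2:
            raise ValueError("a CV fold lost one outcome class; reduce folds")

    aucs = np.zeros((len(candidates), folds))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f, (tr, val) in enumerate(splits):
            D_tr = _design(Z[tr], C[tr])
            D_val = _design(Z[val], C[val])
            c = 0
            for mix in alpha_grid:
                params = None
                for lam in paths[mix]:
                    params = _fit_enet(D_tr, y[tr], k, float(lam), mix, start=params)
                    aucs[c, f] = roc_auc_score(y[val], D_val @ params)
                    c += 1

    mean_auc = aucs.mean(axis=1)
    cv_table = pd.DataFrame(
        {
            "alpha": [c[0] for c in candidates],
            "lambda": [c[1] for c in candidates],
            "mean_auc": mean_auc,
        }
    )
    # argmax AUC; ties -> larger lambda, then smaller alpha
    best = cv_table.sort_values(
        ["mean_auc", "lambda", "alpha"], ascending=[False, False, True], kind="mergesort"
    ).index[0]
    best_mix = float(cv_table.loc[best, "alpha"])
    best_lam = float(cv_table.loc[best, "lambda"])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = _fit_enet(_design(Z, C), y, k, best_lam, best_mix)
    return MetaGRSModel(
        traits=traits,
        gamma=params[1 : 1 + k],
        covariate_names=covariate_names,
        covariate_coefs=params[1 + k :],
        intercept=float(params[0]),
        alpha=best_mix,
        lam=best_lam,
        cv_table=cv_table,
        score_means=mu,
        score_sds=sd,
        seed=seed,
    )


def compute_metagrs(
    model: MetaGRSModel,
    pcagrs_scores: pd.DataFrame,
    use_train_moments: bool = False,
) -> np.ndarray:
    """MetaGRS_i = sum_k gamma_k * standardized PCA-GRS_ik.

    Covariates and intercept are *not* part of the score; they re-enter
    only in the evaluation regressions. Scores are standardized with the
    evaluation cohort's own moments by default (per-cohort convention),
    or with the stored training moments when ``use_train_moments``.
    """
    if list(pcagrs_scores.columns) != model.traits:
        raise ValueError(
            f"trait mismatch: model has {model.traits}, scores have "
            f"{list(pcagrs_scores.columns)}"
        )
    S = pcagrs_scores.to_numpy().astype(float)
    if use_train_moments:
        mu, sd = model.score_means, model.score_sds
    else:
        mu, sd = S.mean(axis=0), S.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    return ((S - mu) / sd) @ model.gamma


def univariate_coefficients(
    pcagrs_scores: pd.DataFrame,
    pheno: pd.DataFrame,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-trait single-score logistic coefficients with 95% Wald CIs.

    Each trait's standardized PCA-GRS enters its own logistic regression
    of case status with the shared covariates; returns columns
    ``trait, coef, se, ci_low, ci_high, p, separation_flag``.
    """
    y = pheno["status"].to_numpy().astype(float)
    if covariate_names is None:
        covariate_names = ["sex"] + [f"PC{i}" for i in range(1, 6)]
        covariate_names = [c for c in covariate_names if c in pheno.columns]
    C = pheno[covariate_names].to_numpy().astype(float)

    rows = []
    for trait in pcagrs_scores.columns:
        s = pcagrs_scores[trait].to_numpy().astype(float)
        sd = s.std()
        z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
        D = np.column_stack([np.ones(len(y)), z, C])
        flag = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, D).fit(disp=0, maxiter=200)
            coef, se = res.params[1], res.bse[1]
            pval = res.pvalues[1]
            if not res.mle_retvals.get("converged", True) or abs(coef) > 15 or not np.isfinite(se):
                flag = True
        except Exception:
            coef, se, pval, flag = np.nan, np.nan, np.nan, True
        rows.append(
            {
                "trait": trait,
                "coef": coef,
                "se": se,
                "ci_low": coef - 1.959963984540054 * se,
                "ci_high": coef + 1.959963984540054 * se,
                "p": pval,
                "separation_flag": flag,
            }
        )
    return pd.DataFrame(rows)
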