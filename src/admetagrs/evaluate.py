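"""Predictive-power evaluation of genetic risk scores.

Two complementary views, matching how polygenic-score validation is
usually reported: a Cox proportional-hazards model on age of onset
(hazard ratio per 1 SD of score, Harrell's C-index) and a logistic model
on case status (odds ratio per SD, AUC, Nagelkerke pseudo-R2), each
adjusting for age, sex and the leading genotype PCs; plus APOE-e4
stratification, APOE-region exclusion for sensitivity analyses, a
cohort-summary table with Fisher exact tests, and a side-by-side model
comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from .geno_io import SummaryStats

__all__ = [
    "CoxResult",
    "LogisticResult",
    "fit_cox",
    "harrell_c",
    "fit_logistic_eval",
    "stratify_by_e4",
    "exclude_region",
    "fisher_exact_2xk",
    "cohort_summary",
    "compare_models",
]

DEFAULT_COVARIATES = ["age", "sex", "PC1", "PC2", "PC3", "PC4", "PC5"]

#: APOE/TOMM40/APOC1 cluster with flanks, GRCh37
APOE_REGION = (19, 44_400_000, 46_500_000)


@dataclass
class CoxResult:
    beta: float
    hr: float
    se: float
    p: float
    c_index: float
    n: int
    n_events: int
    converged: bool = True
    diagnostics: str = ""

    def to_dict(self) -> dict:
        return {
            "beta": self.beta, "hr": self.hr, "se": self.se, "p": self.p,
            "c_index": self.c_index, "n": self.n, "n_events": self.n_events,
            "converged": self.converged,
        }


@dataclass
class LogisticResult:
    beta: float
    or_: float
    se: float
    p: float
    auc: float
    pseudo_r2: float
    n: int

    def to_dict(self) -> dict:
        return {
            "beta": self.beta, "or": self.or_, "se": self.se, "p": self.p,
            "auc": self.auc, "pseudo_r2": self.pseudo_r2, "n": self.n,
        }


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------


def harrell_c(risk, time, event) -> float:
    """Harrell's concordance index.

    Usable pairs are those where the shorter time carries an event
    (ties in time are excluded); a pair is concordant when the shorter
    time has the strictly higher risk, and risk ties count 1/2.
    Vectorized O(n^2); fine for cohort-scale n.
    """
    risk = np.asarray(risk, float)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    if risk.shape != time.shape or risk.shape != event.shape:
        raise ValueError("risk, time and event must have equal length")

    dt = time[:, None] - time[None, :]  # t_i - t_j
    usable = (dt < 0) & event[:, None]  # i strictly earlier, i has event
    if not usable.any():
        raise ValueError("no usable pairs (no events or all times tied)")
    dr = risk[:, None] - risk[None, :]
    concordant = (dr > 0) & usable
    tied = (dr == 0) & usable
    return float((concordant.sum() + 0.5 * tied.sum()) / usable.sum())


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------


def _standardize(score: np.ndarray) -> np.ndarray:
    score = np.asarray(score, float)
    sd = score.std()
    if sd == 0:
        raise ValueError("score has zero variance")
    return (score - score.mean()) / sd


def fit_cox(
    score,
    pheno: pd.DataFrame,
    covariates: list[str] | None = None,
    ties: str = "efron",
) -> CoxResult:
    """Cox PH fit of onset age on the per-SD standardized score.

    ``pheno`` needs ``age`` (onset for events, censoring otherwise) and
    ``event``; covariates default to baseline age, sex and PC1..PC5
    (whichever are present). The C-index is Harrell's C of the model's
    full linear predictor. Ties handled by Efron's method (Breslow via
    ``ties``). ``score=None`` fits the covariates-only reference model
    (beta/HR reported as NaN).
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in pheno.columns]
    event = pheno["event"].to_numpy().astype(int)
    if event.sum() == 0:
        raise ValueError("no events in the evaluation sample")
    t = pheno["age"].to_numpy().astype(float)
    if (t <= 0).any():
        raise ValueError("follow-up times must be positive")

    base = {"time": t, "event": event}
    if score is not None:
        base = {"score": _standardize(score), **base}
    df = pd.DataFrame(base)
    for c in covariates:
        if c == "age":
            # "age" as a covariate of an age-of-onset model means baseline
            # age; only usable when an age_baseline column distinct from
            # the timescale exists
            if "age_baseline" in pheno:
                df["age_baseline"] = pheno["age_baseline"].to_numpy().astype(float)
            continue
        df[c] = pheno[c].to_numpy().astype(float)
    # constant covariates carry no information and break the fit
    drop = [c for c in df.columns if c not in ("time", "event") and df[c].std() == 0]
    df = df.drop(columns=drop)

    converged, diag = True, ""
    if ties == "efron":
        cph = CoxPHFitter(penalizer=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cph.fit(df, duration_col="time", event_col="event")
            except Exception as exc:  # pragma: no cover - convergence pathologies
                converged, diag = False, str(exc)
                cph = CoxPHFitter(penalizer=1e-4)
                cph.fit(df, duration_col="time", event_col="event")
        if score is not None:
            beta = float(cph.params_["score"])
            se = float(cph.standard_errors_["score"])
            p = float(cph.summary.loc["score", "p"])
        else:
            beta = se = p = float("nan")
        lp = np.log(cph.predict_partial_hazard(df).to_numpy())
    elif ties == "breslow":
        exog_cols = [c for c in df.columns if c not in ("time", "event")]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.PHReg(
                df["time"], df[exog_cols], status=df["event"], ties="breslow"
            ).fit()
        if score is not None:
            i = exog_cols.index("score")
            beta = float(res.params[i])
            se = float(res.bse[i])
            p = float(res.pvalues[i])
        else:
            beta = se = p = float("nan")
        lp = df[exog_cols].to_numpy() @ res.params
    else:
        raise ValueError("ties must be 'efron' or 'breslow'")
    c = harrell_c(lp, df["time"].to_numpy(), df["event"].to_numpy())
    return CoxResult(
        beta=beta, hr=math.exp(beta), se=se, p=p, c_index=c,
        n=len(df), n_events=int(event.sum()), converged=converged, diagnostics=diag,
    )


def _nagelkerke(ll_model: float, ll_null: float, n: int) -> float:
    cs = 1.0 - math.exp(2.0 * (ll_null - ll_model) / n)
    denom = 1.0 - math.exp(2.0 * ll_null / n)
    return cs / denom if denom > 0 else float("nan")


def fit_logistic_eval(
    score,
    pheno: pd.DataFrame,
    covariates: list[str] | None = None,
    pseudo_r2: str = "nagelkerke",
) -> LogisticResult:
    """Logistic fit of case status on the per-SD standardized score.

    AUC is computed from the fitted probabilities of the full model;
    pseudo-R2 is Nagelkerke by default (``"mcfadden"`` available).
    ``score=None`` fits the covariates-only reference model.
    """
    if covariates is None:
        covariates = [c for c in DEFAULT_COVARIATES if c in pheno.columns]
    y = pheno["status"].to_numpy().astype(float)
    if np.unique(y).size < 2:
        raise ValueError("evaluation sample contains a single outcome class")
    C = pheno[covariates].to_numpy().astype(float) if covariates else np.empty((len(y), 0))
    keep_cov = C.std(axis=0) > 0 if C.size else np.array([], bool)
    parts = [np.ones(len(y))]
    if score is not None:
        parts.append(_standardize(score))
    D = np.column_stack(parts + [C[:, keep_cov]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, D).fit(disp=0, maxiter=200)
        null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0)

    prob = res.predict(D)
    auc = roc_auc(y, prob)
    if pseudo_r2 == "nagelkerke":
        r2 = _nagelkerke(res.llf, null.llf, len(y))
    elif pseudo_r2 == "mcfadden":
        r2 = 1.0 - res.llf / null.llf
    else:
        raise ValueError("pseudo_r2 must be 'nagelkerke' or 'mcfadden'")
    if score is not None:
        beta, se, p = float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])
        or_ = math.exp(beta)
    else:
        beta = se = p = or_ = float("nan")
    return LogisticResult(beta=beta, or_=or_, se=se, p=p, auc=auc, pseudo_r2=r2, n=len(y))


def roc_auc(y, score) -> float:
    """AUC as the normalized Mann-Whitney U statistic (ties count 1/2)."""
    y = np.asarray(y).astype(bool)
    score = np.asarray(score, float)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(score)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


# ---------------------------------------------------------------------------
# stratification and region exclusion
# ---------------------------------------------------------------------------


def stratify_by_e4(pheno: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a cohort by APOE e4 carriage.

    Carriers have e4 dosage >= 1 (e3e4, e4e4, e2e4), non-carriers dosage
    0; samples with missing e4 dosage are excluded and counted under
    ``"missing"`` (an empty frame keeps the bookkeeping honest).
    """
    d = pheno["e4_dosage"]
    missing = d.isna()
    carriers = pheno[(d >= 1) & ~missing]
    noncarriers = pheno[(d == 0) & ~missing]
    return {
        "carriers": carriers.reset_index(drop=True),
        "non_carriers": noncarriers.reset_index(drop=True),
        "missing": pheno[missing].reset_index(drop=True),
    }


def exclude_region(
    ss: SummaryStats,
    chrom: int = APOE_REGION[0],
    start: int = APOE_REGION[1],
    end: int = APOE_REGION[2],
) -> tuple[SummaryStats, int]:
    """Drop SNPs with position in the half-open interval [start, end) on
    ``chrom``; returns the filtered sumstats and the removal count."""
    t = ss.table
    inside = (t["CHR"].astype(int) == chrom) & (t["BP"] >= start) & (t["BP"] < end)
    return ss.replace_table(t[~inside]), int(inside.sum())


# ---------------------------------------------------------------------------
# Fisher exact tests and the cohort summary
# ---------------------------------------------------------------------------


def _fisher_2x2(table: np.ndarray) -> float:
    """Two-sided conditional exact test by hypergeometric enumeration."""
    a, b = int(table[0, 0]), int(table[0, 1])
    c, d = int(table[1, 0]), int(table[1, 1])
    n = a + b + c + d
    k_col = a + c
    r1 = a + b
    rv = stats.hypergeom(n, k_col, r1)
    support = np.arange(max(0, r1 + k_col - n), min(r1, k_col) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-7)].sum()))


def fisher_exact_2xk(
    table,
    max_tables: int = 2_000_000,
    n_mc: int = 200_000,
    seed: int = 0,
) -> float:
    """Exact conditional test of independence on a 2 x k count table.

    Two-sided p = total probability, under the multivariate hypergeometric
    distribution conditional on both margins, of tables no more probable
    than the observed one. For k = 2 this is the classical Fisher exact
    test. Larger tables are fully enumerated while the number of candidate
    tables stays below ``max_tables``, otherwise a seeded Monte-Carlo
    estimate over ``n_mc`` conditional draws is returned.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    k = t.shape[1]
    if k == 2:
        return _fisher_2x2(t)

    col = t.sum(axis=0)
    r1 = int(t[0].sum())
    n = int(t.sum())

    def log_prob(x: np.ndarray) -> float:
        # P(x) = prod_j C(col_j, x_j) / C(n, r1)
        return float(
            sum(_lchoose(col[j], x[j]) for j in range(k)) - _lchoose(n, r1)
        )

    lp_obs = log_prob(t[0])

    # enumeration budget: product over columns of (col_j + 1), bounded by r1
    budget = 1
    for cj in col:
        budget *= min(cj, r1) + 1
        if budget > max_tables:
            break
    if budget <= max_tables:
        total = 0.0
        x = np.zeros(k, dtype=int)

        def recurse(j: int, remaining: int, lp_acc: float) -> None:
            nonlocal total
            if j == k - 1:
                if remaining <= col[j]:
                    lp = lp_acc + _lchoose(col[j], remaining) - _lchoose(n, r1)
                    if lp <= lp_obs + 1e-7:
                        total += math.exp(lp)
                return
            hi = min(col[j], remaining)
            lo = max(0, remaining - int(col[j + 1 :].sum()))
            for xj in range(lo, hi + 1):
                recurse(j + 1, remaining - xj, lp_acc + _lchoose(col[j], xj))

        recurse(0, r1, 0.0)
        return float(min(1.0, total))

    # Monte-Carlo fallback: sample row-1 allocations from the conditional law
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(k), col)
    hits = 0
    for _ in range(n_mc):
        pick = rng.choice(pool, size=r1, replace=False)
        x = np.bincount(pick, minlength=k)
        if log_prob(x) <= lp_obs + 1e-7:
            hits += 1
    return float((hits + 1) / (n_mc + 1))


def _lchoose(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -math.inf
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


APOE_CLASSES = ["e2e2", "e2e3", "e3e3", "e3e4", "e4e4", "e2e4"]


def _apoe_class(e2, e4) -> str | None:
    if pd.isna(e2) or pd.isna(e4):
        return None
    e2, e4 = int(e2), int(e4)
    if e2 + e4 > 2:
        return None
    return {
        (2, 0): "e2e2", (1, 0): "e2e3", (0, 0): "e3e3",
        (0, 1): "e3e4", (0, 2): "e4e4", (1, 1): "e2e4",
    }.get((e2, e4))


def cohort_summary(pheno: pd.DataFrame) -> pd.DataFrame:
    """Case/control cohort summary with per-row Fisher exact tests.

    One row each for AD status, sex (count of one sex level) and the six
    APOE genotype classes. Each genotype/sex row's p-value is a 2 x 2
    Fisher exact test of that class against all others, cases vs
    controls — the construction consistent with a single p per row.
    """
    if len(pheno) == 0:
        raise ValueError("empty cohort")
    status = pheno["status"].astype(int)
    cases = pheno[status == 1]
    controls = pheno[status == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("cohort summary needs both cases and controls")

    rows = [
        {
            "characteristic": "AD",
            "all_n": int((status == 1).sum()),
            "control_n": np.nan,
            "case_n": np.nan,
            "p": np.nan,
        }
    ]
    if "sex" in pheno:
        male = pheno["sex"].to_numpy() == 1
        tab = np.array(
            [
                [int(male[status == 0].sum()), int((~male[status == 0]).sum())],
                [int(male[status == 1].sum()), int((~male[status == 1]).sum())],
            ]
        )
        rows.append(
            {
                "characteristic": "sex_male",
                "all_n": int(male.sum()),
                "control_n": tab[0, 0],
                "case_n": tab[1, 0],
                "p": fisher_exact_2xk(tab.T),
            }
        )
    if {"e2_dosage", "e4_dosage"} <= set(pheno.columns):
        klass = pheno.apply(lambda r: _apoe_class(r["e2_dosage"], r["e4_dosage"]), axis=1)
        for cls in APOE_CLASSES:
            in_cls = (klass == cls).to_numpy()
            ctrl_in = int(in_cls[status == 0].sum())
            case_in = int(in_cls[status == 1].sum())
            tab = np.array(
                [
                    [ctrl_in, len(controls) - ctrl_in],
                    [case_in, len(cases) - case_in],
                ]
            )
            rows.append(
                {
                    "characteristic": cls,
                    "all_n": int(in_cls.sum()),
                    "control_n": ctrl_in,
                    "case_n": case_in,
                    "p": fisher_exact_2xk(tab),
                }
            )
    out = pd.DataFrame(rows)
    out["all_pct"] = 100 * out["all_n"] / len(pheno)
    return out


def compare_models(reports: dict[str, dict[str, CoxResult | LogisticResult | None]]) -> pd.DataFrame:
    """Side-by-side table of evaluation results.

    ``reports`` maps model name (reference / AD-GRS / MetaGRS) to a dict
    of stratum name -> result (None for a missing stratum, which is
    reported as an omitted row with a note).
    """
    rows = []
    for model, strata in reports.items():
        for stratum, res in strata.items():
            if res is None:
                rows.append({"model": model, "stratum": stratum, "note": "omitted: no samples"})
                continue
            d = res.to_dict()
            d.update({"model": model, "stratum": stratum, "note": ""})
            rows.append(d)
    df = pd.DataFrame(rows)
    front = ["model", "stratum"]
    return df[front + [c for c in df.columns if c not in front]]
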