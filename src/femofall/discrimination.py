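"""Case-control discrimination statistics.

Group-difference testing (normality-gated t-test / Mann-Whitney U),
cross-validated logistic-regression scoring, AUROC, and the DeLong test for
correlated AUROCs, plus the report builders that assemble the summary and
AUROC tables for a descriptor cohort.

Two cross-validated AUROC estimators are provided.  ``pooled_loo`` pools
the leave-one-out held-out probabilities and computes one AUROC; it is kept
because the per-subject paired scores it yields are what the DeLong
comparison needs, but it carries a well-known pessimistic bias for
weakly-informative predictors (each left-out subject drags the fold's fit
away from itself, anti-correlating score and label).  ``leave_pair_out``
(the default for reported AUROCs) scores every (case, control) pair with a
model fitted on the remaining n-2 subjects and is close to unbiased; see
docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import mannwhitneyu, norm, rankdata, shapiro, ttest_ind

__all__ = [
    "ScoreVector",
    "DiscriminationReport",
    "auroc",
    "mann_whitney_u",
    "group_difference_test",
    "fit_logistic",
    "loocv_logistic",
    "cv_auroc",
    "delong_test",
    "delong_variance",
    "build_reports",
]

COEF_CAP = 50.0  # |beta| bound after standardization (separation guard)


@dataclass(frozen=True)
class ScoreVector:
    """Per-subject scores (e.g. cross-validated probabilities) with labels."""

    scores: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))
        if self.scores.shape != self.labels.shape or self.scores.ndim != 1:
            raise ValueError("scores and labels must be matching 1D arrays")


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(case score > control score), ties count half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC needs both classes present")
    r = rankdata(scores)
    return float((r[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def mann_whitney_u(x, y) -> float:
    """U statistic counting the second sample's wins (ties half)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = rankdata(np.concatenate([x, y]))
    ry = r[len(x):].sum()
    return float(ry - len(y) * (len(y) + 1) / 2)


def group_difference_test(
    values, labels, alpha_normality: float = 0.05, equal_var: bool = False
) -> tuple[float, str]:
    """Two-group location test with a Shapiro-Wilk normality gate.

    Both groups normal at ``alpha_normality`` -> unpaired two-sample t-test
    (Welch by default, pooled with ``equal_var=True``); otherwise the
    Mann-Whitney U test (exact vs asymptotic chosen by scipy's policy, with
    tie correction).  Returns (p_value, test_used).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    a = values[labels == 0]
    b = values[labels == 1]
    if min(len(a), len(b)) < 3:
        raise ValueError("need at least 3 subjects per group")
    if np.ptp(values) == 0.0:
        return 1.0, "mann-whitney"

    def _normal(sample):
        if np.ptp(sample) == 0.0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return shapiro(sample).pvalue > alpha_normality

    if _normal(a) and _normal(b):
        res = ttest_ind(a, b, equal_var=equal_var)
        return float(res.pvalue), "t-welch" if not equal_var else "t-pooled"
    res = mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue), "mann-whitney"


# ---------------------------------------------------------------------------
# logistic scoring


def fit_logistic(X, y, cap: float = COEF_CAP, tol: float = 1e-8, max_iter: int = 60):
    """Unpenalized logistic regression (intercept + features) by Newton-IRLS.

    Coefficients are capped at ``cap`` in absolute value, which bounds the
    fit under complete separation instead of diverging.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    A = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    capped = False
    for _ in range(max_iter):
        mu = expit(A @ beta)
        W = mu * (1 - mu) + 1e-12
        g = A.T @ (y - mu)
        H = (A * W[:, None]).T @ A
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.any(np.abs(beta) > cap):
            beta = np.clip(beta, -cap, cap)
            capped = True
        if np.max(np.abs(step)) < tol:
            break
    if capped:
        warnings.warn("logistic coefficients capped (separation guard)", stacklevel=2)
    return beta


def loocv_logistic(features, labels, cap: float = COEF_CAP) -> ScoreVector:
    """Pooled leave-one-out held-out probabilities of a logistic model.

    For each subject the model is refitted on the other n-1 subjects
    (features standardized inside the training fold) and the held-out
    predicted probability recorded.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and X.size > 2:
        X = X.T
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 10:
        raise ValueError("LOOCV needs at least 10 subjects")
    if X.shape[1] > 2:
        raise ValueError("univariate or two-descriptor models only")
    probs = np.empty(n)
    idx = np.arange(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            m = idx != i
            mu = X[m].mean(axis=0)
            sd = X[m].std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            beta = fit_logistic((X[m] - mu) / sd, y[m], cap=cap)
            xi = (X[i] - mu) / sd
            probs[i] = expit(beta[0] + xi @ beta[1:])
    return ScoreVector(scores=probs, labels=y)


def _lpo_auroc(X, y, cap=COEF_CAP, tol=1e-6, max_iter=30) -> float:
    """Leave-pair-out CV AUROC; all pair models fitted by batched IRLS."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    cases = np.flatnonzero(y == 1)
    ctrls = np.flatnonzero(y == 0)
    if len(cases) == 0 or len(ctrls) == 0:
        raise ValueError("both classes required")
    I, J = np.meshgrid(cases, ctrls, indexing="ij")
    I = I.ravel()
    J = J.ravel()
    P = len(I)
    mask = np.ones((P, n))
    mask[np.arange(P), I] = 0.0
    mask[np.arange(P), J] = 0.0
    msum = mask.sum(1)[:, None]
    xm = (mask @ X) / msum  # (P, p)
    xc = X[None, :, :] - xm[:, None, :]
    var = np.einsum("pn,pnf->pf", mask, xc**2) / (msum - 1)
    sd = np.sqrt(var)
    sd[sd == 0] = 1.0
    Xs = xc / sd[:, None, :]
    D = np.concatenate([np.ones((P, n, 1)), Xs], axis=2)  # (P, n, p+1)
    Dt = np.ascontiguousarray(D.transpose(0, 2, 1))
    # warm start from the full-sample fit (pair folds differ by 2 subjects)
    mu_full = X.mean(axis=0)
    sd_full = X.std(axis=0, ddof=1)
    sd_full[sd_full == 0] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        beta0 = fit_logistic((X - mu_full) / sd_full, y, cap=cap, tol=1e-6)
    beta = np.broadcast_to(beta0, (P, p + 1)).copy()
    for _ in range(max_iter):
        eta = (D @ beta[..., None])[..., 0]
        mu = expit(eta)
        w = mask * (mu * (1 - mu) + 1e-12)
        r = mask * (y[None, :] - mu)
        g = (Dt @ r[..., None])[..., 0]
        H = Dt @ (D * w[..., None])
        step = np.linalg.solve(H, g[..., None])[..., 0]
        beta = np.clip(beta + step, -cap, cap)
        if np.max(np.abs(step)) < tol:
            break
    rows = np.arange(P)
    si = np.einsum("pf,pf->p", D[rows, I], beta)
    sj = np.einsum("pf,pf->p", D[rows, J], beta)
    return float((np.sum(si > sj) + 0.5 * np.sum(si == sj)) / P)


def cv_auroc(features, labels, method: str = "leave_pair_out") -> float:
    """Cross-validated logistic AUROC for 1-2 descriptor columns."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1 and X.size > 2:
        X = X.T
    if X.shape[1] > 2:
        raise ValueError("univariate or two-descriptor models only")
    y = np.asarray(labels, dtype=int)
    if method == "leave_pair_out":
        return _lpo_auroc(X, y)
    if method == "pooled_loo":
        sv = loocv_logistic(X, y)
        return auroc(sv.scores, sv.labels)
    raise ValueError(f"unknown CV AUROC method '{method}'")


# ---------------------------------------------------------------------------
# DeLong


def _placements(scores, labels):
    x = scores[labels == 1]
    yv = scores[labels == 0]
    comp = (x[:, None] > yv[None, :]).astype(float) + 0.5 * (
        x[:, None] == yv[None, :]
    )
    v10 = comp.mean(axis=1)
    v01 = comp.mean(axis=0)
    return v10, v01, comp.mean()


def delong_variance(scores, labels) -> float:
    """DeLong variance estimate of a single empirical AUROC."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    v10, v01, _ = _placements(scores, labels)
    m, n = len(v10), len(v01)
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_test(scores_a, scores_b, labels):
    """Paired DeLong comparison of two AUROCs on the same subjects.

    Returns ``(auc_a, auc_b, z, p)``; identical score rankings give zero
    difference variance and p = 1.
    """
    labels = np.asarray(labels, dtype=int)
    a10, a01, auc_a = _placements(np.asarray(scores_a, float), labels)
    b10, b01, auc_b = _placements(np.asarray(scores_b, float), labels)
    m, n = len(a10), len(a01)
    s10 = np.cov(np.vstack([a10, b10]), ddof=1)
    s01 = np.cov(np.vstack([a01, b01]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 1e-16:
        return float(auc_a), float(auc_b), 0.0, 1.0
    z = diff / np.sqrt(var)
    p = float(2 * norm.sf(abs(z)))
    return float(auc_a), float(auc_b), float(z), p


# ---------------------------------------------------------------------------
# reports


@dataclass
class DiscriminationReport:
    """Summary (means +/- SD, difference tests) and AUROC tables."""

    summary: pd.DataFrame
    auroc_table: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _parse_combination(combo) -> tuple:
    if isinstance(combo, str):
        return tuple(c.strip() for c in combo.split("+"))
    return tuple(combo)


def build_reports(
    cohort: pd.DataFrame,
    combinations=(),
    references=("aBMD_gcm2", "vBMD_trab_mgcm3"),
    estimator: str = "leave_pair_out",
) -> DiscriminationReport:
    """Summary and AUROC reports for a labelled descriptor cohort.

    ``cohort`` needs a ``group`` column ('control'/'fracture') plus numeric
    descriptor columns.  ``combinations`` are descriptor pairs (tuples or
    'A+B' strings) fitted as two-feature logistic models.  DeLong p-values
    against each reference descriptor are computed on the pooled LOOCV
    probability vectors, which provide the paired per-subject scores the
    test requires.
    """
    if "group" not in cohort:
        raise KeyError("cohort lacks the 'group' column")
    labels = (cohort["group"] == "fracture").to_numpy().astype(int)
    desc_cols = [
        c
        for c in cohort.columns
        if c not in ("subject_id", "group")
        and np.issubdtype(cohort[c].dtype, np.number)
    ]
    for ref in references:
        if ref not in cohort.columns:
            raise KeyError(f"reference descriptor '{ref}' missing from cohort")

    rows = []
    for c in desc_cols:
        v = cohort[c].to_numpy(dtype=float)
        p, test = group_difference_test(v, labels)
        rows.append(
            dict(
                descriptor=c,
                control_mean=v[labels == 0].mean(),
                control_sd=v[labels == 0].std(ddof=1),
                fracture_mean=v[labels == 1].mean(),
                fracture_sd=v[labels == 1].std(ddof=1),
                p_value=p,
                test=test,
            )
        )
    summary = pd.DataFrame(rows)

    ref_scores = {
        ref: loocv_logistic(cohort[ref].to_numpy(dtype=float), labels).scores
        for ref in references
    }
    entries = [(c, (c,)) for c in desc_cols] + [
        ("+".join(_parse_combination(cb)), _parse_combination(cb))
        for cb in combinations
    ]
    arows = []
    for name, cols in entries:
        missing = [c for c in cols if c not in cohort.columns]
        if missing:
            raise KeyError(f"descriptor column '{missing[0]}' missing from cohort")
        Xc = cohort[list(cols)].to_numpy(dtype=float)
        a = cv_auroc(Xc, labels, method=estimator)
        scores = loocv_logistic(Xc, labels).scores
        row = dict(descriptor=name, AUROC=a)
        for ref in references:
            _, _, _, p = delong_test(scores, ref_scores[ref], labels)
            row[f"p_vs_{ref}"] = p
        arows.append(row)
    auroc_table = pd.DataFrame(arows)
    return DiscriminationReport(
        summary=summary,
        auroc_table=auroc_table,
        metadata=dict(
            estimator=estimator,
            normality_gate="shapiro-wilk, alpha=0.05",
            references=list(references),
            n=len(cohort),
        ),
    )
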