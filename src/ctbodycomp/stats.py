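"""Cohort risk statistics: Mann-Whitney U, logistic regression, ROC, 2×2.

The statistical layer mirrors a univariate-then-multivariate workflow:
continuous imaging parameters are compared between endpoint groups with
the two-sided Mann-Whitney U test, the jointly informative predictors
(sarcopenia, visceral fat area, duct diameter) enter a binary logistic
regression reported as odds ratios with 95% Wald intervals, and
discrimination is summarized by ROC curves whose AUC is computed through
the Mann-Whitney identity AUC = U / (n₁·n₂) with ties counted ½.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .composition import PatientRecord


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------- formatting

def format_percent(count: int, total: int, mode: str = "half-up") -> str:
    """One-decimal percentage formatter.

    ``half-up`` rounds 12.857 → "12.9"; ``truncate`` drops the second
    decimal (12.857 → "12.8").  Half-up is the default because it matches
    the majority of conventionally printed clinical tables.
    """
    if total <= 0:
        raise StatsError("total must be > 0")
    pct = 100.0 * count / total
    if mode == "truncate":
        # scale in exact decimal space to avoid 33.3*10 = 332.999… artifacts
        v = math.floor(round(pct * 1000) / 100) / 10.0
    elif mode == "half-up":
        v = math.floor(round(pct * 1000) / 100 + 0.5) / 10.0
    else:
        raise StatsError(f"unknown mode {mode!r}")
    return f"{v:.1f}"


def format_p(p: float) -> str:
    """Render a p-value the way clinical tables print it: ``p < x.xx``
    with the bound being the value rounded *up* to two decimals."""
    if not 0.0 <= p <= 1.0:
        raise StatsError("p must lie in [0, 1]")
    bound = math.ceil(p * 100 - 1e-12) / 100
    bound = max(bound, 0.01)
    return f"p < {bound:.2f}"


# ------------------------------------------------------------- Mann-Whitney

@dataclass(frozen=True)
class GroupComparison:
    variable: str
    n1: int
    n2: int
    median1: float
    median2: float
    range1: tuple[float, float]
    range2: tuple[float, float]
    u: float
    p: float
    method: str

    def __post_init__(self):
        if not 0 <= self.u <= self.n1 * self.n2:
            raise StatsError("U outside [0, n1*n2]")


def mann_whitney(
    group1: Sequence[float], group2: Sequence[float], variable: str = ""
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    Uses the exact null distribution when n₁+n₂ ≤ 12 and the pooled data
    are tie-free, otherwise the normal approximation with tie and
    continuity corrections.  A pooled-constant input yields p = 1.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0:
        u, p, method = x.size * y.size / 2.0, 1.0, "degenerate"
    elif x.size + y.size <= 12 and not has_ties:
        res = _sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        u, p, method = float(res.statistic), float(res.pvalue), "exact"
    else:
        res = _sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        u, p, method = float(res.statistic), float(res.pvalue), "asymptotic"
    return GroupComparison(
        variable=variable,
        n1=int(x.size),
        n2=int(y.size),
        median1=float(np.median(x)),
        median2=float(np.median(y)),
        range1=(float(x.min()), float(x.max())),
        range2=(float(y.min()), float(y.max())),
        u=u,
        p=min(p, 1.0),
        method=method,
    )


# ---------------------------------------------------------------- logistic

@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood binary logistic fit (IRLS / Newton-Raphson)."""

    predictors: tuple[str, ...]
    coef: np.ndarray  # log-odds, intercept first
    se: np.ndarray
    n: int
    converged: bool
    separation: bool
    loglik: float
    loglik_path: tuple[float, ...]
    max_grad: float
    ci_level: float = 0.95

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def conf_int(self) -> np.ndarray:
        """(k, 2) Wald interval bounds on the odds-ratio scale."""
        z = _sps.norm.ppf(0.5 + self.ci_level / 2.0)
        # exponent clipped: a separated fit's half-infinite interval is
        # reported as a huge finite bound rather than overflowing
        lo = np.exp(np.clip(self.coef - z * self.se, -700, 700))
        hi = np.exp(np.clip(self.coef + z * self.se, -700, 700))
        return np.column_stack([lo, hi])

    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2.0 * _sps.norm.sf(np.abs(z))

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "predictor": self.predictors,
            "coef": self.coef,
            "se": self.se,
            "or": self.odds_ratios,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": self.p_values(),
        })


def _expit(eta):
    from scipy.special import expit

    return expit(eta)


def _loglik(y, eta):
    # numerically safe Bernoulli log-likelihood: sum y*eta - log(1+e^eta)
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(
    outcome: Sequence[int],
    predictors: pd.DataFrame | dict,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Fit P(y=1) = expit(b0 + Xb) by iteratively reweighted least squares.

    Newton steps with step-halving guarantee a non-decreasing likelihood
    path; the fit is declared converged when the score (gradient) max-norm
    drops below 1e-6.  Runaway coefficients or fitted probabilities pinned
    at 0/1 on a perfectly separated sample are reported through the
    ``separation`` flag instead of being returned as if they were stable
    estimates.
    """
    X = pd.DataFrame(predictors)
    names = ("intercept", *map(str, X.columns))
    y = np.asarray(outcome, dtype=float)
    if y.ndim != 1 or len(y) != len(X):
        raise StatsError("outcome and predictors must align")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise StatsError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise StatsError("outcome has a single class; logistic fit undefined")
    A = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
    n, k = A.shape
    if n <= k:
        raise StatsError(f"need n > {k} observations for {k - 1} predictors")

    beta = np.zeros(k)
    path = [_loglik(y, A @ beta)]
    converged = False
    for _ in range(max_iter):
        eta = A @ beta
        mu = _expit(eta)
        w = mu * (1.0 - mu)
        grad = A.T @ (y - mu)
        if np.max(np.abs(grad)) < 1e-6 and len(path) > 1:
            converged = True
            break
        H = A.T @ (A * np.maximum(w, 1e-12)[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step-halve until the likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll = _loglik(y, A @ cand)
            if ll >= path[-1] - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        path.append(_loglik(y, A @ beta))
        if np.abs(path[-1] - path[-2]) < tol and np.max(np.abs(grad)) < 1e-6:
            converged = True
            break

    eta = A @ beta
    mu = _expit(eta)
    grad = A.T @ (y - mu)
    max_grad = float(np.max(np.abs(grad)))
    converged = converged or max_grad < 1e-6
    separation = bool(np.max(np.abs(beta)) > 30.0) or (
        not converged and (mu[y == 1].min() > 0.999 or mu[y == 0].max() < 0.001)
    )
    w = np.maximum(mu * (1 - mu), 1e-12)
    cov = np.linalg.inv(A.T @ (A * w[:, None]))
    se = np.sqrt(np.diag(cov))
    return LogisticFit(
        predictors=names,
        coef=beta,
        se=se,
        n=n,
        converged=converged and not separation,
        separation=separation,
        loglik=path[-1],
        loglik_path=tuple(path),
        max_grad=max_grad,
    )


# --------------------------------------------------------------------- ROC

@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray  # 1 - specificity
    tpr: np.ndarray  # sensitivity
    auc: float
    lower_is_positive: bool
    n_pos: int
    n_neg: int


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    lower_is_positive: bool = False,
) -> RocResult:
    """ROC curve and AUC via the rank (Mann-Whitney) statistic.

    ``lower_is_positive=True`` orients the curve so that *low* scores
    predict the event — the convention needed for muscle attenuation and
    duct diameter, which are risk factors when small.  Tied score pairs
    count ½, making the AUC exactly U/(n₁·n₂).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise StatsError("scores and labels must be equal-length vectors")
    if set(np.unique(y)) - {0, 1}:
        raise StatsError("labels must be binary 0/1")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise StatsError("both classes must be present")
    oriented = -s if lower_is_positive else s
    ranks = _sps.rankdata(oriented)  # mid-ranks: ties get the ½ convention
    u = float(ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0)
    auc = u / (n_pos * n_neg)

    order = np.argsort(-oriented, kind="mergesort")
    ys = y[order]
    ss = oriented[order]
    distinct = np.r_[np.diff(ss) != 0, True]
    tps = np.cumsum(ys)[distinct]
    fps = np.cumsum(1 - ys)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, ss[distinct]]
    return RocResult(
        thresholds=thresholds,
        fpr=fpr,
        tpr=tpr,
        auc=auc,
        lower_is_positive=lower_is_positive,
        n_pos=n_pos,
        n_neg=n_neg,
    )


# --------------------------------------------------------------------- 2×2

@dataclass(frozen=True)
class TwoByTwo:
    """Counts of an exposure × event cross-table with row percentages."""

    exposed_event: int
    exposed_nonevent: int
    unexposed_event: int
    unexposed_nonevent: int
    percent_mode: str = "half-up"

    def __post_init__(self):
        if min(self.exposed_event, self.exposed_nonevent,
               self.unexposed_event, self.unexposed_nonevent) < 0:
            raise StatsError("counts must be >= 0")

    @property
    def n_exposed(self) -> int:
        return self.exposed_event + self.exposed_nonevent

    @property
    def n_unexposed(self) -> int:
        return self.unexposed_event + self.unexposed_nonevent

    def row_percent_exposed(self) -> str:
        return format_percent(self.exposed_event, self.n_exposed, self.percent_mode)

    def row_percent_unexposed(self) -> str:
        return format_percent(self.unexposed_event, self.n_unexposed, self.percent_mode)

    def odds_ratio(self) -> float:
        """Cross-product OR; Haldane-Anscombe +0.5 when any cell is zero."""
        a, b = self.exposed_event, self.exposed_nonevent
        c, d = self.unexposed_event, self.unexposed_nonevent
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        return (a * d) / (b * c)


def two_by_two(
    records: Sequence[PatientRecord],
    exposure: Callable[[PatientRecord], Optional[bool]],
    event: Callable[[PatientRecord], bool],
    percent_mode: str = "half-up",
) -> TwoByTwo:
    """Cross-tabulate an exposure predicate against an event predicate.

    Records where the exposure predicate returns ``None`` (e.g. an
    unmeasurable duct) are excluded rather than forced into a row.
    """
    if not records:
        raise StatsError("records must be non-empty")
    cells = [0, 0, 0, 0]
    for r in records:
        e = exposure(r)
        if e is None:
            continue
        ev = bool(event(r))
        idx = (0 if e else 2) + (0 if ev else 1)
        cells[idx] += 1
    return TwoByTwo(*cells, percent_mode=percent_mode)


# ------------------------------------------------------------------ report

_TABLE_VARS = [
    ("a_vat_cm2", "A_VAT [cm2]"), ("a_mpso_cm2", "A_MPSO [cm2]"),
    ("a_mspi_cm2", "A_MSPI [cm2]"), ("a_mven_cm2", "A_MVEN [cm2]"),
    ("a_mtot_cm2", "A_MTOT [cm2]"), ("ma_hu", "MA [HU]"),
    ("smi_cm2_m2", "SMI [cm2/m2]"), ("dpp_mm", "DPP [mm]"), ("dpd_mm", "DPD [mm]"),
]


def summarize_cohort(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Univariate risk-factor table over both endpoints.

    For every imaging parameter and endpoint (major complication; severe
    POPF): per-group median and range plus the Mann-Whitney p; sarcopenia
    is reported as counts per group.  Missing continuous values (e.g.
    unmeasurable ducts) are dropped pairwise.
    """
    from .cohort import cohort_to_frame

    if not records:
        raise StatsError("records must be non-empty")
    df = cohort_to_frame(list(records))
    df["major"] = [r.major_complication for r in records]
    df["popf_severe"] = [r.severe_popf for r in records]
    rows = []
    for endpoint in ("major", "popf_severe"):
        g = df[endpoint].astype(bool)
        for col, label in _TABLE_VARS:
            vals = df[col].astype(float)
            x = vals[~g].dropna()
            y = vals[g].dropna()
            if len(x) == 0 or len(y) == 0:
                continue
            cmp = mann_whitney(x, y, variable=label)
            rows.append({
                "endpoint": endpoint, "variable": label,
                "n_noevent": cmp.n1, "n_event": cmp.n2,
                "median_noevent": cmp.median1, "median_event": cmp.median2,
                "min_noevent": cmp.range1[0], "max_noevent": cmp.range1[1],
                "min_event": cmp.range2[0], "max_event": cmp.range2[1],
                "U": cmp.u, "p": cmp.p, "p_printed": format_p(cmp.p),
            })
        n_sarc_no = int(df.loc[~g, "sarcopenic"].sum())
        n_sarc_yes = int(df.loc[g, "sarcopenic"].sum())
        rows.append({
            "endpoint": endpoint, "variable": "sarcopenic [n]",
            "n_noevent": int((~g).sum()), "n_event": int(g.sum()),
            "median_noevent": n_sarc_no, "median_event": n_sarc_yes,
            "min_noevent": np.nan, "max_noevent": np.nan,
            "min_event": np.nan, "max_event": np.nan,
            "U": np.nan, "p": np.nan, "p_printed": "",
        })
    return pd.DataFrame(rows)
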