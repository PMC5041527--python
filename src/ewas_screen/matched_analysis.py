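"""Per-variable association tests over matched strata.

Binary variables are tested with the Cochran-Mantel-Haenszel chi-square
(1 df, two-sided, no continuity correction) together with the
Mantel-Haenszel common odds ratio and its Robins-Breslow-Greenland 95 % CI.
Ordinal variables are tested with conditional logistic regression: the
exposure enters linearly on its [0, 1] encoding, so exp(coefficient) is the
odds ratio between the two extreme responses.

Both tests operate on plain arrays (case/control status, exposure, integer
stratum labels) so they serve the matched analysis (strata of size 2-3, one
case each) and the propensity analysis (decile strata) alike.  For strata
containing a single case the conditional likelihood is maximized by a
dedicated Newton solver (exact, vectorized over strata); strata with several
cases are delegated to statsmodels' conditional logit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TestResult",
    "StratifiedTable",
    "cmh_test",
    "conditional_logit",
    "run_matched_screen",
    "results_to_frame",
]

STATUS_OK = "ok"
STATUS_DEGENERATE = "degenerate"
STATUS_NONCONVERGED = "nonconverged"
STATUS_FILTERED = "filtered"

Z975 = stats.norm.ppf(0.975)


@dataclass
class TestResult:
    """Outcome of one per-variable association test."""

    variable_id: str
    analysis: str  # "matched" or "propensity"
    p_value: float = np.nan
    effect_size: float = np.nan  # odds-ratio scale (extreme responses for ordinal)
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_cases_used: int = 0
    n_controls_used: int = 0
    missing_pct_cases: float = np.nan
    missing_pct_controls: float = np.nan
    status: str = STATUS_OK
    statistic: float = np.nan
    n_strata_used: int = 0
    n_strata_dropped: int = 0
    effective_k: int | None = None
    rf_seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "variable_id": self.variable_id,
            "analysis": self.analysis,
            "p_value": self.p_value,
            "effect_size": self.effect_size,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_cases": self.n_cases_used,
            "n_controls": self.n_controls_used,
            "missing_case_pct": self.missing_pct_cases,
            "missing_control_pct": self.missing_pct_controls,
            "status": self.status,
            "statistic": self.statistic,
            "n_strata_used": self.n_strata_used,
            "n_strata_dropped": self.n_strata_dropped,
            "effective_k": self.effective_k,
            "rf_seed": self.rf_seed,
        }


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    frame = pd.DataFrame([r.to_dict() for r in results])
    if frame.empty:
        frame = pd.DataFrame(
            columns=list(TestResult("", "").to_dict().keys())
        )
    return frame


@dataclass
class StratifiedTable:
    """Per-stratum 2x2 counts (exposure x status) for a binary variable.

    ``a``: exposed cases, ``b``: exposed controls, ``c``: unexposed cases,
    ``d``: unexposed controls — one entry per informative stratum.  Strata
    whose case (or every control) had a missing exposure are excluded before
    construction and counted in ``n_dropped``.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    n_dropped: int = 0

    @classmethod
    def from_arrays(
        cls,
        is_case: np.ndarray,
        exposure: np.ndarray,
        strata: np.ndarray,
    ) -> "StratifiedTable":
        """Build per-stratum counts from flat arrays.

        Missing exposures (NaN) are dropped; strata left with no case or no
        control are dropped entirely and counted.
        """
        is_case = np.asarray(is_case, dtype=bool)
        exposure = np.asarray(exposure, dtype=float)
        strata = np.asarray(strata)
        ok = np.isfinite(exposure)
        vals = np.unique(exposure[ok])
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("binary exposure must be coded 0/1")
        codes, _ = pd.factorize(strata, sort=False)
        n_strata = codes.max() + 1 if codes.size else 0
        w = ok.astype(float)
        exp1 = np.where(ok, exposure, 0.0)
        a = np.bincount(codes, weights=w * is_case * exp1, minlength=n_strata)
        c = np.bincount(codes, weights=w * is_case * (1 - exp1), minlength=n_strata)
        b = np.bincount(codes, weights=w * ~is_case * exp1, minlength=n_strata)
        d = np.bincount(codes, weights=w * ~is_case * (1 - exp1), minlength=n_strata)
        keep = ((a + c) > 0) & ((b + d) > 0)
        return cls(a=a[keep], b=b[keep], c=c[keep], d=d[keep],
                   n_dropped=int((~keep).sum()))

    @property
    def n_strata(self) -> int:
        return len(self.a)


def _cmh_from_counts(tab: StratifiedTable) -> tuple[float, float]:
    """CMH chi-square statistic and its variance denominator."""
    a, b, c, d = tab.a, tab.b, tab.c, tab.d
    T = a + b + c + d
    n1 = a + c  # cases
    n0 = b + d  # controls
    m1 = a + b  # exposed
    m0 = c + d  # unexposed
    usable = T > 1
    T, n1, n0, m1, m0, a = (x[usable] for x in (T, n1, n0, m1, m0, a))
    expected = n1 * m1 / T
    var = n1 * n0 * m1 * m0 / (T * T * (T - 1))
    num = float(np.sum(a - expected))
    den = float(np.sum(var))
    if den <= 0:
        return 0.0, 0.0
    return num * num / den, den


def _mh_odds_ratio(tab: StratifiedTable) -> tuple[float, float, float]:
    """Mantel-Haenszel common OR with a Robins-Breslow-Greenland 95 % CI.

    Returns (or, ci_low, ci_high); NaNs where undefined.
    """
    a, b, c, d = tab.a, tab.b, tab.c, tab.d
    T = a + b + c + d
    ok = T > 0
    a, b, c, d, T = (x[ok] for x in (a, b, c, d, T))
    R_i = a * d / T
    S_i = b * c / T
    R, S = float(R_i.sum()), float(S_i.sum())
    if R == 0 and S == 0:
        return np.nan, np.nan, np.nan
    if S == 0:
        return np.inf, np.nan, np.nan
    if R == 0:
        return 0.0, np.nan, np.nan
    or_mh = R / S
    P = (a + d) / T
    Q = (b + c) / T
    var_log = (
        float((P * R_i).sum()) / (2 * R * R)
        + float((P * S_i + Q * R_i).sum()) / (2 * R * S)
        + float((Q * S_i).sum()) / (2 * S * S)
    )
    se = np.sqrt(var_log)
    log_or = np.log(or_mh)
    return or_mh, float(np.exp(log_or - Z975 * se)), float(np.exp(log_or + Z975 * se))


def cmh_test(
    table: StratifiedTable,
    variable_id: str = "",
    analysis: str = "matched",
) -> TestResult:
    """Cochran-Mantel-Haenszel test of conditional association.

    No continuity correction; two-sided p from chi-square(1).  Fully
    concordant strata contribute zero.  With no informative stratum the
    statistic is 0 and p = 1 but no estimate is produced (degenerate).
    """
    res = TestResult(variable_id=variable_id, analysis=analysis)
    res.n_strata_used = table.n_strata
    res.n_strata_dropped = table.n_dropped
    res.n_cases_used = int((table.a + table.c).sum())
    res.n_controls_used = int((table.b + table.d).sum())
    stat, var = _cmh_from_counts(table)
    or_mh, lo, hi = _mh_odds_ratio(table)
    if var <= 0:
        res.status = STATUS_DEGENERATE
        res.statistic = 0.0
        res.p_value = 1.0
        return res
    res.statistic = stat
    res.p_value = float(stats.chi2.sf(stat, df=1))
    if not np.isfinite(or_mh) or or_mh == 0.0:
        res.status = STATUS_DEGENERATE  # MH estimator undefined; p still valid
        res.effect_size = or_mh
        return res
    res.effect_size = or_mh
    res.ci_low, res.ci_high = lo, hi
    return res


# ---------------------------------------------------------------------------
# Conditional logistic regression
# ---------------------------------------------------------------------------

def _clogit_one_case_newton(
    X: np.ndarray,
    is_case: np.ndarray,
    codes: np.ndarray,
    n_strata: int,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool, float]:
    """Newton-Raphson maximization of the conditional likelihood when every
    stratum contains exactly one case.

    Per stratum the likelihood is exp(x_case'b) / sum_j exp(x_j'b); the score
    and information follow from the within-stratum weighted moments, which
    are accumulated with bincount so the solver is O(n) per iteration.

    Returns (beta, covariance, converged, loglik).
    """
    n, p = X.shape
    beta = np.zeros(p)

    def moments(beta):
        eta = X @ beta
        eta = eta - eta.max()  # global shift cancels within strata
        w = np.exp(eta)
        S0 = np.bincount(codes, weights=w, minlength=n_strata)
        S1 = np.empty((n_strata, p))
        for j in range(p):
            S1[:, j] = np.bincount(codes, weights=w * X[:, j], minlength=n_strata)
        M2 = np.empty((n_strata, p, p))
        for j in range(p):
            for k in range(j, p):
                m = np.bincount(
                    codes, weights=w * X[:, j] * X[:, k], minlength=n_strata
                )
                M2[:, j, k] = m
                M2[:, k, j] = m
        return w, S0, S1, M2

    def loglik_of(beta):
        eta = X @ beta
        ll = float(eta[is_case].sum())
        shift = np.full(n_strata, -np.inf)
        np.maximum.at(shift, codes, eta)
        w = np.exp(eta - shift[codes])
        S0 = np.bincount(codes, weights=w, minlength=n_strata)
        ll -= float((np.log(S0) + shift).sum())
        return ll

    ll = loglik_of(beta)
    converged = False
    for _ in range(max_iter):
        w, S0, S1, M2 = moments(beta)
        E = S1 / S0[:, None]  # per-stratum weighted mean of X
        grad = X[is_case].sum(axis=0) - E.sum(axis=0)
        H = -(M2 / S0[:, None, None] - E[:, :, None] * E[:, None, :]).sum(axis=0)
        # H is negative semidefinite; information = -H
        info = -H
        if not np.all(np.isfinite(info)) or np.linalg.cond(info) > 1e12:
            return beta, np.full((p, p), np.nan), False, ll
        step = np.linalg.solve(info, grad)
        # step halving to guarantee ascent
        for _ in range(30):
            candidate = beta + step
            ll_new = loglik_of(candidate)
            if ll_new >= ll - 1e-12:
                break
            step = step / 2
        else:
            return beta, np.linalg.inv(info), False, ll
        delta = np.max(np.abs(step)) / max(1.0, np.max(np.abs(candidate)))
        beta, ll = candidate, ll_new
        if delta < tol:
            converged = True
            break
    if np.max(np.abs(beta)) > 25:  # separation: estimate diverging
        converged = False
    _, S0, S1, M2 = moments(beta)
    E = S1 / S0[:, None]
    info = (M2 / S0[:, None, None] - E[:, :, None] * E[:, None, :]).sum(axis=0)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, cov, converged, ll


def _clogit_general(X, is_case, codes) -> tuple[np.ndarray, np.ndarray, bool]:
    """Conditional logit for strata with several cases (statsmodels)."""
    from statsmodels.discrete.conditional_models import ConditionalLogit

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ConditionalLogit(is_case.astype(float), X, groups=codes)
        try:
            fit = model.fit(disp=0, maxiter=200)
        except Exception:
            return np.full(X.shape[1], np.nan), np.full((X.shape[1],) * 2, np.nan), False
    retvals = getattr(fit, "mle_retvals", None) or {}
    converged = bool(retvals.get("converged", True))
    return np.asarray(fit.params), np.asarray(fit.cov_params()), converged


def conditional_logit(
    is_case: np.ndarray,
    exposure: np.ndarray,
    strata: np.ndarray,
    covariates: np.ndarray | None = None,
    variable_id: str = "",
    analysis: str = "matched",
) -> TestResult:
    """Conditional logistic regression of case status on an encoded exposure.

    Complete cases only (jointly on exposure and covariates).  Strata left
    without both a case and a control, or with no within-stratum variation in
    any column, contribute nothing and are dropped.  The reported effect is
    exp(beta_exposure): since exposures are encoded on [0, 1], this is the
    odds ratio between the two extreme responses.  Wald CI and p-value.
    """
    is_case = np.asarray(is_case, dtype=bool)
    exposure = np.asarray(exposure, dtype=float)
    strata = np.asarray(strata)
    if covariates is None:
        X = exposure[:, None]
    else:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != len(exposure):
            covariates = covariates.T
        X = np.column_stack([exposure, covariates])

    res = TestResult(variable_id=variable_id, analysis=analysis)
    ok = np.all(np.isfinite(X), axis=1)
    X, is_case_f, strata_f = X[ok], is_case[ok], strata[ok]
    codes, _ = pd.factorize(strata_f, sort=False)
    n_strata = codes.max() + 1 if codes.size else 0

    # drop strata without both statuses present
    n_cases_s = np.bincount(codes, weights=is_case_f.astype(float), minlength=n_strata)
    n_tot_s = np.bincount(codes, minlength=n_strata)
    informative = (n_cases_s > 0) & (n_cases_s < n_tot_s)
    keep = informative[codes]
    res.n_strata_dropped = int((~informative).sum())
    X, is_case_f = X[keep], is_case_f[keep]
    codes, _ = pd.factorize(codes[keep], sort=False)
    n_strata = codes.max() + 1 if codes.size else 0
    res.n_strata_used = n_strata
    res.n_cases_used = int(is_case_f.sum())
    res.n_controls_used = int((~is_case_f).sum())

    if n_strata == 0:
        res.status = STATUS_DEGENERATE
        return res

    # within-stratum variation of the exposure is required
    means = np.bincount(codes, weights=X[:, 0], minlength=n_strata) / np.bincount(
        codes, minlength=n_strata
    )
    within_var = float(np.sum((X[:, 0] - means[codes]) ** 2))
    if within_var <= 0:
        res.status = STATUS_DEGENERATE
        return res

    one_case = bool(np.all(n_cases_s[informative] == 1))
    if one_case:
        beta, cov, converged, _ = _clogit_one_case_newton(X, is_case_f, codes, n_strata)
    else:
        beta, cov, converged = _clogit_general(X, is_case_f, codes)

    if not converged or not np.all(np.isfinite(beta)) or not np.isfinite(cov[0, 0]):
        res.status = STATUS_NONCONVERGED
        return res

    b = float(beta[0])
    se = float(np.sqrt(cov[0, 0]))
    res.statistic = (b / se) ** 2 if se > 0 else np.nan
    res.p_value = float(2 * stats.norm.sf(abs(b) / se)) if se > 0 else np.nan
    res.effect_size = float(np.exp(b))
    res.ci_low = float(np.exp(b - Z975 * se))
    res.ci_high = float(np.exp(b + Z975 * se))
    return res


# ---------------------------------------------------------------------------
# Screen driver
# ---------------------------------------------------------------------------

def run_matched_screen(
    sample,
    matrix: pd.DataFrame,
    spec,
    variables: Sequence[str] | None = None,
) -> list[TestResult]:
    """Test every variable over the matched strata.

    ``sample`` is a collection of :class:`~.questionnaire_model.MatchedStratum`;
    ``matrix`` the encoded response table.  Binary variables go to
    :func:`cmh_test`, ordinal ones to :func:`conditional_logit`.  One
    :class:`TestResult` per variable, ordered by variable_id.  ``variables``
    restricts the screen (the ids kept by the sd filter); by default every
    column of the matrix is tested.
    """
    member_ids: list[str] = []
    status_list: list[bool] = []
    stratum_list: list[int] = []
    for k, stratum in enumerate(sample):
        for pid in stratum.member_ids:
            member_ids.append(pid)
            status_list.append(pid == stratum.case_id)
            stratum_list.append(k)
    is_case = np.array(status_list, dtype=bool)
    strata = np.array(stratum_list, dtype=int)

    sub = matrix.reindex(member_ids)
    values = sub.to_numpy(dtype=float)
    columns = list(sub.columns)

    if variables is None:
        variables = columns
    todo = sorted(variables)
    col_index = {c: i for i, c in enumerate(columns)}

    results = []
    n_cases = max(int(is_case.sum()), 1)
    n_controls = max(int((~is_case).sum()), 1)
    for var in todo:
        x = values[:, col_index[var]]
        missing_cases = 100.0 * np.sum(~np.isfinite(x[is_case])) / n_cases
        missing_controls = 100.0 * np.sum(~np.isfinite(x[~is_case])) / n_controls
        if spec[var].kind == "binary":
            tab = StratifiedTable.from_arrays(is_case, x, strata)
            res = cmh_test(tab, variable_id=var, analysis="matched")
        else:
            res = conditional_logit(
                is_case, x, strata, variable_id=var, analysis="matched"
            )
        res.missing_pct_cases = missing_cases
        res.missing_pct_controls = missing_controls
        results.append(res)
    return results
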