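"""Propensity-score stratified screen.

For each exposure a random-forest *regression* is trained to predict the
exposure from the participant covariates (reference age, parental-profession
class, urban-unit index, percent farmers, and one indicator per large
recruitment center).  The propensity score is the forest's out-of-bag
prediction, the sample is cut into deciles of the score, and the
exposure-status association is tested within those strata — CMH for binary
variables, conditional logistic regression for ordinal ones — mirroring the
matched analysis with matched sets replaced by propensity strata.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .matched_analysis import (
    STATUS_DEGENERATE,
    StratifiedTable,
    TestResult,
    cmh_test,
    conditional_logit,
)

__all__ = [
    "build_covariate_matrix",
    "fit_propensity",
    "quantile_stratify",
    "run_propensity_screen",
    "variable_seed",
]

logger = logging.getLogger(__name__)

CENTER_MIN_SIZE = 30  # centers above this size get their own indicator
MIN_FIT_N = 50  # smallest sample a forest is fit on
DEFAULT_N_TREES = 500
DEFAULT_K = 10


def build_covariate_matrix(sample: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariate matrix for the propensity model.

    ``sample`` is a participant table already restricted to the propensity
    sample.  Columns, in deterministic order: reference_age, ses,
    urban_unit_index, pct_farmers, then one 0/1 indicator per recruitment
    center with more than :data:`CENTER_MIN_SIZE` participants *in this
    sample* (sorted by center id).  Small-center participants have all
    indicators zero.  Missing covariates are rejected — they should have
    been excluded upstream.
    """
    base_cols = ["reference_age", "ses", "urban_unit_index", "pct_farmers"]
    if sample.empty:
        return pd.DataFrame(columns=base_cols)
    required = base_cols + ["center_id", "participant_id"]
    missing_cols = [c for c in required if c not in sample.columns]
    if missing_cols:
        raise ValueError(f"sample lacks covariate columns: {missing_cols}")
    sub = sample[required].copy()
    if sub[base_cols + ["center_id"]].isna().any().any():
        bad = sub.loc[sub[base_cols + ["center_id"]].isna().any(axis=1), "participant_id"]
        raise ValueError(
            f"missing covariates for participants {bad.tolist()[:5]} "
            "(propensity sample must be built first)"
        )
    out = sub[base_cols].astype(float)
    counts = sub["center_id"].value_counts()
    big = sorted(counts.index[counts > CENTER_MIN_SIZE])
    for center in big:
        out[f"center_{center}"] = (sub["center_id"] == center).astype(float)
    out.index = sub["participant_id"].to_numpy()
    return out


def variable_seed(master_seed: int, variable_id: str) -> int:
    """Stable per-variable seed derived from the master seed.

    Uses a cryptographic digest so the value is independent of Python's
    hash randomization and of variable iteration order.
    """
    digest = hashlib.sha256(f"{master_seed}:{variable_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def fit_propensity(
    covariates: pd.DataFrame | np.ndarray,
    exposure: np.ndarray,
    seed: int,
    n_trees: int = DEFAULT_N_TREES,
) -> np.ndarray:
    """Out-of-bag random-forest propensity scores for one exposure.

    A regression forest is used even for binary exposures; scores are the
    out-of-bag predictions, clipped to [0, 1].  Same seed and data give
    identical scores.
    """
    X = np.asarray(covariates, dtype=float)
    y = np.asarray(exposure, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("covariates and exposure must align")
    if not np.all(np.isfinite(y)):
        raise ValueError("exposure must be complete (drop missing first)")
    if len(y) < MIN_FIT_N:
        raise ValueError(f"need at least {MIN_FIT_N} participants, got {len(y)}")
    if np.ptp(y) == 0:
        raise ValueError("constant exposure (should have been sd-filtered)")
    p = X.shape[1]
    mtry = max(1, int(np.ceil(p / 3)))
    rf = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=5,  # reference implementation's regression nodesize
        bootstrap=True,
        oob_score=True,
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        rf.fit(X, y)
    scores = np.asarray(rf.oob_prediction_, dtype=float)
    bad = ~np.isfinite(scores)
    if bad.any():  # only possible with very small forests
        scores[bad] = float(np.mean(y))
    return np.clip(scores, 0.0, 1.0)


def quantile_stratify(scores: np.ndarray, k: int = DEFAULT_K) -> np.ndarray:
    """Cut scores into (at most) ``k`` quantile strata.

    Cut points are the k-quantiles of the score distribution; duplicate cut
    points (heavy ties) are merged, which can yield fewer than ``k`` strata.
    Returns integer labels 1..K_eff ordered by score interval.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be non-missing")
    if k < 1:
        raise ValueError("k must be >= 1")
    if scores.size == 0:
        return np.array([], dtype=int)
    edges = np.quantile(scores, np.linspace(0, 1, k + 1)[1:-1])
    edges = np.unique(edges)
    labels = np.searchsorted(edges, scores, side="left") + 1
    if np.ptp(scores) == 0:
        logger.warning("all propensity scores identical: single stratum")
    # relabel to consecutive 1..K_eff in score order
    present = np.unique(labels)
    remap = {old: new for new, old in enumerate(present, start=1)}
    labels = np.vectorize(remap.get)(labels)
    k_eff = len(present)
    if k_eff < k and np.ptp(scores) > 0:
        logger.info("quantile ties merged: %d strata instead of %d", k_eff, k)
    return labels.astype(int)


def run_propensity_screen(
    sample: pd.DataFrame,
    matrix: pd.DataFrame,
    spec,
    seed: int,
    variables: Sequence[str] | None = None,
    k: int = DEFAULT_K,
    n_trees: int = DEFAULT_N_TREES,
) -> list[TestResult]:
    """Propensity-stratified test of every variable on a flat sample.

    ``sample`` is the participant table of the propensity sample (matching
    ignored), ``matrix`` the encoded responses.  Per variable: complete
    cases on the exposure, a fresh forest seeded from (seed, variable_id),
    decile stratification of its out-of-bag scores, then CMH (binary) or
    conditional logit (ordinal) across the strata.
    """
    covariates = build_covariate_matrix(sample)
    ids = covariates.index.to_numpy()
    status = (
        sample.set_index("participant_id").loc[ids, "status"] == "case"
    ).to_numpy()
    sub = matrix.reindex(ids)
    values = sub.to_numpy(dtype=float)
    columns = list(sub.columns)
    col_index = {c: i for i, c in enumerate(columns)}
    X_all = covariates.to_numpy(dtype=float)

    if variables is None:
        variables = columns
    todo = sorted(variables)

    n_cases = max(int(status.sum()), 1)
    n_controls = max(int((~status).sum()), 1)
    results: list[TestResult] = []
    for var in todo:
        x = values[:, col_index[var]]
        ok = np.isfinite(x)
        res_missing_cases = 100.0 * np.sum(~ok & status) / n_cases
        res_missing_controls = 100.0 * np.sum(~ok & ~status) / n_controls
        rf_seed = variable_seed(seed, var)
        if ok.sum() < MIN_FIT_N or np.ptp(x[ok]) == 0:
            res = TestResult(
                variable_id=var, analysis="propensity", status=STATUS_DEGENERATE
            )
        else:
            scores = fit_propensity(X_all[ok], x[ok], seed=rf_seed, n_trees=n_trees)
            strata = quantile_stratify(scores, k=k)
            if spec[var].kind == "binary":
                tab = StratifiedTable.from_arrays(status[ok], x[ok], strata)
                res = cmh_test(tab, variable_id=var, analysis="propensity")
            else:
                res = conditional_logit(
                    status[ok], x[ok], strata,
                    variable_id=var, analysis="propensity",
                )
            res.effective_k = int(strata.max()) if strata.size else 0
        res.rf_seed = rf_seed
        res.missing_pct_cases = res_missing_cases
        res.missing_pct_controls = res_missing_controls
        results.append(res)
    return results
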