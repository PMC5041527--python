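"""Multiple-testing control and the dual-analysis discovery rule.

The screen reports a variable as *discovered* only when it passes the
false-discovery-rate threshold in the matched analysis AND the family-wise
threshold in the propensity analysis, which controls false positives more
tightly than either rule alone.  Holm's step-down procedure is used for the
family-wise decisions (same error control as plain Bonferroni, uniformly
more powerful); the plain Bonferroni line alpha/m is also emitted for plots.
The number of tests m counts only variables whose test actually produced a
p-value (status ok), per analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "bonferroni_holm",
    "benjamini_hochberg",
    "dual_discovery",
    "volcano_table",
    "comparison_table",
    "DiscoveryReport",
]

NEGLOG10_P_CEILING = 300.0  # display cap for p == 0


def bonferroni_holm(pvals, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Holm step-down rejections plus the plain Bonferroni display line.

    Returns (boolean rejection flags aligned with the input, alpha/m).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.nan
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = alpha / (m - np.arange(m))
    sorted_ok = p[order] <= thresholds
    # step-down: reject until the first failure
    if sorted_ok.all():
        n_reject = m
    else:
        n_reject = int(np.argmin(sorted_ok))
    reject = np.zeros(m, dtype=bool)
    reject[order[:n_reject]] = True
    return reject, alpha / m


def benjamini_hochberg(pvals, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up rejections plus a display threshold.

    Rejects the i* smallest p-values where i* is the largest rank i with
    p(i) <= i*alpha/m.  The display threshold is p(i*) (the largest rejected
    p-value), or alpha/m when nothing is rejected.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.nan
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    crit = alpha * np.arange(1, m + 1) / m
    passing = np.nonzero(ranked <= crit)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size == 0:
        return reject, alpha / m
    i_star = passing.max()
    reject[order[: i_star + 1]] = True
    return reject, float(ranked[i_star])


@dataclass
class DiscoveryReport:
    """Joined per-variable outcome of both analyses with discovery flags."""

    table: pd.DataFrame
    alpha: float
    m_matched: int
    m_propensity: int
    fdr_threshold_matched: float
    bonferroni_threshold_matched: float
    bonferroni_threshold_propensity: float

    @property
    def discovered(self) -> list[str]:
        flag = self.table["discovered"].fillna(False).astype(bool)
        return self.table.loc[flag, "variable_id"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _ok_pvals(results: pd.DataFrame) -> pd.DataFrame:
    ok = results.loc[results["status"] == "ok", ["variable_id", "p_value"]].copy()
    ok["p_value"] = pd.to_numeric(ok["p_value"], errors="coerce")
    return ok.loc[np.isfinite(ok["p_value"])]


def dual_discovery(
    matched_results: pd.DataFrame,
    propensity_results: pd.DataFrame,
    alpha: float = 0.05,
) -> DiscoveryReport:
    """Apply both threshold families and combine them.

    A variable is *discovered* iff it is BH-rejected among the matched
    analysis' p-values and Holm-rejected among the propensity analysis' ones.
    Variables tested in only one analysis (or degenerate in one) are
    reported but can never be discovered.  Only status=ok tests enter the
    threshold computations.
    """
    ok_m = _ok_pvals(matched_results)
    ok_p = _ok_pvals(propensity_results)
    rej_fdr_m, thr_fdr_m = benjamini_hochberg(ok_m["p_value"].to_numpy(), alpha)
    rej_fwer_m, thr_bonf_m = bonferroni_holm(ok_m["p_value"].to_numpy(), alpha)
    rej_fwer_p, thr_bonf_p = bonferroni_holm(ok_p["p_value"].to_numpy(), alpha)

    flags_m = pd.DataFrame(
        {
            "variable_id": ok_m["variable_id"].to_numpy(),
            "passed_fdr_matched": rej_fdr_m,
            "passed_bonferroni_matched": rej_fwer_m,
        }
    )
    flags_p = pd.DataFrame(
        {
            "variable_id": ok_p["variable_id"].to_numpy(),
            "passed_bonferroni_propensity": rej_fwer_p,
        }
    )

    left = matched_results.rename(
        columns={
            c: f"matched_{c}"
            for c in matched_results.columns
            if c != "variable_id"
        }
    )
    right = propensity_results.rename(
        columns={
            c: f"propensity_{c}"
            for c in propensity_results.columns
            if c != "variable_id"
        }
    )
    table = left.merge(right, on="variable_id", how="outer")
    table = table.merge(flags_m, on="variable_id", how="left")
    table = table.merge(flags_p, on="variable_id", how="left")
    for col in (
        "passed_fdr_matched",
        "passed_bonferroni_matched",
        "passed_bonferroni_propensity",
    ):
        flags = table[col] if col in table.columns else pd.Series(False, index=table.index)
        table[col] = flags.map(lambda v: bool(v) if pd.notna(v) else False)
    table["discovered"] = (
        table["passed_fdr_matched"] & table["passed_bonferroni_propensity"]
    )
    table = table.sort_values("variable_id", kind="stable").reset_index(drop=True)
    keep = ["variable_id"] + [
        c
        for c in table.columns
        if c != "variable_id"
        and not c.endswith(("_statistic", "_rf_seed"))
    ]
    return DiscoveryReport(
        table=table[keep],
        alpha=alpha,
        m_matched=len(ok_m),
        m_propensity=len(ok_p),
        fdr_threshold_matched=thr_fdr_m,
        bonferroni_threshold_matched=thr_bonf_m,
        bonferroni_threshold_propensity=thr_bonf_p,
    )


def volcano_table(
    results: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Plot-ready volcano coordinates for one analysis.

    x = log(effect size), so protective factors (OR < 1) sit left of zero;
    y = -log10(p), capped at :data:`NEGLOG10_P_CEILING` for p == 0 (flagged).
    Variables past the BH threshold carry a label.  Returns the table plus
    the threshold constants (Bonferroni and FDR lines on the y scale).
    """
    ok = results.loc[
        (results["status"] == "ok")
        & np.isfinite(results["p_value"])
        & np.isfinite(results["effect_size"])
        & (results["effect_size"] > 0)
    ].copy()
    if ok.empty:
        empty = pd.DataFrame(
            columns=["variable_id", "log_effect", "neglog10_p", "capped", "label"]
        )
        return empty, {"bonferroni_line": np.nan, "fdr_line": np.nan}
    p = ok["p_value"].to_numpy()
    rej_bh, _ = benjamini_hochberg(p, alpha)
    m = len(ok)
    with np.errstate(divide="ignore"):
        y = -np.log10(p)
    capped = ~np.isfinite(y)
    y = np.where(capped, NEGLOG10_P_CEILING, y)
    table = pd.DataFrame(
        {
            "variable_id": ok["variable_id"].to_numpy(),
            "log_effect": np.log(ok["effect_size"].to_numpy()),
            "neglog10_p": y,
            "capped": capped,
            "label": np.where(rej_bh, ok["variable_id"].to_numpy(), ""),
        }
    )
    table = table.sort_values("variable_id", kind="stable").reset_index(drop=True)
    # FDR display line: largest rejected p (or the first BH criterion)
    _, thr_bh = benjamini_hochberg(p, alpha)
    thresholds = {
        "bonferroni_line": float(-np.log10(alpha / m)),
        "fdr_line": float(-np.log10(thr_bh)) if thr_bh > 0 else NEGLOG10_P_CEILING,
    }
    return table, thresholds


def comparison_table(
    matched_results: pd.DataFrame,
    propensity_results: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """(-log10 p) of the two analyses against each other.

    Only variables with ok status in both analyses appear; dual-discovered
    variables are labeled.  Returns the table and the two threshold lines
    (matched FDR horizontal, propensity Bonferroni vertical).
    """
    report = dual_discovery(matched_results, propensity_results, alpha)
    t = report.table
    if t.empty:
        empty = pd.DataFrame(
            columns=["variable_id", "neglog10_p_matched",
                     "neglog10_p_propensity", "label"]
        )
        return empty, {"fdr_line_matched": np.nan,
                       "bonferroni_line_propensity": np.nan, "n_omitted": 0.0}
    pm = pd.to_numeric(t["matched_p_value"], errors="coerce")
    pp = pd.to_numeric(t["propensity_p_value"], errors="coerce")
    both = t.loc[
        np.isfinite(pm)
        & np.isfinite(pp)
        & (t["matched_status"] == "ok")
        & (t["propensity_status"] == "ok")
    ]
    n_dropped = len(t) - len(both)
    with np.errstate(divide="ignore"):
        xm = -np.log10(both["matched_p_value"].to_numpy())
        xp = -np.log10(both["propensity_p_value"].to_numpy())
    table = pd.DataFrame(
        {
            "variable_id": both["variable_id"].to_numpy(),
            "neglog10_p_matched": np.minimum(xm, NEGLOG10_P_CEILING),
            "neglog10_p_propensity": np.minimum(xp, NEGLOG10_P_CEILING),
            "label": np.where(
                both["discovered"].to_numpy(), both["variable_id"].to_numpy(), ""
            ),
        }
    ).reset_index(drop=True)
    lines = {
        "fdr_line_matched": float(-np.log10(report.fdr_threshold_matched))
        if report.fdr_threshold_matched > 0
        else NEGLOG10_P_CEILING,
        "bonferroni_line_propensity": float(
            -np.log10(report.bonferroni_threshold_propensity)
        )
        if report.bonferroni_threshold_propensity > 0
        else NEGLOG10_P_CEILING,
        "n_omitted": float(n_dropped),
    }
    return table, lines
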