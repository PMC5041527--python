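"""Synthetic matched case-control questionnaire studies with known truth.

The generator emulates the statistical structure the two screens assume:

* matched strata of one case with zero, one or two controls (friend/schoolmate
  controls share the case's reference age and, partially, its environment);
* a mixed binary/ordinal questionnaire whose exposures may depend on the
  participant covariates (confounding) and on case status (true effects);
* per-variable missingness with an optional case/control differential.

Case status enters retrospectively, by tilting a participant's exposure
distribution: for encoded level e the probability is proportional to
``base(e) * exp((eta + beta * is_case) * e)`` where ``eta`` collects the
covariate confounding terms and ``beta`` is the variable's true log-odds
effect.  For a binary exposure this is exactly a logistic model, and in
general the odds ratio between the two extreme responses is ``exp(beta)`` —
the quantity both analyses estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .questionnaire_model import (
    PARTICIPANT_COLUMNS,
    QuestionDef,
    QuestionnaireSpec,
    StudyDataset,
)

__all__ = ["SimConfig", "SimTruth", "SimStudy", "simulate_study", "evaluate_screen",
           "write_study"]

# fallback level labels per level count
_LEVEL_LABELS = {
    2: ("no", "yes"),
    3: ("never", "sometimes", "often"),
    4: ("never", "rarely", "often", "daily"),
    5: ("never", "rarely", "sometimes", "often", "daily"),
}

# standardization constants for the confounding linear predictor (fixed, not
# data-dependent, so eta is reproducible across samples)
_Z = {
    "age": (8.0, 4.3),
    "ses": (1.0, 0.75),
    "urban": (4.0, 2.6),
    "farm": (0.10, 0.10),
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic study.

    ``control_pattern`` gives the proportions of cases with 0, 1 and 2
    controls (normalized; the default mirrors a recruitment where most cases
    bring no control).  ``effects`` maps variable ids to true log-odds
    effects per unit of encoded exposure; ``confounding`` maps variable ids
    to coefficient dicts with any of the keys ``age``, ``ses``, ``urban``,
    ``farm``.  ``case_covariate_shift`` perturbs the *case* covariate
    distribution (keys ``age`` in years, ``ses`` and ``urban`` on a logit
    scale) to create case-control covariate imbalance for confounding
    studies.
    """

    n_cases: int = 300
    control_pattern: tuple[float, float, float] = (1077.0, 451.0, 241.0)
    n_extra_controls: int = 0
    n_variables: int = 200
    frac_binary: float = 0.75
    ordinal_levels: tuple[int, ...] = (3, 4, 5)
    frac_reversed: float = 0.1
    effects: Mapping[str, float] = field(default_factory=dict)
    confounding: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    case_covariate_shift: Mapping[str, float] = field(default_factory=dict)
    n_centers: int = 6
    center_weights: tuple[float, ...] | None = None
    n_communes: int = 120
    ses_probs: tuple[float, float, float] = (837.0, 725.0, 278.0)
    missing_rate: float = 0.04
    missing_case_multiplier: float = 1.2
    matching_fidelity: float = 0.8
    school_error_rate: float = 0.0
    covariate_missing_rate: float = 0.0
    age_out_rate: float = 0.0
    delay_out_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_variables < 1:
            raise ValueError("n_cases and n_variables must be positive")
        if any(p < 0 for p in self.control_pattern) or sum(self.control_pattern) <= 0:
            raise ValueError("control_pattern must be nonnegative, not all zero")
        if any(L < 2 or L > 5 for L in self.ordinal_levels):
            raise ValueError("ordinal level counts must be in [2, 5]")
        for rate in (self.missing_rate, self.school_error_rate,
                     self.covariate_missing_rate, self.frac_binary,
                     self.frac_reversed, self.matching_fidelity):
            if not 0 <= rate <= 1:
                raise ValueError("rates and fractions must lie in [0, 1]")
        for beta in self.effects.values():
            if not np.isfinite(beta):
                raise ValueError("effects must be finite")

    @property
    def pattern_probs(self) -> np.ndarray:
        p = np.asarray(self.control_pattern, dtype=float)
        return p / p.sum()


@dataclass
class SimTruth:
    """Ground truth of a simulated study."""

    variable_ids: list[str]
    effects: dict[str, float]  # variable_id -> true log-odds effect
    confounding: dict[str, dict[str, float]]
    baselines: dict[str, list[float]]  # variable_id -> base level probabilities
    seed: int = 0

    @property
    def nonnull(self) -> set[str]:
        return {v for v, b in self.effects.items() if b != 0.0}

    def true_or(self, variable_id: str) -> float:
        """True extreme-response odds ratio."""
        return float(np.exp(self.effects.get(variable_id, 0.0)))

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class SimStudy:
    dataset: StudyDataset
    truth: SimTruth


def _make_spec(config: SimConfig, rng: np.random.Generator) -> QuestionnaireSpec:
    n_bin = int(round(config.frac_binary * config.n_variables))
    questions = []
    for i in range(config.n_variables):
        vid = f"q{i + 1:04d}"
        if i < n_bin:
            levels = _LEVEL_LABELS[2]
            kind = "binary"
        else:
            L = config.ordinal_levels[(i - n_bin) % len(config.ordinal_levels)]
            levels = _LEVEL_LABELS[L]
            kind = "binary" if L == 2 else "ordinal"
        orientation = "reversed" if rng.random() < config.frac_reversed else "as_is"
        questions.append(
            QuestionDef(variable_id=vid, kind=kind, levels=levels,
                        orientation=orientation)
        )
    return QuestionnaireSpec(tuple(questions))


def _standardize(name: str, values: np.ndarray) -> np.ndarray:
    mu, sd = _Z[name]
    return (values - mu) / sd


def _draw_covariates(
    n: int, config: SimConfig, rng: np.random.Generator,
    communes: pd.DataFrame, center_probs: np.ndarray, shifted: bool,
) -> pd.DataFrame:
    """Base covariate draw; ``shifted`` applies the case covariate shift."""
    shift = config.case_covariate_shift if shifted else {}
    age = rng.uniform(0.5, 15.5, size=n) + float(shift.get("age", 0.0))
    age = np.clip(age, 0.5, 15.5)
    ses_logp = np.log(np.asarray(config.ses_probs, float) / sum(config.ses_probs))
    ses_logp = ses_logp + float(shift.get("ses", 0.0)) * np.array([0.0, 1.0, 2.0])
    ses_p = np.exp(ses_logp - ses_logp.max())
    ses_p /= ses_p.sum()
    ses = rng.choice(3, size=n, p=ses_p)
    uui = communes["urban_unit_index"].to_numpy()
    commune_w = np.exp(float(shift.get("urban", 0.0)) * _standardize("urban", uui))
    commune_w /= commune_w.sum()
    commune = rng.choice(len(communes), size=n, p=commune_w)
    center = rng.choice(len(center_probs), size=n, p=center_probs)
    return pd.DataFrame(
        {
            "reference_age": age,
            "ses": ses,
            "commune": commune,
            "center": center,
        }
    )


def simulate_study(config: SimConfig, seed: int | None = None) -> SimStudy:
    """Generate one synthetic study; identical config+seed give identical output.

    Generative order: questionnaire spec, communes/centers, per-case
    covariates (optionally shifted), controls with convexly mixed covariates
    sharing the case's reference age, exposures from the tilted level model,
    then missingness.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    spec = _make_spec(config, rng)

    communes = pd.DataFrame(
        {
            "urban_unit_index": rng.integers(0, 9, size=config.n_communes),
        }
    )
    communes["pct_farmers"] = np.round(
        np.clip(
            rng.beta(2, 8, size=config.n_communes)
            * (1.0 - communes["urban_unit_index"] / 10.0),
            0.0,
            0.6,
        ),
        4,
    )
    if config.center_weights is None:
        w = np.exp(-0.45 * np.arange(config.n_centers))
    else:
        w = np.asarray(config.center_weights, dtype=float)
    center_probs = w / w.sum()

    # --- participants -----------------------------------------------------
    cases = _draw_covariates(
        config.n_cases, config, rng, communes, center_probs, shifted=True
    )
    cases["delay"] = rng.uniform(0.3, 8.0, size=config.n_cases)
    n_controls_per_case = rng.choice(3, size=config.n_cases, p=config.pattern_probs)

    case_nums = np.arange(config.n_cases)
    set_ids = np.where(
        n_controls_per_case > 0,
        np.char.add("m", np.char.zfill((case_nums + 1).astype(str), 5)),
        None,
    )
    case_df = pd.DataFrame(
        {
            "participant_id": [f"case{i + 1:05d}" for i in case_nums],
            "status": "case",
            "matched_set_id": set_ids,
            "reference_age": cases["reference_age"].to_numpy(),
            "delay": cases["delay"].to_numpy(),
            "ses": cases["ses"].to_numpy(),
            "commune": cases["commune"].to_numpy(),
            "center": cases["center"].to_numpy(),
        }
    )

    # controls: convex mix of the case's environment with a fresh draw;
    # reference age is shared by design (same recall endpoint)
    owner = np.repeat(case_nums, n_controls_per_case)
    m = len(owner)
    fresh = _draw_covariates(m, config, rng, communes, center_probs, shifted=False)
    inherit = rng.random((m, 3)) < config.matching_fidelity
    starts = np.concatenate([[0], np.cumsum(n_controls_per_case)[:-1]])
    within = np.arange(m) - starts[owner] + 1
    ctrl_df = pd.DataFrame(
        {
            "participant_id": [
                f"ctrl{i + 1:05d}_{j}" for i, j in zip(owner, within)
            ],
            "status": "control",
            "matched_set_id": set_ids[owner],
            "reference_age": cases["reference_age"].to_numpy()[owner],
            "delay": np.nan,
            "ses": np.where(inherit[:, 0], cases["ses"].to_numpy()[owner],
                            fresh["ses"].to_numpy()),
            "commune": np.where(inherit[:, 1], cases["commune"].to_numpy()[owner],
                                fresh["commune"].to_numpy()),
            "center": np.where(inherit[:, 2], cases["center"].to_numpy()[owner],
                               fresh["center"].to_numpy()),
        }
    )
    frames = [case_df, ctrl_df]
    if config.n_extra_controls > 0:
        xtra = _draw_covariates(
            config.n_extra_controls, config, rng, communes, center_probs,
            shifted=False,
        )
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": [
                        f"xctrl{j + 1:05d}" for j in range(config.n_extra_controls)
                    ],
                    "status": "control",
                    "matched_set_id": None,
                    "reference_age": xtra["reference_age"].to_numpy(),
                    "delay": np.nan,
                    "ses": xtra["ses"].to_numpy(),
                    "commune": xtra["commune"].to_numpy(),
                    "center": xtra["center"].to_numpy(),
                }
            )
        )
    part = pd.concat(frames, ignore_index=True)
    part["commune"] = part["commune"].astype(int)
    part["center"] = part["center"].astype(int)
    part["urban_unit_index"] = communes["urban_unit_index"].to_numpy()[part["commune"]]
    part["pct_farmers"] = communes["pct_farmers"].to_numpy()[part["commune"]]
    part["center_id"] = "c" + (part["center"] + 1).astype(str)
    part["reference_age"] = part["reference_age"].round(3)
    part["delay"] = part["delay"].round(3)

    # school flag consistent with age unless the error knob is on
    age = part["reference_age"].to_numpy()
    school = age >= 6.0
    if config.school_error_rate > 0:
        flip = rng.random(len(part)) < config.school_error_rate
        school = np.where(flip & (age < 5.5), True, school)
    part["attended_primary_school"] = school

    # knobs that push participants outside the exclusion windows (for tests)
    if config.age_out_rate > 0:
        hit = rng.random(len(part)) < config.age_out_rate
        part.loc[hit, "reference_age"] = np.round(
            rng.uniform(16.0, 18.0, size=int(hit.sum())), 3
        )
    if config.delay_out_rate > 0:
        is_case = (part["status"] == "case").to_numpy()
        hit = (rng.random(len(part)) < config.delay_out_rate) & is_case
        part.loc[hit, "delay"] = np.round(
            rng.uniform(10.5, 14.0, size=int(hit.sum())), 3
        )
    if config.covariate_missing_rate > 0:
        hit = rng.random(len(part)) < config.covariate_missing_rate
        part.loc[hit, ["urban_unit_index", "pct_farmers"]] = np.nan

    part = part.drop(columns=["commune", "center"])
    part = part[PARTICIPANT_COLUMNS]

    # --- exposures --------------------------------------------------------
    eta_inputs = {
        "age": _standardize("age", part["reference_age"].to_numpy(dtype=float)),
        "ses": _standardize("ses", part["ses"].to_numpy(dtype=float)),
        "urban": _standardize(
            "urban",
            pd.to_numeric(part["urban_unit_index"], errors="coerce")
            .fillna(4.0)
            .to_numpy(dtype=float),
        ),
        "farm": _standardize(
            "farm",
            pd.to_numeric(part["pct_farmers"], errors="coerce")
            .fillna(0.1)
            .to_numpy(dtype=float),
        ),
    }
    is_case = (part["status"] == "case").to_numpy()
    n = len(part)

    effects = {q.variable_id: float(config.effects.get(q.variable_id, 0.0))
               for q in spec}
    confounding = {
        q.variable_id: {k: float(v)
                        for k, v in config.confounding.get(q.variable_id, {}).items()}
        for q in spec
    }
    baselines: dict[str, list[float]] = {}
    responses: dict[str, np.ndarray] = {}
    for q in spec:
        L = q.n_levels
        enc = np.linspace(0.0, 1.0, L)
        if L == 2:
            p0 = rng.uniform(0.15, 0.85)
            base = np.array([1.0 - p0, p0])
        else:
            base = rng.dirichlet(np.full(L, 3.0))
            base = np.clip(base, 0.03, None)
            base /= base.sum()
        baselines[q.variable_id] = [round(float(x), 6) for x in base]
        eta = np.zeros(n)
        for key, coef in confounding[q.variable_id].items():
            eta += coef * eta_inputs[key]
        tilt = eta + effects[q.variable_id] * is_case
        logits = np.log(base)[None, :] + tilt[:, None] * enc[None, :]
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        idx = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        # emit the label whose encoded value is enc[idx] (undo orientation)
        if q.orientation == "reversed":
            labels = np.array(q.levels[::-1])
        else:
            labels = np.array(q.levels)
        responses[q.variable_id] = labels[idx]

    raw = pd.DataFrame(responses, index=part["participant_id"].to_numpy())
    raw.index.name = "participant_id"

    # --- missingness ------------------------------------------------------
    if config.missing_rate > 0:
        rate = np.where(
            is_case,
            min(1.0, config.missing_rate * config.missing_case_multiplier),
            config.missing_rate,
        )
        mask = rng.random(raw.shape) < rate[:, None]
        raw = raw.mask(pd.DataFrame(mask, index=raw.index, columns=raw.columns))

    dataset = StudyDataset(participants=part, raw_responses=raw, spec=spec)
    truth = SimTruth(
        variable_ids=spec.variable_ids,
        effects=effects,
        confounding=confounding,
        baselines=baselines,
        seed=seed,
    )
    return SimStudy(dataset=dataset, truth=truth)


def write_study(study: SimStudy, outdir) -> None:
    """Emit participants.csv, responses.csv, questionnaire.yaml, truth.json."""
    import os

    os.makedirs(outdir, exist_ok=True)
    study.dataset.participants.to_csv(
        os.path.join(outdir, "participants.csv"), index=False
    )
    study.dataset.raw_responses.to_csv(os.path.join(outdir, "responses.csv"))
    study.dataset.spec.to_yaml(os.path.join(outdir, "questionnaire.yaml"))
    study.truth.to_json(os.path.join(outdir, "truth.json"))


def evaluate_screen(
    results: pd.DataFrame,
    truth: SimTruth,
    rejected: Mapping[str, bool] | Sequence[str] | None = None,
    alpha: float = 0.05,
) -> dict:
    """Score a screen's results against the generator's ground truth.

    ``rejected`` may be a variable->flag mapping, a collection of rejected
    ids, or None (then raw p < alpha on ok-status tests).  Returns type-I
    error among nulls, whether any null was rejected (FWER contribution),
    the false discovery proportion, power among non-nulls, bias and RMSE of
    the log effect estimates over non-nulls, and CI coverage of the true
    odds ratio.
    """
    unknown = set(results["variable_id"]) - set(truth.variable_ids)
    if unknown:
        raise ValueError(f"results contain ids not in truth: {sorted(unknown)[:5]}")
    ok = results.loc[results["status"] == "ok"].set_index("variable_id")
    if rejected is None:
        rej = {v: bool(p < alpha) for v, p in ok["p_value"].items()}
    elif isinstance(rejected, Mapping):
        rej = {v: bool(rejected.get(v, False)) for v in ok.index}
    else:
        rejected = set(rejected)
        rej = {v: v in rejected for v in ok.index}

    nonnull = truth.nonnull
    nulls = [v for v in ok.index if v not in nonnull]
    trues = [v for v in ok.index if v in nonnull]
    n_rej = sum(rej.values())
    false_rej = sum(rej[v] for v in nulls)
    true_rej = sum(rej[v] for v in trues)

    bias = rmse = coverage = np.nan
    if trues:
        est = np.log(ok.loc[trues, "effect_size"].to_numpy(dtype=float))
        tru = np.array([truth.effects[v] for v in trues])
        finite = np.isfinite(est)
        if finite.any():
            bias = float(np.mean(est[finite] - tru[finite]))
            rmse = float(np.sqrt(np.mean((est[finite] - tru[finite]) ** 2)))
        lo = ok.loc[trues, "ci_low"].to_numpy(dtype=float)
        hi = ok.loc[trues, "ci_high"].to_numpy(dtype=float)
        tor = np.exp(tru)
        with np.errstate(invalid="ignore"):
            cov = (lo <= tor) & (tor <= hi)
        finite_ci = np.isfinite(lo) & np.isfinite(hi)
        if finite_ci.any():
            coverage = float(np.mean(cov[finite_ci]))

    return {
        "n_tests": len(ok),
        "n_null": len(nulls),
        "n_nonnull": len(trues),
        "n_rejections": int(n_rej),
        "n_false_rejections": int(false_rej),
        "any_false_rejection": bool(false_rej > 0),
        "type_i_rate": float(false_rej / len(nulls)) if nulls else np.nan,
        "power": float(true_rej / len(trues)) if trues else np.nan,
        "fdp": float(false_rej / n_rej) if n_rej else 0.0,
        "bias_log_effect": bias,
        "rmse_log_effect": rmse,
        "ci_coverage": coverage,
    }
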