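"""Questionnaire data model: variable encoding, exclusion cascade, sample building.

The data model has three layers:

* :class:`QuestionnaireSpec` — a declarative description of every variable
  (kind, ordered levels, orientation) that fully determines its encoding.
* :class:`StudyDataset` — participant metadata plus the raw response table.
* Sample builders — the exclusion cascade, the matched strata, and the flat
  propensity sample, each with an explicit log of what was removed and why.

Encoded values always live in the closed interval [0, 1]: a binary variable
maps to {0, 1} and an ordinal variable with L levels maps its k-th level
(after applying the orientation flag) to k/(L-1).  The attainable values are
a function of the spec alone, never of the observed data, so encodings are
comparable across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "QuestionDef",
    "QuestionnaireSpec",
    "StudyDataset",
    "MatchedStratum",
    "ExclusionConfig",
    "ExclusionLog",
    "PARTICIPANT_COLUMNS",
    "encode_variables",
    "participant_missingness",
    "apply_exclusions",
    "build_matched_sample",
    "build_propensity_sample",
    "sd_filter",
    "read_participants",
    "read_responses",
]

#: Required columns of a participant table, in canonical order.
PARTICIPANT_COLUMNS = [
    "participant_id",
    "status",
    "matched_set_id",
    "reference_age",
    "delay",
    "ses",
    "urban_unit_index",
    "pct_farmers",
    "center_id",
    "attended_primary_school",
]

VALID_KINDS = ("binary", "ordinal")
VALID_ORIENTATIONS = ("as_is", "reversed")


@dataclass(frozen=True)
class QuestionDef:
    """Declarative definition of one questionnaire variable.

    Parameters
    ----------
    variable_id
        Unique text identifier.
    kind
        ``"binary"`` (exactly two levels) or ``"ordinal"`` (3-5 levels).
    levels
        Ordered response labels, from the natural lowest to highest level.
    orientation
        ``"as_is"`` keeps the stated order; ``"reversed"`` flips it so the
        highest encoded value always has a consistent interpretive direction.
    """

    variable_id: str
    kind: str
    levels: tuple[str, ...]
    orientation: str = "as_is"

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", tuple(str(x) for x in self.levels))
        if self.kind not in VALID_KINDS:
            raise ValueError(f"{self.variable_id}: unknown kind {self.kind!r}")
        if self.orientation not in VALID_ORIENTATIONS:
            raise ValueError(
                f"{self.variable_id}: unknown orientation {self.orientation!r}"
            )
        n = len(self.levels)
        if n < 2:
            raise ValueError(f"{self.variable_id}: degenerate variable with {n} level(s)")
        if n > 5:
            raise ValueError(f"{self.variable_id}: more than 5 levels ({n})")
        if len(set(self.levels)) != n:
            raise ValueError(f"{self.variable_id}: duplicate levels {self.levels}")
        if (self.kind == "binary") != (n == 2):
            raise ValueError(
                f"{self.variable_id}: kind={self.kind} inconsistent with {n} levels"
            )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def encoding(self) -> dict[str, float]:
        """Map each level label to its encoded value in [0, 1].

        Levels are equally spaced; endpoints are exactly 0 and 1.  The
        orientation flag is applied before spacing, so a reversed variable
        maps its first stated level to 1.
        """
        L = self.n_levels
        values = np.linspace(0.0, 1.0, L)
        if self.orientation == "reversed":
            values = values[::-1]
        return dict(zip(self.levels, values.tolist()))


@dataclass(frozen=True)
class QuestionnaireSpec:
    """Ordered collection of :class:`QuestionDef` with unique ids."""

    questions: tuple[QuestionDef, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "questions", tuple(self.questions))
        ids = [q.variable_id for q in self.questions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variable ids: {dupes}")

    def __len__(self) -> int:
        return len(self.questions)

    def __iter__(self) -> Iterator[QuestionDef]:
        return iter(self.questions)

    def __getitem__(self, variable_id: str) -> QuestionDef:
        try:
            return self._by_id[variable_id]
        except AttributeError:
            object.__setattr__(
                self, "_by_id", {q.variable_id: q for q in self.questions}
            )
            return self._by_id[variable_id]

    def __contains__(self, variable_id: str) -> bool:
        return any(q.variable_id == variable_id for q in self.questions)

    @property
    def variable_ids(self) -> list[str]:
        return [q.variable_id for q in self.questions]

    def to_yaml(self, path) -> None:
        data = {
            "questions": [
                {
                    "variable_id": q.variable_id,
                    "kind": q.kind,
                    "levels": list(q.levels),
                    "orientation": q.orientation,
                }
                for q in self.questions
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path) -> "QuestionnaireSpec":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        return cls(
            tuple(
                QuestionDef(
                    variable_id=str(q["variable_id"]),
                    kind=q["kind"],
                    levels=tuple(q["levels"]),
                    orientation=q.get("orientation", "as_is"),
                )
                for q in data["questions"]
            )
        )


@dataclass(frozen=True)
class MatchedStratum:
    """A case plus its one or two matched controls."""

    stratum_id: str
    case_id: str
    control_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "control_ids", tuple(self.control_ids))
        if not 1 <= len(self.control_ids) <= 2:
            raise ValueError(
                f"stratum {self.stratum_id}: {len(self.control_ids)} controls"
            )

    @property
    def size(self) -> int:
        return 1 + len(self.control_ids)

    @property
    def member_ids(self) -> tuple[str, ...]:
        return (self.case_id, *self.control_ids)


@dataclass(frozen=True)
class ExclusionConfig:
    """Thresholds of the exclusion cascade and the variability filter."""

    missingness_max: float = 0.5
    age_min: float = 0.5
    age_max: float = 15.5
    delay_max: float = 10.0
    school_age_cut: float = 5.5
    sd_min: float = 0.1


# Rule codes, in the order they are applied.  The log records the first rule
# that removed each participant; rules are conjunctive so the order only
# affects the log, not the retained set.
RULE_UNUSABLE = "unusable"
RULE_MISSINGNESS = "missingness"
RULE_AGE_WINDOW = "age_window"
RULE_DELAY = "delay"
RULE_SCHOOL = "school_consistency"
RULE_UNMATCHED = "unmatched"
RULE_MISSING_COVARIATES = "missing_covariates"
RULE_ORDER = [RULE_UNUSABLE, RULE_MISSINGNESS, RULE_AGE_WINDOW, RULE_DELAY, RULE_SCHOOL]


@dataclass
class ExclusionLog:
    """Per-participant record of the first rule that removed them."""

    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["participant_id", "rule"])
    )

    def add(self, participant_ids: Iterable[str], rule: str) -> None:
        ids = list(participant_ids)
        if not ids:
            return
        new = pd.DataFrame({"participant_id": ids, "rule": rule})
        self.records = pd.concat([self.records, new], ignore_index=True)

    def counts(self) -> dict[str, int]:
        return self.records["rule"].value_counts().to_dict()

    @property
    def excluded_ids(self) -> set[str]:
        return set(self.records["participant_id"])

    def __len__(self) -> int:
        return len(self.records)

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


@dataclass
class StudyDataset:
    """Participant metadata plus the raw (label-valued) response table.

    ``participants`` must contain :data:`PARTICIPANT_COLUMNS`;
    ``raw_responses`` is wide (rows = participants, columns = variables) with
    missing responses as NaN/None.
    """

    participants: pd.DataFrame
    raw_responses: pd.DataFrame
    spec: QuestionnaireSpec

    def __post_init__(self) -> None:
        missing = [c for c in PARTICIPANT_COLUMNS if c not in self.participants.columns]
        if missing:
            raise ValueError(f"participants table missing columns: {missing}")
        pids = self.participants["participant_id"]
        if pids.duplicated().any():
            raise ValueError("duplicate participant ids")
        bad_status = set(self.participants["status"]) - {"case", "control"}
        if bad_status:
            raise ValueError(f"unknown status values: {sorted(bad_status)}")
        if not self.raw_responses.index.isin(pids).all():
            raise ValueError("response rows for unknown participants")
        extra = [c for c in self.raw_responses.columns if c not in self.spec]
        if extra:
            raise ValueError(f"response columns not in questionnaire spec: {extra[:5]}")

    @property
    def participant_ids(self) -> list[str]:
        return self.participants["participant_id"].tolist()

    def subset(self, participant_ids: Sequence[str]) -> "StudyDataset":
        keep = self.participants["participant_id"].isin(set(participant_ids))
        participants = self.participants.loc[keep].reset_index(drop=True)
        responses = self.raw_responses.loc[
            self.raw_responses.index.isin(set(participant_ids))
        ]
        return replace(self, participants=participants, raw_responses=responses)


def encode_variables(
    raw_responses: pd.DataFrame, spec: QuestionnaireSpec
) -> pd.DataFrame:
    """Encode a wide table of level labels to values in [0, 1].

    Missing responses (NaN/None/empty string) stay missing (NaN).  An unknown
    label raises with the offending variable and participant identified.
    """
    encoded = {}
    for column in raw_responses.columns:
        qdef = spec[column]
        mapping = qdef.encoding()
        arr = raw_responses[column].to_numpy(dtype=object)
        present = pd.notna(arr) & (arr != "")
        codes = pd.Categorical(arr, categories=qdef.levels).codes
        level_values = np.array([mapping[lv] for lv in qdef.levels])
        values = np.where(codes >= 0, level_values[codes], np.nan)
        bad = present & (codes < 0)
        if bad.any():
            first = int(bad.nonzero()[0][0])
            raise ValueError(
                f"unknown response label {arr[first]!r} for variable "
                f"{qdef.variable_id!r} (participant {raw_responses.index[first]!r})"
            )
        encoded[column] = values
    return pd.DataFrame(encoded, index=raw_responses.index)


def participant_missingness(
    raw_responses: pd.DataFrame, participant_id: str | None = None
):
    """Fraction of unanswered questions per participant.

    Returns a Series indexed by participant, or a scalar if ``participant_id``
    is given.  All columns of the table count as questions.
    """
    if raw_responses.shape[1] == 0:
        raise ValueError("cannot compute missingness with zero questions")
    missing = raw_responses.isna() | raw_responses.astype("string").eq("").fillna(False)
    frac = missing.sum(axis=1) / raw_responses.shape[1]
    if participant_id is not None:
        if participant_id not in raw_responses.index:
            raise KeyError(f"participant {participant_id!r} not in response table")
        return float(frac.loc[participant_id])
    return frac


def _effective_delay(participants: pd.DataFrame) -> pd.Series:
    """Delay used by the delay rule: a case's own delay; a control inherits
    its matched case's delay (controls have no diagnosis).  Unmatched
    controls with no delay of their own are exempt (NaN)."""
    delay = pd.to_numeric(participants["delay"], errors="coerce").copy()
    is_case = participants["status"] == "case"
    case_delay = (
        participants.loc[is_case]
        .dropna(subset=["matched_set_id"])
        .set_index("matched_set_id")["delay"]
    )
    is_ctrl = ~is_case
    ctrl_sets = participants.loc[is_ctrl, "matched_set_id"]
    inherited = ctrl_sets.map(case_delay)
    delay.loc[is_ctrl] = pd.to_numeric(inherited, errors="coerce").to_numpy()
    return delay


def apply_exclusions(
    dataset: StudyDataset, rules: ExclusionConfig | None = None
) -> tuple[StudyDataset, ExclusionLog]:
    """Apply the exclusion cascade and return the filtered dataset plus log.

    Rules, in fixed order (the log records the first rule hit):

    1. ``unusable`` — missing reference age.
    2. ``missingness`` — more than ``missingness_max`` of questions unanswered.
    3. ``age_window`` — reference age outside [``age_min``, ``age_max``].
    4. ``delay`` — diagnosis-to-questionnaire delay above ``delay_max``
       (controls use their matched case's delay; no delay available = exempt).
    5. ``school_consistency`` — reported primary-school attendance with a
       reference age below ``school_age_cut`` (missing answer = not excluded).
    """
    if rules is None:
        rules = ExclusionConfig()
    part = dataset.participants
    log = ExclusionLog()
    pid = part["participant_id"]

    age = pd.to_numeric(part["reference_age"], errors="coerce")
    miss_by_pid = participant_missingness(dataset.raw_responses)
    missingness = pid.map(miss_by_pid).fillna(1.0)
    delay = _effective_delay(part)
    school = part["attended_primary_school"]
    school_yes = school.map(
        lambda x: bool(x) if pd.notna(x) and x not in ("", "nan") else False
    )

    triggered = {
        RULE_UNUSABLE: age.isna(),
        RULE_MISSINGNESS: missingness > rules.missingness_max,
        RULE_AGE_WINDOW: (age < rules.age_min) | (age > rules.age_max),
        RULE_DELAY: delay > rules.delay_max,
        RULE_SCHOOL: school_yes & (age < rules.school_age_cut),
    }
    removed = pd.Series(False, index=part.index)
    for rule in RULE_ORDER:
        hit = triggered[rule].fillna(False) & ~removed
        log.add(pid[hit].tolist(), rule)
        removed |= hit

    kept_ids = pid[~removed].tolist()
    return dataset.subset(kept_ids), log


def build_matched_sample(
    dataset: StudyDataset, log: ExclusionLog | None = None
) -> list[MatchedStratum]:
    """Group surviving participants into matched strata of size 2 or 3.

    Cases without surviving controls and controls without a surviving case
    are dropped (and recorded in ``log`` under the ``unmatched`` rule).
    Strata with more than two surviving controls keep the first two by
    participant id (not expected under the study design).
    """
    part = dataset.participants
    strata: list[MatchedStratum] = []
    dropped: list[str] = []
    matched = part.dropna(subset=["matched_set_id"])
    unmatched = part.loc[~part.index.isin(matched.index), "participant_id"]
    dropped.extend(unmatched.tolist())

    for set_id, group in matched.groupby("matched_set_id", sort=True):
        cases = group.loc[group["status"] == "case", "participant_id"].tolist()
        controls = sorted(
            group.loc[group["status"] == "control", "participant_id"].tolist()
        )
        if len(cases) != 1 or not controls:
            dropped.extend(group["participant_id"].tolist())
            continue
        strata.append(
            MatchedStratum(
                stratum_id=str(set_id),
                case_id=cases[0],
                control_ids=tuple(controls[:2]),
            )
        )
        dropped.extend(controls[2:])
    if log is not None:
        log.add(dropped, RULE_UNMATCHED)
    return strata


def build_propensity_sample(
    dataset: StudyDataset, log: ExclusionLog | None = None
) -> list[str]:
    """Flat participant list for the propensity analysis.

    Keeps every participant (matched or not) whose commune covariates
    (urban-unit index and percent farmers, i.e. a usable postal code) and
    parental-profession class are available; matching is ignored thereafter.
    """
    part = dataset.participants
    covs = part[["ses", "urban_unit_index", "pct_farmers", "reference_age", "center_id"]]
    ok = covs.notna().all(axis=1)
    if log is not None:
        log.add(part.loc[~ok, "participant_id"].tolist(), RULE_MISSING_COVARIATES)
    return part.loc[ok, "participant_id"].tolist()


def sd_filter(
    matrix: pd.DataFrame,
    sample_ids: Sequence[str],
    threshold: float = 0.1,
) -> tuple[list[str], pd.DataFrame]:
    """Keep variables with standard deviation >= ``threshold`` in the sample.

    The standard deviation is the population formula (divisor n) over
    non-missing values of the pooled analysis sample.  Returns the kept
    variable ids (original column order) and a table of dropped variables
    with reason ``low_sd`` or ``all_missing``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    ids = [i for i in sample_ids if i in matrix.index]
    if not ids:
        raise ValueError("empty analysis sample")
    sub = matrix.loc[ids]
    n_obs = sub.notna().sum(axis=0)
    sd = sub.std(axis=0, ddof=0)
    kept, dropped = [], []
    for var in matrix.columns:
        if n_obs[var] == 0:
            dropped.append((var, "all_missing", np.nan))
        elif sd[var] < threshold:
            dropped.append((var, "low_sd", float(sd[var])))
        else:
            kept.append(var)
    dropped_df = pd.DataFrame(dropped, columns=["variable_id", "reason", "sd"])
    return kept, dropped_df


def read_participants(path) -> pd.DataFrame:
    """Read ``participants.csv``; enforce required columns and dtypes."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "status": str, "center_id": str},
    )
    missing = [c for c in PARTICIPANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"participants file missing columns: {missing}")
    df["matched_set_id"] = df["matched_set_id"].astype("string")
    for col in ("reference_age", "delay", "pct_farmers"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    aps = df["attended_primary_school"]
    df["attended_primary_school"] = aps.map(
        lambda x: x
        if pd.isna(x)
        else str(x).strip().lower() in ("1", "true", "yes")
    )
    return df


def read_responses(path) -> pd.DataFrame:
    """Read ``responses.csv`` (wide: participant_id column + one column per
    variable, labels as text)."""
    df = pd.read_csv(path, dtype=str)
    if "participant_id" not in df.columns:
        raise ValueError("responses file must have a participant_id column")
    df = df.set_index("participant_id")
    return df
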