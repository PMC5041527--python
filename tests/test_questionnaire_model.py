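import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewas_screen import (
    ExclusionConfig,
    QuestionDef,
    QuestionnaireSpec,
    StudyDataset,
    apply_exclusions,
    build_matched_sample,
    build_propensity_sample,
    encode_variables,
    participant_missingness,
    sd_filter,
)
from ewas_screen.questionnaire_model import (
    RULE_AGE_WINDOW,
    RULE_DELAY,
    RULE_MISSINGNESS,
    RULE_SCHOOL,
    RULE_UNUSABLE,
)


class TestQuestionDef:
    def test_binary_requires_two_levels(self):
        with pytest.raises(ValueError):
            QuestionDef("x", "binary", ("a", "b", "c"))
        with pytest.raises(ValueError):
            QuestionDef("x", "ordinal", ("a", "b"))

    def test_degenerate_single_level_rejected(self):
        with pytest.raises(ValueError):
            QuestionDef("x", "binary", ("only",))

    def test_too_many_levels_rejected(self):
        with pytest.raises(ValueError):
            QuestionDef("x", "ordinal", tuple("abcdef"))

    def test_duplicate_levels_rejected(self):
        with pytest.raises(ValueError):
            QuestionDef("x", "ordinal", ("a", "b", "a"))

    def test_five_level_encoding_equally_spaced(self):
        q = QuestionDef("freq", "ordinal",
                        ("never", "rarely", "sometimes", "often", "daily"))
        assert q.encoding() == {
            "never": 0.0, "rarely": 0.25, "sometimes": 0.5,
            "often": 0.75, "daily": 1.0,
        }

    def test_binary_encoding(self):
        q = QuestionDef("b", "binary", ("no", "yes"))
        assert q.encoding() == {"no": 0.0, "yes": 1.0}

    def test_three_level_midpoint(self):
        q = QuestionDef("o", "ordinal", ("lo", "mid", "hi"))
        assert q.encoding()["mid"] == 0.5

    def test_reversed_orientation_flips(self):
        q = QuestionDef("r", "ordinal", ("lo", "mid", "hi"),
                        orientation="reversed")
        assert q.encoding() == {"lo": 1.0, "mid": 0.5, "hi": 0.0}

    @given(st.integers(min_value=2, max_value=5))
    def test_endpoints_always_zero_and_one(self, n_levels):
        q = QuestionDef("v", "binary" if n_levels == 2 else "ordinal",
                        tuple(f"l{i}" for i in range(n_levels)))
        values = list(q.encoding().values())
        assert min(values) == 0.0 and max(values) == 1.0


class TestQuestionnaireSpec:
    def test_duplicate_ids_rejected(self):
        q = QuestionDef("same", "binary", ("no", "yes"))
        with pytest.raises(ValueError):
            QuestionnaireSpec((q, q))

    def test_lookup_and_order(self, small_spec):
        assert small_spec["ord3"].n_levels == 3
        assert small_spec.variable_ids == ["bin_a", "bin_rev", "ord3", "ord5"]

    def test_yaml_roundtrip(self, small_spec, tmp_path):
        path = tmp_path / "q.yaml"
        small_spec.to_yaml(path)
        loaded = QuestionnaireSpec.from_yaml(path)
        assert loaded == small_spec


class TestEncodeVariables:
    def test_values(self, tiny_dataset):
        enc = encode_variables(tiny_dataset.raw_responses, tiny_dataset.spec)
        assert enc.loc["c1", "bin_a"] == 1.0
        assert enc.loc["k1", "bin_a"] == 0.0
        # reversed binary: "no" encodes to 1
        assert enc.loc["c1", "bin_rev"] == 1.0
        assert enc.loc["k1", "bin_rev"] == 0.0
        assert enc.loc["c2", "ord3"] == 0.5
        assert enc.loc["c2", "ord5"] == 0.25

    def test_missing_stays_missing(self, tiny_dataset):
        enc = encode_variables(tiny_dataset.raw_responses, tiny_dataset.spec)
        assert np.isnan(enc.loc["k9", "bin_a"])
        assert np.isnan(enc.loc["c3", "bin_rev"])

    def test_unknown_label_rejected_with_context(self, tiny_dataset):
        raw = tiny_dataset.raw_responses.copy()
        raw.loc["c1", "ord3"] = "bogus"
        with pytest.raises(ValueError, match="bogus.*ord3.*c1"):
            encode_variables(raw, tiny_dataset.spec)

    def test_range_invariant(self, null_study):
        enc = encode_variables(null_study.dataset.raw_responses,
                               null_study.dataset.spec)
        vals = enc.to_numpy().ravel()
        vals = vals[np.isfinite(vals)]
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_permutation_equivariance(self, tiny_dataset):
        raw = tiny_dataset.raw_responses
        enc = encode_variables(raw, tiny_dataset.spec)
        perm = raw.sample(frac=1, random_state=0)
        enc_perm = encode_variables(perm, tiny_dataset.spec)
        pd.testing.assert_frame_equal(enc_perm, enc.loc[perm.index])

    def test_encoding_is_spec_driven_not_data_driven(self, small_spec):
        # only the middle level observed: still encodes to 0.5, not rescaled
        raw = pd.DataFrame({"ord3": ["sometimes", "sometimes"]},
                           index=["p1", "p2"])
        enc = encode_variables(raw, small_spec)
        assert (enc["ord3"] == 0.5).all()


class TestParticipantMissingness:
    def test_majority_unanswered(self):
        n, k = 845, 423
        raw = pd.DataFrame(
            [["yes"] * (n - k) + [None] * k], index=["p"],
            columns=[f"v{i}" for i in range(n)],
        )
        frac = participant_missingness(raw, "p")
        assert frac == pytest.approx(k / n)
        assert frac > 0.5

    def test_extremes(self):
        raw = pd.DataFrame({"a": ["x", None], "b": ["y", None]},
                           index=["full", "empty"])
        assert participant_missingness(raw, "full") == 0.0
        assert participant_missingness(raw, "empty") == 1.0

    def test_zero_questions_rejected(self):
        with pytest.raises(ValueError):
            participant_missingness(pd.DataFrame(index=["p"]))

    def test_unknown_participant(self, tiny_dataset):
        with pytest.raises(KeyError):
            participant_missingness(tiny_dataset.raw_responses, "ghost")


def _one_participant_dataset(small_spec, **overrides):
    row = {
        "participant_id": "p1", "status": "case", "matched_set_id": None,
        "reference_age": 8.0, "delay": 2.0, "ses": 1, "urban_unit_index": 3,
        "pct_farmers": 0.1, "center_id": "c1",
        "attended_primary_school": True,
    }
    row.update(overrides)
    participants = pd.DataFrame([row])
    raw = pd.DataFrame(
        {"bin_a": ["yes"], "bin_rev": ["no"], "ord3": ["never"],
         "ord5": ["daily"]},
        index=["p1"],
    )
    return StudyDataset(participants=participants, raw_responses=raw,
                        spec=small_spec)


class TestApplyExclusions:
    @pytest.mark.parametrize(
        "overrides, rule",
        [
            ({"reference_age": 0.3, "attended_primary_school": False},
             RULE_AGE_WINDOW),
            ({"reference_age": 16.0}, RULE_AGE_WINDOW),
            ({"delay": 12.0}, RULE_DELAY),
            ({"reference_age": 5.0, "attended_primary_school": True},
             RULE_SCHOOL),
            ({"reference_age": np.nan}, RULE_UNUSABLE),
        ],
    )
    def test_single_rule(self, small_spec, overrides, rule):
        ds = _one_participant_dataset(small_spec, **overrides)
        filtered, log = apply_exclusions(ds)
        assert len(filtered.participants) == 0
        assert log.counts() == {rule: 1}

    def test_boundaries_inclusive(self, small_spec):
        for age in (0.5, 15.5):
            ds = _one_participant_dataset(small_spec, reference_age=age,
                                          attended_primary_school=age > 6)
            filtered, _ = apply_exclusions(ds)
            assert len(filtered.participants) == 1
        ds = _one_participant_dataset(small_spec, delay=10.0)
        filtered, _ = apply_exclusions(ds)
        assert len(filtered.participants) == 1

    def test_missingness_rule(self, small_spec):
        ds = _one_participant_dataset(small_spec)
        ds.raw_responses.loc["p1", ["bin_a", "bin_rev", "ord3"]] = None
        filtered, log = apply_exclusions(ds)
        assert log.counts() == {RULE_MISSINGNESS: 1}
        assert len(filtered.participants) == 0

    def test_school_missing_answer_not_excluded(self, small_spec):
        ds = _one_participant_dataset(small_spec, reference_age=4.0,
                                      attended_primary_school=None)
        filtered, _ = apply_exclusions(ds)
        assert len(filtered.participants) == 1

    def test_first_rule_logged(self, small_spec):
        # both missingness and age violated: missingness is logged (order)
        ds = _one_participant_dataset(small_spec, reference_age=0.3)
        ds.raw_responses.loc["p1", :] = None
        _, log = apply_exclusions(ds)
        assert log.counts() == {RULE_MISSINGNESS: 1}

    def test_control_inherits_case_delay(self, tiny_dataset):
        part = tiny_dataset.participants.copy()
        part.loc[part["participant_id"] == "c1", "delay"] = 12.0
        ds = StudyDataset(part, tiny_dataset.raw_responses, tiny_dataset.spec)
        filtered, log = apply_exclusions(ds)
        gone = set(log.records["participant_id"])
        assert {"c1", "k1"} <= gone  # case and its control both out

    def test_orphan_control_exempt_from_delay(self, tiny_dataset):
        filtered, log = apply_exclusions(tiny_dataset)
        # k9's matched case never returned a questionnaire: no delay, retained
        assert "k9" in set(filtered.participants["participant_id"])

    def test_monotone_in_rules(self, null_study):
        loose = ExclusionConfig(missingness_max=1.0, age_min=-1, age_max=99,
                                delay_max=99, school_age_cut=0)
        ds = null_study.dataset
        kept_loose = set(apply_exclusions(ds, loose)[0].participants
                         ["participant_id"])
        kept_default = set(apply_exclusions(ds)[0].participants
                           ["participant_id"])
        assert kept_default <= kept_loose


class TestSampleBuilders:
    def test_matched_sizes(self, tiny_dataset):
        filtered, log = apply_exclusions(tiny_dataset)
        strata = build_matched_sample(filtered, log)
        by_id = {s.stratum_id: s for s in strata}
        assert by_id["s1"].size == 2
        assert by_id["s2"].size == 3
        # unmatched case c3 and orphan control k9 dropped
        dropped = set(log.records.loc[log.records["rule"] == "unmatched",
                                      "participant_id"])
        assert {"c3", "k9"} <= dropped

    def test_case_without_surviving_control_dropped(self, tiny_dataset):
        part = tiny_dataset.participants
        keep = part["participant_id"] != "k1"
        ds = StudyDataset(part.loc[keep].reset_index(drop=True),
                          tiny_dataset.raw_responses.drop(index="k1"),
                          tiny_dataset.spec)
        strata = build_matched_sample(ds)
        assert {s.stratum_id for s in strata} == {"s2"}

    def test_sizes_only_2_or_3(self, null_study):
        filtered, log = apply_exclusions(null_study.dataset)
        strata = build_matched_sample(filtered, log)
        assert strata
        assert {s.size for s in strata} <= {2, 3}

    def test_propensity_keeps_unmatched(self, tiny_dataset):
        ids = build_propensity_sample(tiny_dataset)
        assert "c3" in ids and "k9" in ids

    def test_propensity_drops_missing_covariates(self, tiny_dataset):
        part = tiny_dataset.participants.copy()
        part.loc[part["participant_id"] == "c1", "pct_farmers"] = np.nan
        ds = StudyDataset(part, tiny_dataset.raw_responses, tiny_dataset.spec)
        log_ids = build_propensity_sample(ds)
        assert "c1" not in log_ids

    def test_propensity_empty_dataset(self, small_spec):
        ds = _one_participant_dataset(small_spec)
        empty = ds.subset([])
        assert build_propensity_sample(empty) == []


class TestSdFilter:
    def test_rare_binary_dropped(self):
        # prevalence 0.01 -> sd = sqrt(.01*.99) = 0.0995 < 0.1
        x = np.zeros(1000)
        x[:10] = 1.0
        mat = pd.DataFrame({"rare": x}, index=[f"p{i}" for i in range(1000)])
        kept, dropped = sd_filter(mat, mat.index.tolist(), 0.1)
        assert kept == []
        assert dropped.iloc[0]["reason"] == "low_sd"
        assert dropped.iloc[0]["sd"] == pytest.approx(np.sqrt(0.01 * 0.99))

    def test_constant_and_balanced(self):
        mat = pd.DataFrame(
            {"const": [0.5] * 10, "bal": [0, 1] * 5},
            index=[f"p{i}" for i in range(10)],
        )
        kept, dropped = sd_filter(mat, mat.index.tolist(), 0.1)
        assert kept == ["bal"]
        assert dropped["variable_id"].tolist() == ["const"]

    def test_all_missing_flagged_distinctly(self):
        mat = pd.DataFrame({"gone": [np.nan] * 5, "ok": [0, 1, 0, 1, 0]},
                           index=[f"p{i}" for i in range(5)])
        kept, dropped = sd_filter(mat, mat.index.tolist(), 0.1)
        assert kept == ["ok"]
        assert dropped.set_index("variable_id").loc["gone", "reason"] == \
            "all_missing"

    def test_sd_is_sample_specific(self):
        mat = pd.DataFrame({"v": [0, 0, 0, 1, 1, 1]},
                           index=[f"p{i}" for i in range(6)])
        kept_all, _ = sd_filter(mat, mat.index.tolist(), 0.1)
        kept_sub, _ = sd_filter(mat, ["p0", "p1", "p2"], 0.1)
        assert kept_all == ["v"] and kept_sub == []

    def test_empty_sample_rejected(self):
        mat = pd.DataFrame({"v": [0, 1]}, index=["a", "b"])
        with pytest.raises(ValueError):
            sd_filter(mat, [], 0.1)
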