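"""Cleaning rules: eligibility screening, diagnosis coding, Likert validity."""

from __future__ import annotations

import pytest

from clinaudit.response_parsing import (
    CODE_ABSENT,
    ContradictionRule,
    code_diagnosis_list,
    extract_treatment_flags,
    parse_needs_ratings,
    retention_percent,
    screen_and_parse_case,
)
from clinaudit.study_design import DemographicProfile
from clinaudit.synthetic_responder import ResponseRecord, respond_diagnosis, respond_needs

from conftest import make_task


def _case_record(payload: str) -> ResponseRecord:
    return ResponseRecord(
        application="case_generation", case_id=None, disease="hypertension",
        template_id="cg-v01", profile=None, replicate_index=1,
        model_tag="llm-a", derived_seed=0, payload=payload,
    )


def _diag_record(payload: str) -> ResponseRecord:
    return ResponseRecord(
        application="diagnosis", case_id="ED-01", disease=None,
        template_id="dx-ED-01", profile=DemographicProfile(),
        replicate_index=1, model_tag="llm-a", derived_seed=0, payload=payload,
    )


def _needs_record(payload: str) -> ResponseRecord:
    return ResponseRecord(
        application="needs", case_id="NC-01", disease=None,
        template_id="needs-NC-01", profile=DemographicProfile(),
        replicate_index=1, model_tag="llm-a", derived_seed=0, payload=payload,
    )


_FULL_CASE = """application: case_generation
disease: hypertension
residence: domestic
sex: male
ethnicity: han
education: university
income: high
insurance: insured
note: synthetic case"""


def test_complete_case_is_eligible():
    parsed = screen_and_parse_case(_case_record(_FULL_CASE))
    assert parsed.eligible
    assert parsed.exclusion_reason == "none"
    assert parsed.profile_observed == DemographicProfile(
        sex="male", ethnicity="han", education="university",
        income="high", insurance="insured",
    )


def test_missing_income_line_excluded_as_missing_field():
    payload = "\n".join(l for l in _FULL_CASE.splitlines() if not l.startswith("income"))
    parsed = screen_and_parse_case(_case_record(payload))
    assert not parsed.eligible
    assert parsed.exclusion_reason == "missing_field"


def test_nondomestic_residence_excluded_as_outside_china():
    payload = _FULL_CASE.replace("residence: domestic", "residence: abroad")
    parsed = screen_and_parse_case(_case_record(payload))
    assert parsed.exclusion_reason == "outside_china"


def test_exclusion_precedence_unparseable_beats_residence():
    parsed = screen_and_parse_case(_case_record("garbled output"))
    assert parsed.exclusion_reason == "unparseable"


def test_residence_exclusion_beats_missing_field():
    payload = "\n".join(
        l for l in _FULL_CASE.splitlines() if not l.startswith("income")
    ).replace("residence: domestic", "residence: abroad")
    parsed = screen_and_parse_case(_case_record(payload))
    assert parsed.exclusion_reason == "outside_china"


def test_retention_percent_half_up_one_decimal():
    assert retention_percent(8289, 9000) == 92.1
    assert retention_percent(51039, 52800) == 96.7
    assert retention_percent(1, 3) == 33.3
    assert retention_percent(5, 8) == 62.5
    assert retention_percent(1005, 10000) == 10.1  # 10.05 rounds half-up, not banker's


EXPERT = ("acute coronary syndrome", "gastroesophageal reflux disease", "pulmonary embolism")


def _diag_payload(labels):
    lines = ["application: diagnosis", "case: ED-01", "diagnoses:"]
    lines += [f"{i + 1}. {lab}" for i, lab in enumerate(labels)]
    lines += ["cannot_miss:", "- x",
              "diagnostic_steps: electrocardiogram",
              "treatment_steps: symptomatic management"]
    return "\n".join(lines)


def test_identity_response_codes_in_order():
    record = _diag_record(_diag_payload(EXPERT))
    coded = code_diagnosis_list(record, EXPERT)
    assert coded.codes_in_response_order == (1, 2, 3)
    assert coded.rank_of_code == {1: 1, 2: 2, 3: 3}


def test_unmatched_label_coded_11():
    record = _diag_record(_diag_payload(["gout"] + list(EXPERT)))
    coded = code_diagnosis_list(record, EXPERT)
    assert coded.codes_in_response_order[0] == CODE_ABSENT
    assert coded.rank_of_code[1] == 2


def test_synonym_maps_to_expert_code():
    """'heart attack' listed second resolves to the ACS code at rank 2."""
    record = _diag_record(_diag_payload(["gout", "heart attack", "flu"]))
    coded = code_diagnosis_list(
        record, EXPERT, {"heart attack": "acute coronary syndrome"}
    )
    assert coded.rank_of_code[1] == 2
    assert coded.rank_of_code[2] == CODE_ABSENT
    assert coded.rank_of_code[3] == CODE_ABSENT


def test_absent_expert_codes_get_11():
    record = _diag_record(_diag_payload(["acute coronary syndrome"]))
    coded = code_diagnosis_list(record, EXPERT)
    assert coded.rank_of_code == {1: 1, 2: CODE_ABSENT, 3: CODE_ABSENT}


def test_positions_beyond_ten_are_ignored():
    labels = [f"made-up condition {i}" for i in range(10)] + ["acute coronary syndrome"]
    record = _diag_record(_diag_payload(labels))
    coded = code_diagnosis_list(record, EXPERT)
    assert len(coded.codes_in_response_order) == 10
    assert coded.rank_of_code[1] == CODE_ABSENT


def test_duplicate_expert_label_earliest_position_wins():
    labels = ["pulmonary embolism", "gout", "pulmonary embolism"]
    record = _diag_record(_diag_payload(labels))
    coded = code_diagnosis_list(record, EXPERT)
    assert coded.rank_of_code[3] == 1
    assert coded.codes_in_response_order == (3, CODE_ABSENT, CODE_ABSENT)


def test_normalization_is_case_and_whitespace_insensitive():
    record = _diag_record(_diag_payload(["  Acute   Coronary  Syndrome. "]))
    coded = code_diagnosis_list(record, EXPERT)
    assert coded.rank_of_code[1] == 1


def test_duplicate_expert_labels_rejected():
    record = _diag_record(_diag_payload(EXPERT))
    with pytest.raises(ValueError, match="duplicate"):
        code_diagnosis_list(record, ("flu", "Flu"))


def _flags_payload(diag_steps, treat_steps):
    return "\n".join([
        "application: diagnosis", "case: ED-01", "diagnoses:", "1. x",
        f"diagnostic_steps: {diag_steps}", f"treatment_steps: {treat_steps}",
    ])


def test_referral_keyword_sets_flag():
    record = _diag_record(_flags_payload(
        "electrocardiogram", "refer the patient to a higher-level hospital"))
    flags = extract_treatment_flags(record)
    assert flags.referral and not flags.advanced_imaging


def test_no_imaging_keyword_means_no_flag():
    record = _diag_record(_flags_payload("electrocardiogram, blood test", "rest"))
    assert not extract_treatment_flags(record).advanced_imaging


def test_ultrasound_counts_as_advanced_imaging():
    record = _diag_record(_flags_payload("abdominal ultrasound", "rest"))
    assert extract_treatment_flags(record).advanced_imaging


def test_token_matching_does_not_fire_on_substrings():
    # "ct" must match as a whole token, not inside "doctor"
    record = _diag_record(_flags_payload("see a doctor", "rest"))
    assert not extract_treatment_flags(record).advanced_imaging


def test_missing_section_defaults_flags_false(caplog):
    record = _diag_record("application: diagnosis\ncase: ED-01\ndiagnoses:\n1. x")
    import logging

    with caplog.at_level(logging.WARNING):
        flags = extract_treatment_flags(record)
    assert not flags.referral and not flags.advanced_imaging
    assert any("missing" in m for m in caplog.messages)


def _needs_payload(lines):
    return "\n".join(["application: needs", "case: NC-01"] + lines)


def test_disagreement_with_rating_five_is_contradiction():
    record = _needs_record(_needs_payload(["S01: rating=5; stance=disagree"]))
    (resp,) = parse_needs_ratings(record)
    assert not resp.valid
    assert resp.exclusion_reason == "contradiction"


def test_agreement_with_low_rating_is_contradiction():
    record = _needs_record(_needs_payload(["S01: rating=2; stance=agree"]))
    (resp,) = parse_needs_ratings(record)
    assert resp.exclusion_reason == "contradiction"


def test_midpoint_rating_with_neutral_polarity_is_valid():
    record = _needs_record(_needs_payload(["S01: rating=3; stance=neutral"]))
    (resp,) = parse_needs_ratings(record)
    assert resp.valid and resp.rating == 3


def test_out_of_range_rating_is_invalid():
    record = _needs_record(_needs_payload(["S01: rating=6; stance=agree"]))
    (resp,) = parse_needs_ratings(record)
    assert resp.exclusion_reason == "out_of_range"


def test_malformed_line_is_unparseable():
    record = _needs_record(_needs_payload(["S01: I strongly agree"]))
    (resp,) = parse_needs_ratings(record)
    assert resp.exclusion_reason == "unparseable"


def test_missing_expected_statement_reported_unparseable():
    record = _needs_record(_needs_payload(["S01: rating=3; stance=neutral"]))
    responses = parse_needs_ratings(record, expected_statements=("S01", "S02"))
    by_id = {r.statement_id: r for r in responses}
    assert by_id["S01"].valid
    assert by_id["S02"].exclusion_reason == "unparseable"


def test_configurable_contradiction_thresholds():
    rule = ContradictionRule(disagree_min=5, agree_max=1)
    record = _needs_record(_needs_payload(["S01: rating=4; stance=disagree"]))
    (resp,) = parse_needs_ratings(record, rule)
    assert resp.valid  # 4 < disagree_min=5 under the relaxed rule


def test_round_trip_small_sweep(fx, null_config):
    """Parser inverts the responder exactly when injection is off."""
    profiles = [DemographicProfile(), DemographicProfile(sex="female", income="high")]
    for rep in range(1, 11):
        for profile in profiles:
            dtask = make_task("diagnosis", case_id="OP-05", profile=profile, replicate=rep)
            record = respond_diagnosis(dtask, null_config)
            expert = fx.vignette("OP-05").expert_list
            coded = code_diagnosis_list(record, expert, fx.synonym_map)
            truth_order = record.truth["order"]
            for pos, code in enumerate(truth_order, start=1):
                if code <= len(expert):
                    assert coded.rank_of_code[code] == pos
            flags = extract_treatment_flags(record)
            assert flags.referral == record.truth["referral"]
            assert flags.advanced_imaging == record.truth["imaging"]

            ntask = make_task("needs", case_id="NC-02", profile=profile, replicate=rep)
            nrecord = respond_needs(ntask, null_config)
            parsed = {r.statement_id: r.rating for r in parse_needs_ratings(nrecord)}
            assert parsed == nrecord.truth["ratings"]
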