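"""Behaviour of the bias-injectable synthetic responder."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from clinaudit.response_parsing import (
    code_diagnosis_list,
    extract_treatment_flags,
    parse_needs_ratings,
    screen_and_parse_case,
)
from clinaudit.study_design import DemographicProfile
from clinaudit.synthetic_responder import (
    CaseGenConfig,
    SyntheticResponder,
    respond_case_generation,
    respond_diagnosis,
    respond_needs,
)

from conftest import make_task


def _with_case_gen(config, **kwargs):
    return dataclasses.replace(
        config, case_gen=dataclasses.replace(config.case_gen, **kwargs)
    )


def _with_diagnosis(config, **kwargs):
    return dataclasses.replace(
        config, diagnosis=dataclasses.replace(config.diagnosis, **kwargs)
    )


def _with_needs(config, **kwargs):
    return dataclasses.replace(
        config, needs=dataclasses.replace(config.needs, **kwargs)
    )


def test_identical_task_and_config_yield_identical_payloads(null_config):
    task = make_task("diagnosis", case_id="ED-01", profile=DemographicProfile())
    r1 = respond_diagnosis(task, null_config)
    r2 = respond_diagnosis(task, null_config)
    assert r1.payload == r2.payload


def test_null_config_diagnosis_emits_expert_order_verbatim(fx, null_config):
    for case_id in ("ED-01", "OP-03"):
        task = make_task("diagnosis", case_id=case_id, profile=DemographicProfile())
        record = respond_diagnosis(task, null_config)
        coded = code_diagnosis_list(record, fx.vignette(case_id).expert_list, fx.synonym_map)
        k = len(fx.vignette(case_id).expert_list)
        assert coded.codes_in_response_order[:k] == tuple(range(1, k + 1))
        assert all(coded.rank_of_code[c] == c for c in range(1, k + 1))


def test_degenerate_sex_distribution_always_emits_male(fx, null_config):
    dists = {d: dict(v) for d, v in null_config.case_gen.distributions.items()}
    dists["hypertension"] = {**dists["hypertension"], "sex": {"male": 1.0, "female": 0.0}}
    config = _with_case_gen(null_config, distributions=dists)
    for rep in range(1, 20):
        task = make_task("case_generation", disease="hypertension", replicate=rep)
        record = respond_case_generation(task, config)
        assert "sex: male" in record.payload


def test_case_generation_sampling_matches_configured_probability(fx, null_config):
    """Sampled male share lands within 3 binomial SE of P(male)=0.7."""
    dists = {d: dict(v) for d, v in null_config.case_gen.distributions.items()}
    dists["diabetes"] = {**dists["diabetes"], "sex": {"male": 0.7, "female": 0.3}}
    config = _with_case_gen(null_config, distributions=dists)
    n = 10_000
    males = 0
    for rep in range(1, n + 1):
        task = make_task("case_generation", disease="diabetes", replicate=rep, master_seed=5)
        if respond_case_generation(task, config).truth["demographics"]["sex"] == "male":
            males += 1
    se = (0.7 * 0.3 / n) ** 0.5
    assert abs(males / n - 0.7) < 3 * se


def test_null_case_generation_sampling_is_uniform(null_config):
    """Null config: each level within 3 binomial SE of 0.5 at n=10,000."""
    n = 10_000
    counts = {attr: 0 for attr in ("sex", "ethnicity", "education", "income", "insurance")}
    first = {"sex": "male", "ethnicity": "han", "education": "primary_school",
             "income": "low", "insurance": "insured"}
    for rep in range(1, n + 1):
        task = make_task("case_generation", disease="hypertension", replicate=rep, master_seed=9)
        demo = respond_case_generation(task, null_config).truth["demographics"]
        for attr, lvl in first.items():
            counts[attr] += demo[attr] == lvl
    se = (0.25 / n) ** 0.5
    for attr, k in counts.items():
        assert abs(k / n - 0.5) < 3 * se, attr


def test_missing_field_probability_one_forces_downstream_exclusion(null_config):
    config = _with_case_gen(null_config, missing_field_prob=1.0)
    for rep in range(1, 30):
        task = make_task("case_generation", disease="hypertension", replicate=rep)
        parsed = screen_and_parse_case(respond_case_generation(task, config))
        assert not parsed.eligible
        assert parsed.exclusion_reason == "missing_field"


def test_unknown_disease_rejected(null_config):
    task = make_task("case_generation", disease="gout")
    with pytest.raises(KeyError, match="gout"):
        respond_case_generation(task, null_config)


def test_degenerate_referral_propensities(fx, null_config):
    config = _with_diagnosis(
        null_config,
        referral_probs={("insurance", "insured"): 0.0, ("insurance", "uninsured"): 1.0},
    )
    for rep in range(1, 20):
        insured = make_task("diagnosis", case_id="ED-02",
                            profile=DemographicProfile(insurance="insured"), replicate=rep)
        uninsured = make_task("diagnosis", case_id="ED-02",
                              profile=DemographicProfile(insurance="uninsured"), replicate=rep)
        assert not extract_treatment_flags(respond_diagnosis(insured, config)).referral
        assert extract_treatment_flags(respond_diagnosis(uninsured, config)).referral


def test_rank_shift_raises_mean_primary_rank_for_shifted_group(fx, null_config):
    """+2 shift on the primary for uninsured pushes its mean rank up."""
    config = _with_diagnosis(
        null_config,
        rank_shifts={("insurance", "uninsured"): {1: 2}},
        rank_noise_sd=1.0,
    )
    expert = fx.vignette("ED-01").expert_list
    means = {}
    for level in ("insured", "uninsured"):
        ranks = []
        for rep in range(1, 401):
            task = make_task("diagnosis", case_id="ED-01",
                             profile=DemographicProfile(insurance=level),
                             replicate=rep, master_seed=3)
            coded = code_diagnosis_list(respond_diagnosis(task, config), expert, fx.synonym_map)
            ranks.append(coded.rank_of_code[1])
        means[level] = sum(ranks) / len(ranks)
    assert means["uninsured"] > means["insured"]


def test_missing_expert_baseline_rejected(null_config):
    task = make_task("diagnosis", case_id="ZZ-99", profile=DemographicProfile())
    with pytest.raises(KeyError, match="ZZ-99"):
        respond_diagnosis(task, null_config)


def test_needs_zero_noise_zero_shift_emits_constant_rating(fx, null_config):
    means = {sid: 3.0 for sid in null_config.needs.baseline_means}
    config = _with_needs(null_config, baseline_means=means, noise_scale=0.0)
    task = make_task("needs", case_id="NC-01", profile=DemographicProfile())
    for resp in parse_needs_ratings(respond_needs(task, config), expected_statements=None):
        assert resp.rating == 3
        assert resp.valid


def test_needs_ratings_always_in_1_to_5(fx, null_config):
    config = _with_needs(null_config, noise_scale=4.0)
    for rep in range(1, 50):
        task = make_task("needs", case_id="NC-03",
                         profile=DemographicProfile(sex="female"), replicate=rep)
        for resp in parse_needs_ratings(respond_needs(task, config)):
            assert resp.rating in {1, 2, 3, 4, 5}


def test_contradiction_probability_one_excludes_every_statement(null_config):
    config = _with_needs(null_config, contradiction_prob=1.0)
    for rep in range(1, 20):
        task = make_task("needs", case_id="NC-05",
                         profile=DemographicProfile(), replicate=rep)
        for resp in parse_needs_ratings(respond_needs(task, config)):
            assert not resp.valid
            assert resp.exclusion_reason == "contradiction"


def test_null_config_symmetric_across_levels(fx, null_config):
    """Under the null config the rating distribution is level-invariant."""
    responder = SyntheticResponder(null_config)
    pools = {"male": [], "female": []}
    for rep in range(1, 301):
        for sex in pools:
            task = make_task("needs", case_id="NC-01",
                             profile=DemographicProfile(sex=sex), replicate=rep,
                             master_seed=17)
            pools[sex].extend(
                r.rating for r in parse_needs_ratings(responder(task)) if r.valid
            )
    m0 = np.mean(pools["male"])
    m1 = np.mean(pools["female"])
    pooled_sd = np.std(pools["male"] + pools["female"], ddof=1)
    se = pooled_sd * (2 / len(pools["male"])) ** 0.5
    assert abs(m0 - m1) < 3 * se


def test_invalid_probability_rejected(null_config):
    with pytest.raises(ValueError, match="missing_field_prob"):
        CaseGenConfig(distributions=null_config.case_gen.distributions,
                      missing_field_prob=1.5)


def test_distribution_not_summing_to_one_rejected():
    with pytest.raises(ValueError, match="sums to"):
        CaseGenConfig(distributions={"hypertension": {"sex": {"male": 0.6, "female": 0.5}}})
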