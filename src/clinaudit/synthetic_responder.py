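"""A seedable synthetic responder standing in for live LLM APIs.

Audits of live language models cannot be reproduced offline, so the
pipeline is exercised against a configurable stochastic responder that
emits structured text in a fixed dialect. Its bias model covers the three
applications:

* case generation — demographics sampled from per-disease categorical
  distributions, with optional missing-field and out-of-scope-residence
  injection (so cleaning rules have something to exclude);
* diagnosis — additive integer rank shifts (plus optional symmetric
  integer noise) applied to the expert baseline order, attribute-level
  referral / advanced-imaging propensities, and off-list label insertion;
* needs assessment — Likert ratings drawn around per-statement baseline
  means with attribute-level mean shifts, plus contradiction injection.

With all bias parameters at zero (the *null* configuration) every parsed
quantity is distributionally identical across demographic subgroups, which
is what calibrates the audit's false-discovery behaviour.

The responder dialect is line-oriented ``key: value`` text with a numbered
diagnosis list, chosen to be deterministic and exactly invertible by
:mod:`clinaudit.response_parsing` when injection is off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

import numpy as np

from .fixtures import Fixtures, MODEL_TEMPERATURES
from .study_design import ATTRIBUTES, LEVELS, DemographicProfile, Task

__all__ = [
    "CaseGenConfig",
    "DiagnosisConfig",
    "NeedsConfig",
    "ResponderConfig",
    "ResponseRecord",
    "SyntheticResponder",
    "make_null_config",
    "respond_case_generation",
    "respond_diagnosis",
    "respond_needs",
]

AttrLevel = tuple[str, str]  # (attribute, level)


def _check_prob(p: float, name: str) -> None:
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass
class CaseGenConfig:
    """Per-disease demographic sampling for case generation."""

    #: disease -> attribute -> level -> probability
    distributions: Mapping[str, Mapping[str, Mapping[str, float]]]
    missing_field_prob: float = 0.0
    out_of_scope_prob: float = 0.0

    def __post_init__(self) -> None:
        _check_prob(self.missing_field_prob, "missing_field_prob")
        _check_prob(self.out_of_scope_prob, "out_of_scope_prob")
        for disease, dists in self.distributions.items():
            for attr, levels in dists.items():
                total = sum(levels.values())
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"distribution for {disease}/{attr} sums to {total}, not 1"
                    )
                for level, p in levels.items():
                    _check_prob(p, f"P({disease}/{attr}={level})")


@dataclass
class DiagnosisConfig:
    """Rank perturbation and treatment propensities for the diagnosis task."""

    #: case -> ten baseline labels (expert list padded with distractors)
    baselines: Mapping[str, tuple[str, ...]]
    #: (attribute, level) -> {expert code (1-based baseline position) -> shift}
    rank_shifts: Mapping[AttrLevel, Mapping[int, int]] = field(default_factory=dict)
    rank_noise_sd: float = 0.0
    referral_base: float = 0.10
    #: (attribute, level) -> referral probability override; later attributes
    #: in the canonical order override earlier ones
    referral_probs: Mapping[AttrLevel, float] = field(default_factory=dict)
    imaging_base: float = 0.30
    imaging_probs: Mapping[AttrLevel, float] = field(default_factory=dict)
    offlist_prob: float = 0.0
    #: labels available for off-list insertion, per case
    offlist_labels: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rank_noise_sd < 0:
            raise ValueError("rank_noise_sd must be >= 0")
        _check_prob(self.referral_base, "referral_base")
        _check_prob(self.imaging_base, "imaging_base")
        _check_prob(self.offlist_prob, "offlist_prob")
        for key, p in {**dict(self.referral_probs), **dict(self.imaging_probs)}.items():
            _check_prob(p, f"propensity for {key}")
        for case, labels in self.baselines.items():
            if len(labels) != 10 or len(set(labels)) != 10:
                raise ValueError(f"baseline for {case} must hold 10 distinct labels")


@dataclass
class NeedsConfig:
    """Likert-generation parameters for the needs-assessment task."""

    #: statement -> baseline mean on the 1..5 scale
    baseline_means: Mapping[str, float]
    #: case -> ordered statement ids
    statements_by_case: Mapping[str, tuple[str, ...]]
    noise_scale: float = 1.0
    #: (attribute, level) -> {statement -> additive mean shift}
    mean_shifts: Mapping[AttrLevel, Mapping[str, float]] = field(default_factory=dict)
    contradiction_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        _check_prob(self.contradiction_prob, "contradiction_prob")
        for sid, mu in self.baseline_means.items():
            if not 1.0 <= mu <= 5.0:
                raise ValueError(f"baseline mean for {sid} must be in [1, 5], got {mu}")


@dataclass
class ResponderConfig:
    model_tag: str
    case_gen: CaseGenConfig
    diagnosis: DiagnosisConfig
    needs: NeedsConfig
    temperature_meta: float = 0.7  # recorded, never used computationally

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature_meta <= 1.0:
            raise ValueError("temperature_meta must be in [0, 1]")


@dataclass(frozen=True)
class ResponseRecord:
    """One raw responder output with full task provenance.

    ``truth`` carries the responder's internal draws (sampled demographics,
    applied permutation, flags, ratings) for round-trip verification; it is
    never serialised into logs.
    """

    application: str
    case_id: Optional[str]
    disease: Optional[str]
    template_id: str
    profile: Optional[DemographicProfile]
    replicate_index: int
    model_tag: str
    derived_seed: int
    payload: str
    truth: Optional[dict] = None

    @classmethod
    def from_task(cls, task: Task, payload: str, truth: Optional[dict] = None) -> "ResponseRecord":
        return cls(
            application=task.application,
            case_id=task.case_id,
            disease=task.disease,
            template_id=task.template_id,
            profile=task.profile,
            replicate_index=task.replicate_index,
            model_tag=task.model_tag,
            derived_seed=task.derived_seed,
            payload=payload,
            truth=truth,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "application": self.application,
                "case_id": self.case_id,
                "disease": self.disease,
                "template_id": self.template_id,
                "profile": self.profile.as_dict() if self.profile else None,
                "replicate_index": self.replicate_index,
                "model_tag": self.model_tag,
                "derived_seed": self.derived_seed,
                "payload": self.payload,
            }
        )

    @classmethod
    def from_json(cls, line: str) -> "ResponseRecord":
        d = json.loads(line)
        profile = DemographicProfile(**d["profile"]) if d["profile"] else None
        return cls(
            application=d["application"], case_id=d["case_id"], disease=d["disease"],
            template_id=d["template_id"], profile=profile,
            replicate_index=d["replicate_index"], model_tag=d["model_tag"],
            derived_seed=d["derived_seed"], payload=d["payload"],
        )


def make_null_config(model_tag: str, fixtures: Fixtures) -> ResponderConfig:
    """Build the zero-bias calibration configuration.

    All rank shifts are zero (expert order emitted verbatim), treatment
    propensities are level-independent, demographic sampling is uniform,
    and no missing-field / out-of-scope / contradiction injection occurs.
    Likert rating noise stays at 1.0 so the needs channel remains
    stochastic (randomness is not bias); the diagnosis rank noise is zero.
    """
    uniform = {
        disease: {attr: {lvl: 0.5 for lvl in LEVELS[attr]} for attr in ATTRIBUTES}
        for disease in fixtures.diseases
    }
    baselines = {}
    offlist = {}
    for v in fixtures.vignettes:
        pad = [d for d in v.distractors if d not in v.expert_list]
        n_pad = 10 - len(v.expert_list)
        baselines[v.case_id] = tuple(v.expert_list) + tuple(pad[:n_pad])
        offlist[v.case_id] = tuple(pad[n_pad:])
    return ResponderConfig(
        model_tag=model_tag,
        temperature_meta=MODEL_TEMPERATURES.get(model_tag, 0.7),
        case_gen=CaseGenConfig(distributions=uniform),
        diagnosis=DiagnosisConfig(baselines=baselines, offlist_labels=offlist),
        needs=NeedsConfig(
            baseline_means={s.statement_id: s.baseline_mean for s in fixtures.statements},
            statements_by_case={
                c.case_id: tuple(s.statement_id for s in c.statements)
                for c in fixtures.needs_cases
            },
        ),
    )


def _task_rng(task: Task, rng: Optional[np.random.Generator]) -> np.random.Generator:
    # each task gets its own stream derived from its identity, so results do
    # not depend on execution order
    return rng if rng is not None else np.random.default_rng(task.derived_seed)


def respond_case_generation(
    task: Task, config: ResponderConfig, rng: Optional[np.random.Generator] = None
) -> ResponseRecord:
    """Emit a case-generation payload with sampled demographics."""
    if task.application != "case_generation":
        raise ValueError("task is not a case_generation task")
    cg = config.case_gen
    if task.disease not in cg.distributions:
        raise KeyError(f"unknown disease {task.disease!r}")
    g = _task_rng(task, rng)
    dists = cg.distributions[task.disease]
    sampled: dict[str, str] = {}
    for attr in ATTRIBUTES:
        levels = LEVELS[attr]
        p_first = dists[attr][levels[0]]
        sampled[attr] = levels[0] if g.random() < p_first else levels[1]
    out_of_scope = g.random() < cg.out_of_scope_prob
    missing_attr: Optional[str] = None
    if g.random() < cg.missing_field_prob:
        missing_attr = ATTRIBUTES[int(g.integers(0, len(ATTRIBUTES)))]
    lines = [
        "application: case_generation",
        f"disease: {task.disease}",
        f"residence: {'abroad' if out_of_scope else 'domestic'}",
    ]
    for attr in ATTRIBUTES:
        if attr != missing_attr:
            lines.append(f"{attr}: {sampled[attr]}")
    lines.append(f"note: synthetic teaching case describing a patient with {task.disease}")
    truth = {"demographics": sampled, "out_of_scope": out_of_scope, "missing": missing_attr}
    return ResponseRecord.from_task(task, "\n".join(lines), truth)


def _effective_prob(
    base: float, overrides: Mapping[AttrLevel, float], profile: DemographicProfile
) -> float:
    p = base
    for attr in ATTRIBUTES:
        key = (attr, profile.level(attr))
        if key in overrides:
            p = overrides[key]
    return p


_IMAGING_CHOICES = ("ct scan", "mri", "ultrasound")


def respond_diagnosis(
    task: Task, config: ResponderConfig, rng: Optional[np.random.Generator] = None
) -> ResponseRecord:
    """Emit a ranked ten-diagnosis payload with next-step sections.

    The ranking applies the profile's summed integer rank shifts (plus
    optional symmetric integer noise) to the baseline order, then re-sorts
    stably by perturbed score with the original index as tie-breaker, so
    zero perturbation reproduces the baseline verbatim.
    """
    if task.application != "diagnosis":
        raise ValueError("task is not a diagnosis task")
    dx = config.diagnosis
    if task.case_id not in dx.baselines:
        raise KeyError(f"no expert baseline for case {task.case_id!r}")
    if task.profile is None:
        raise ValueError("diagnosis task requires a demographic profile")
    g = _task_rng(task, rng)
    baseline = dx.baselines[task.case_id]
    profile = task.profile

    scores = np.arange(1, 11, dtype=float)
    for attr in ATTRIBUTES:
        shifts = dx.rank_shifts.get((attr, profile.level(attr)))
        if shifts:
            for code, delta in shifts.items():
                scores[code - 1] += delta
    if dx.rank_noise_sd > 0:
        scores += np.rint(g.normal(0.0, dx.rank_noise_sd, 10))
    order = np.argsort(scores, kind="stable")  # ties broken by original index
    ranked = [baseline[i] for i in order]

    inserted: Optional[tuple[int, str]] = None
    pool = dx.offlist_labels.get(task.case_id, ())
    if dx.offlist_prob > 0 and pool and g.random() < dx.offlist_prob:
        pos = int(g.integers(0, 10))
        label = pool[int(g.integers(0, len(pool)))]
        ranked.insert(pos, label)
        ranked = ranked[:10]
        inserted = (pos, label)

    imaging = g.random() < _effective_prob(dx.imaging_base, dx.imaging_probs, profile)
    referral = g.random() < _effective_prob(dx.referral_base, dx.referral_probs, profile)

    diag_steps = "history and physical examination, electrocardiogram, basic blood panel"
    if imaging:
        diag_steps += ", " + _IMAGING_CHOICES[int(g.integers(0, 3))]
    treat_steps = "symptomatic management and follow-up"
    if referral:
        treat_steps += ", referral to another hospital"

    lines = ["application: diagnosis", f"case: {task.case_id}", "diagnoses:"]
    lines.extend(f"{i + 1}. {label}" for i, label in enumerate(ranked))
    lines.append("cannot_miss:")
    lines.append(f"- {baseline[1]}")
    lines.append(f"- {baseline[3]}")
    lines.append(f"diagnostic_steps: {diag_steps}")
    lines.append(f"treatment_steps: {treat_steps}")
    truth = {
        "order": [int(i) + 1 for i in order],  # baseline codes in emitted order
        "inserted": inserted,
        "referral": referral,
        "imaging": imaging,
    }
    return ResponseRecord.from_task(task, "\n".join(lines), truth)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def respond_needs(
    task: Task, config: ResponderConfig, rng: Optional[np.random.Generator] = None
) -> ResponseRecord:
    """Emit one Likert rating line per statement of the task's case.

    Ratings are a continuous draw around the shifted baseline mean,
    rounded half-up and clipped to 1..5, with a polarity token consistent
    with the rating unless contradiction injection flips it.
    """
    if task.application != "needs":
        raise ValueError("task is not a needs task")
    nd = config.needs
    if task.case_id not in nd.statements_by_case:
        raise KeyError(f"unknown needs case {task.case_id!r}")
    if task.profile is None:
        raise ValueError("needs task requires a demographic profile")
    g = _task_rng(task, rng)
    profile = task.profile
    lines = ["application: needs", f"case: {task.case_id}"]
    ratings: dict[str, int] = {}
    contradicted: list[str] = []
    for sid in nd.statements_by_case[task.case_id]:
        mu = nd.baseline_means[sid]
        for attr in ATTRIBUTES:
            shifts = nd.mean_shifts.get((attr, profile.level(attr)))
            if shifts:
                mu += shifts.get(sid, 0.0)
        x = g.normal(mu, nd.noise_scale) if nd.noise_scale > 0 else mu
        rating = min(5, max(1, _round_half_up(x)))
        stance = "agree" if rating >= 4 else ("disagree" if rating <= 2 else "neutral")
        if nd.contradiction_prob > 0 and g.random() < nd.contradiction_prob:
            if rating >= 4:
                stance = "disagree"
            elif rating <= 2:
                stance = "agree"
            else:  # force an unambiguous contradiction at the midpoint
                rating, stance = 5, "disagree"
            contradicted.append(sid)
        ratings[sid] = rating
        lines.append(f"{sid}: rating={rating}; stance={stance}")
    truth = {"ratings": ratings, "contradicted": contradicted}
    return ResponseRecord.from_task(task, "\n".join(lines), truth)


_DISPATCH: dict[str, Callable[..., ResponseRecord]] = {
    "case_generation": respond_case_generation,
    "diagnosis": respond_diagnosis,
    "needs": respond_needs,
}


class SyntheticResponder:
    """Callable responder satisfying the pipeline contract (task -> record).

    Any object with the same signature — e.g. an adapter replaying logs
    from a live API — can be plugged into the pipeline in its place.
    """

    name = "synthetic"

    def __init__(self, config: ResponderConfig):
        self.config = config

    def __call__(self, task: Task) -> ResponseRecord:
        try:
            fn = _DISPATCH[task.application]
        except KeyError:
            raise ValueError(f"unknown application {task.application!r}") from None
        return fn(task, self.config)
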