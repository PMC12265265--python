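"""Factorial counterfactual study designs for the three audit applications.

The audit probes a clinical language model in three scenarios:

* ``case_generation`` — the model writes teaching cases for a named disease
  and chooses the patient demographics itself; prompts carry no demographic
  placeholders.
* ``diagnosis`` — the model ranks differential diagnoses and suggests next
  steps for a fixed vignette whose patient demographics are varied
  counterfactually over a full 2^5 factorial of five binary attributes.
* ``needs`` — the model rates Likert statements about a patient whose
  demographics are varied the same way.

This module enumerates the factorial profiles, instantiates prompt text,
and expands a design into a deterministic, seed-carrying task plan.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import string
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

__all__ = [
    "ATTRIBUTES",
    "LEVELS",
    "APPLICATIONS",
    "DemographicProfile",
    "PromptTemplate",
    "Task",
    "StudyPlan",
    "DesignParams",
    "enumerate_profiles",
    "build_plan",
    "instantiate_prompt",
    "derive_seed",
]

#: Fixed attribute order; profile identity and task ordering depend on it.
ATTRIBUTES: tuple[str, ...] = ("sex", "ethnicity", "education", "income", "insurance")

#: Binary levels per attribute; the first-listed level is the default used
#: when an attribute is held fixed in a partial factorial.
LEVELS: dict[str, tuple[str, str]] = {
    "sex": ("male", "female"),
    "ethnicity": ("han", "minority"),
    "education": ("primary_school", "university"),
    "income": ("low", "high"),
    "insurance": ("insured", "uninsured"),
}

APPLICATIONS = ("case_generation", "diagnosis", "needs")

_SEED_MASK = (1 << 63) - 1


@dataclass(frozen=True, slots=True)
class DemographicProfile:
    """One assignment of the five binary sociodemographic attributes."""

    sex: str = "male"
    ethnicity: str = "han"
    education: str = "primary_school"
    income: str = "low"
    insurance: str = "insured"

    def __post_init__(self) -> None:
        for attr in ATTRIBUTES:
            value = getattr(self, attr)
            if value not in LEVELS[attr]:
                raise ValueError(
                    f"invalid level {value!r} for attribute {attr!r}; "
                    f"allowed: {LEVELS[attr]}"
                )

    def level(self, attribute: str) -> str:
        if attribute not in LEVELS:
            raise KeyError(f"unknown attribute {attribute!r}")
        return getattr(self, attribute)

    def as_dict(self) -> dict[str, str]:
        return {a: getattr(self, a) for a in ATTRIBUTES}

    def key(self) -> str:
        """Canonical string identity, used in seeds and logs."""
        return "|".join(getattr(self, a) for a in ATTRIBUTES)


@dataclass(frozen=True, slots=True)
class PromptTemplate:
    """A prompt body with named placeholders.

    Case-generation templates may reference ``{disease}``; diagnosis and
    needs templates reference the five demographic attributes. Placeholders
    use :mod:`string` formatting syntax.
    """

    template_id: str
    application: str
    body: str
    case_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.application not in APPLICATIONS:
            raise ValueError(f"unknown application {self.application!r}")
        if not self.body:
            raise ValueError("template body must be non-empty")
        allowed = set(ATTRIBUTES) | {"disease"}
        extra = set(self.placeholders()) - allowed
        if extra:
            raise ValueError(f"unknown placeholders in {self.template_id}: {sorted(extra)}")

    def placeholders(self) -> tuple[str, ...]:
        names = []
        for _, fname, _, _ in string.Formatter().parse(self.body):
            if fname:
                names.append(fname)
        return tuple(dict.fromkeys(names))


@dataclass(frozen=True, slots=True)
class Task:
    """One unit of work: a prompt instance to be executed by a responder."""

    application: str
    template_id: str
    case_id: Optional[str]
    disease: Optional[str]
    profile: Optional[DemographicProfile]
    replicate_index: int
    model_tag: str
    derived_seed: int

    def provenance(self) -> dict:
        return {
            "application": self.application,
            "template_id": self.template_id,
            "case_id": self.case_id,
            "disease": self.disease,
            "profile": self.profile.as_dict() if self.profile else None,
            "replicate_index": self.replicate_index,
            "model_tag": self.model_tag,
            "derived_seed": self.derived_seed,
        }


@dataclass(frozen=True)
class StudyPlan:
    application: str
    tasks: tuple[Task, ...]
    master_seed: int

    def __len__(self) -> int:
        return len(self.tasks)

    def to_jsonl(self) -> str:
        """One task per line, stable field order."""
        return "\n".join(json.dumps(t.provenance(), sort_keys=False) for t in self.tasks)


@dataclass(frozen=True)
class DesignParams:
    """Design parameters expanded by :func:`build_plan`.

    ``templates`` supplies the prompts. For case generation every template
    is crossed with every disease; for diagnosis/needs each template is
    bound to its case and crossed with the factorial profiles.
    """

    templates: tuple[PromptTemplate, ...]
    model_tags: tuple[str, ...]
    replicates: int
    diseases: tuple[str, ...] = ()
    profiles: tuple[DemographicProfile, ...] = ()

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        if not self.templates:
            raise ValueError("at least one template is required")
        if not self.model_tags:
            raise ValueError("at least one model tag is required")


def enumerate_profiles(
    attributes: Sequence[str] = ATTRIBUTES,
) -> tuple[DemographicProfile, ...]:
    """Enumerate the full factorial over the given binary attributes.

    Returns 2^k distinct profiles in lexicographic order over the fixed
    attribute order (first-listed level first). Attributes not enumerated
    are held at their first-listed (default) level.
    """
    if not 1 <= len(attributes) <= len(ATTRIBUTES):
        raise ValueError("between 1 and 5 attributes required")
    seen = set()
    for name in attributes:
        if name not in LEVELS:
            raise ValueError(f"unknown attribute {name!r}")
        if name in seen:
            raise ValueError(f"duplicate attribute {name!r}")
        seen.add(name)
    # iterate in the fixed canonical order regardless of request order
    varying = [a for a in ATTRIBUTES if a in seen]
    level_axes = [LEVELS[a] for a in varying]
    profiles = []
    for combo in itertools.product(*level_axes):
        values = dict(zip(varying, combo))
        profiles.append(DemographicProfile(**values))
    return tuple(profiles)


def derive_seed(
    master_seed: int,
    application: str,
    case_id: Optional[str],
    template_id: str,
    profile: Optional[DemographicProfile],
    replicate_index: int,
    model_tag: str,
) -> int:
    """Fold a canonical task identity into a 63-bit stream seed.

    A pure function of its arguments, so the seed of any task is independent
    of execution order and of the presence of other tasks in the plan.
    """
    key = "\x1f".join(
        [
            str(master_seed),
            application,
            case_id or "",
            template_id,
            profile.key() if profile is not None else "",
            str(replicate_index),
            model_tag,
        ]
    )
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") & _SEED_MASK


def build_plan(application: str, design: DesignParams, master_seed: int) -> StudyPlan:
    """Expand design parameters into the full deterministic task plan.

    Task counts follow the factorial arithmetic of each application:
    case generation crosses templates x diseases x replicates x models;
    diagnosis and needs cross case templates x profiles x replicates x
    models. Re-invocation with identical inputs yields an identical plan,
    including every derived seed.
    """
    if application not in APPLICATIONS:
        raise ValueError(f"unknown application {application!r}")
    tasks: list[Task] = []
    if application == "case_generation":
        if not design.diseases:
            raise ValueError("case_generation design requires diseases")
        for tpl in design.templates:
            for disease in design.diseases:
                for rep in range(1, design.replicates + 1):
                    for tag in design.model_tags:
                        # the disease plays the case role in the task identity
                        seed = derive_seed(
                            master_seed, application, disease,
                            tpl.template_id, None, rep, tag,
                        )
                        tasks.append(
                            Task(application, tpl.template_id, None, disease=disease,
                                 profile=None, replicate_index=rep, model_tag=tag,
                                 derived_seed=seed)
                        )
    else:
        if not design.profiles:
            raise ValueError(f"{application} design requires profiles")
        for tpl in design.templates:
            if tpl.case_id is None:
                raise ValueError(f"template {tpl.template_id} lacks a case_id")
            for profile in design.profiles:
                for rep in range(1, design.replicates + 1):
                    for tag in design.model_tags:
                        seed = derive_seed(
                            master_seed, application, tpl.case_id,
                            tpl.template_id, profile, rep, tag,
                        )
                        tasks.append(
                            Task(application, tpl.template_id, tpl.case_id,
                                 disease=None, profile=profile,
                                 replicate_index=rep, model_tag=tag,
                                 derived_seed=seed)
                        )
    return StudyPlan(application=application, tasks=tuple(tasks), master_seed=master_seed)


def instantiate_prompt(
    template: PromptTemplate,
    profile: Optional[DemographicProfile] = None,
    disease: Optional[str] = None,
    surface_forms: Optional[Mapping[str, Mapping[str, str]]] = None,
) -> str:
    """Render a template into final prompt text.

    ``surface_forms`` optionally maps attribute -> level -> display text
    (e.g. ``insurance="uninsured"`` -> "without health insurance"); by
    default the level token itself is substituted. Raises ``KeyError``
    naming any placeholder with no value.
    """
    values: dict[str, str] = {}
    if disease is not None:
        values["disease"] = disease
    if profile is not None:
        for a in ATTRIBUTES:
            level = profile.level(a)
            if surface_forms and a in surface_forms:
                values[a] = surface_forms[a].get(level, level)
            else:
                values[a] = level
    missing = [p for p in template.placeholders() if p not in values]
    if missing:
        raise KeyError(f"missing value for placeholder(s) {missing} in {template.template_id}")
    return template.body.format(**values)
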