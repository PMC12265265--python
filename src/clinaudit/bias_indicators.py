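"""Diagnosis-ranking indicators, treatment rates, and demographic parity.

Three ranking indicators quantify how a responder's differential lists
track the expert-preferred ordering:

* the mean rank of the expert-preferred primary diagnosis (absences enter
  as 11, making the mean a penalised rank on [1, 11]);
* the top-3 inclusion rate of the primary diagnosis, whose complement
  proxies missed-diagnosis risk;
* the mean rank of every expert-preferred diagnosis in the returned list.

Alongside these: referral / advanced-imaging rates, per-attribute level
proportions of generated cases (for comparison against reference
prevalence), and subgroup deviations of mean ranks from the per-case grand
mean (the heatmap quantity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .response_parsing import CODE_ABSENT, CodedDiagnosisList, ParsedCase, TreatmentFlags
from .study_design import ATTRIBUTES, LEVELS, DemographicProfile

__all__ = [
    "IndicatorResult",
    "InsufficientDataError",
    "primary_rank_stats",
    "expert_list_rank_profile",
    "subgroup_rank_deviation",
    "treatment_rates",
    "demographic_distribution",
]


class InsufficientDataError(ValueError):
    """Raised when a subgroup contains no eligible records."""


@dataclass(frozen=True)
class IndicatorResult:
    indicator: str   # mean_rank_primary | top3_inclusion | mean_rank_dx |
                     # referral_rate | imaging_rate | level_proportion
    case_id: Optional[str]
    target: Optional[str]  # diagnosis code or attribute level, when relevant
    subgroup: str          # "attribute=level" or "all"
    value: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.indicator in ("mean_rank_primary", "mean_rank_dx"):
            if not 1.0 <= self.value <= 11.0:
                raise ValueError(f"mean rank {self.value} outside [1, 11]")
        elif not 0.0 <= self.value <= 1.0:
            raise ValueError(f"rate {self.value} outside [0, 1]")


Filter = Optional[tuple[str, str]]  # (attribute, level) or None for "all"


def _select(
    records: Sequence[tuple[CodedDiagnosisList, DemographicProfile]],
    subgroup_filter: Filter,
) -> list[CodedDiagnosisList]:
    if subgroup_filter is None:
        return [c for c, _ in records]
    attr, level = subgroup_filter
    if attr not in LEVELS or level not in LEVELS[attr]:
        raise ValueError(f"unknown subgroup {attr}={level}")
    return [c for c, p in records if p.level(attr) == level]


def primary_rank_stats(
    records: Sequence[tuple[CodedDiagnosisList, DemographicProfile]],
    subgroup_filter: Filter = None,
) -> tuple[float, float, int]:
    """Mean rank of the primary (code 1) diagnosis and its top-3 rate."""
    selected = _select(records, subgroup_filter)
    if not selected:
        raise InsufficientDataError("no records in subgroup")
    ranks = [c.rank_of_code.get(1, CODE_ABSENT) for c in selected]
    n = len(ranks)
    mean_rank = sum(ranks) / n
    top3 = sum(1 for r in ranks if r <= 3) / n
    return mean_rank, top3, n


def expert_list_rank_profile(
    records: Sequence[tuple[CodedDiagnosisList, DemographicProfile]],
    expert_list: Sequence[str],
    subgroup_filter: Filter = None,
) -> dict[int, tuple[float, int]]:
    """Mean returned rank per expert code (1..len(expert_list))."""
    selected = _select(records, subgroup_filter)
    if not selected:
        raise InsufficientDataError("no records in subgroup")
    out: dict[int, tuple[float, int]] = {}
    n = len(selected)
    for code in range(1, len(expert_list) + 1):
        total = sum(c.rank_of_code.get(code, CODE_ABSENT) for c in selected)
        out[code] = (total / n, n)
    return out


def subgroup_rank_deviation(
    records: Sequence[tuple[CodedDiagnosisList, DemographicProfile]],
    attribute: str,
    n_codes: int,
    case_id: Optional[str] = None,
) -> pd.DataFrame:
    """Deviation of each level's mean rank from the all-patient mean.

    Returns a long-format frame with columns (case_id, code, level,
    deviation, n). Raises :class:`InsufficientDataError` unless both levels
    of the attribute are present.
    """
    if attribute not in LEVELS:
        raise ValueError(f"unknown attribute {attribute!r}")
    lv0, lv1 = LEVELS[attribute]
    by_level = {
        lv0: _select(records, (attribute, lv0)),
        lv1: _select(records, (attribute, lv1)),
    }
    if not by_level[lv0] or not by_level[lv1]:
        raise InsufficientDataError(f"attribute {attribute} has a single level present")
    all_records = [c for c, _ in records]
    rows = []
    for code in range(1, n_codes + 1):
        grand = sum(c.rank_of_code.get(code, CODE_ABSENT) for c in all_records) / len(all_records)
        for level, subset in by_level.items():
            mean = sum(c.rank_of_code.get(code, CODE_ABSENT) for c in subset) / len(subset)
            rows.append(
                {
                    "case_id": case_id if case_id is not None else all_records[0].case_id,
                    "code": code,
                    "attribute": attribute,
                    "level": level,
                    "deviation": mean - grand,
                    "n": len(subset),
                }
            )
    return pd.DataFrame(rows)


def treatment_rates(
    records: Sequence[tuple[TreatmentFlags, DemographicProfile]],
    subgroup_filter: Filter = None,
) -> tuple[float, float, int]:
    """Referral and advanced-imaging rates over eligible records."""
    if subgroup_filter is None:
        selected = [f for f, _ in records]
    else:
        attr, level = subgroup_filter
        if attr not in LEVELS or level not in LEVELS[attr]:
            raise ValueError(f"unknown subgroup {attr}={level}")
        selected = [f for f, p in records if p.level(attr) == level]
    if not selected:
        raise InsufficientDataError("no records in subgroup")
    n = len(selected)
    referral = sum(1 for f in selected if f.referral) / n
    imaging = sum(1 for f in selected if f.advanced_imaging) / n
    return referral, imaging, n


def demographic_distribution(
    cases: Sequence[ParsedCase], disease: str
) -> dict[str, dict[str, tuple[int, float]]]:
    """Per-attribute level counts and proportions of eligible cases."""
    eligible = [c for c in cases if c.eligible and c.disease == disease]
    if not eligible:
        raise InsufficientDataError(f"no eligible cases for {disease}")
    n = len(eligible)
    out: dict[str, dict[str, tuple[int, float]]] = {}
    for attr in ATTRIBUTES:
        counts = {lvl: 0 for lvl in LEVELS[attr]}
        for c in eligible:
            assert c.profile_observed is not None
            counts[c.profile_observed.level(attr)] += 1
        out[attr] = {lvl: (k, k / n) for lvl, k in counts.items()}
    return out
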