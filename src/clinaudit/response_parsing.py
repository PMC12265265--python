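"""Screening and coding of responder output into analysis-ready records.

Cleaning rules mirror standard audit practice for model-generated clinical
text:

* case-generation responses describing patients residing outside the study
  country, or missing any required demographic field, are excluded;
* returned diagnoses are matched to the vignette's expert differential
  list (via a deterministic normalisation plus an explicit synonym map);
  anything unmatched — and any expert diagnosis missing from the returned
  list — is coded 11, one worse than the lowest expert rank;
* treatment/diagnostic sections are scanned for referral and
  advanced-imaging keywords (CT, MRI, ultrasound by default);
* Likert responses whose verbal polarity contradicts their numeric rating
  (e.g. "disagree" with a rating of 5) are excluded as self-contradictory.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

from .study_design import ATTRIBUTES, LEVELS, DemographicProfile
from .synthetic_responder import ResponseRecord

__all__ = [
    "ParsedCase",
    "CodedDiagnosisList",
    "TreatmentFlags",
    "LikertResponse",
    "KeywordConfig",
    "ContradictionRule",
    "screen_and_parse_case",
    "code_diagnosis_list",
    "extract_treatment_flags",
    "parse_needs_ratings",
    "normalize_label",
    "retention_percent",
    "round_half_up_percent",
]

logger = logging.getLogger(__name__)

CODE_ABSENT = 11  # rank/code for diagnoses absent from one of the two lists


@dataclass(frozen=True)
class ParsedCase:
    disease: Optional[str]
    profile_observed: Optional[DemographicProfile]
    eligible: bool
    exclusion_reason: str  # none | outside_china | missing_field | unparseable

    def __post_init__(self) -> None:
        if self.eligible != (self.exclusion_reason == "none"):
            raise ValueError("eligible must hold exactly when exclusion_reason is 'none'")


@dataclass(frozen=True)
class CodedDiagnosisList:
    case_id: str
    codes_in_response_order: tuple[int, ...]
    rank_of_code: Mapping[int, int]  # expert code -> 1-based rank, 11 if absent


@dataclass(frozen=True)
class TreatmentFlags:
    referral: bool
    advanced_imaging: bool


@dataclass(frozen=True)
class LikertResponse:
    case_id: str
    statement_id: str
    rating: Optional[int]
    polarity_token: str  # agree_like | disagree_like | neutral
    valid: bool
    exclusion_reason: str  # none | contradiction | out_of_range | unparseable


@dataclass(frozen=True)
class KeywordConfig:
    """Keywords scanned (case-insensitively, on whole tokens) per section."""

    referral: tuple[str, ...] = ("referral", "refer", "transfer")
    imaging: tuple[str, ...] = (
        "ct", "ct scan", "computed tomography", "mri",
        "magnetic resonance imaging", "ultrasound", "ultrasonography",
    )


@dataclass(frozen=True)
class ContradictionRule:
    """A response is self-contradictory when verbal polarity and numeric
    rating disagree: disagreement with rating >= ``disagree_min`` or
    agreement with rating <= ``agree_max``."""

    disagree_min: int = 4
    agree_max: int = 2


_WS = re.compile(r"\s+")


def normalize_label(label: str) -> str:
    """Case-fold, trim, collapse whitespace, strip terminal punctuation."""
    s = _WS.sub(" ", label.strip().casefold())
    return s.rstrip(".,;:!?")


def round_half_up_percent(numerator: int, denominator: int) -> float:
    """Percentage at one decimal with half-up rounding (presentation only)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def retention_percent(eligible: int, total: int) -> float:
    return round_half_up_percent(eligible, total)


def _payload_fields(payload: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    for line in payload.splitlines():
        if ":" in line:
            key, _, value = line.partition(":")
            fields[key.strip()] = value.strip()
    return fields


def screen_and_parse_case(record: ResponseRecord) -> ParsedCase:
    """Screen one case-generation response for eligibility.

    Exclusion precedence: unparseable > outside_china > missing_field.
    Exclusion is data, not failure — this function does not raise on bad
    payloads.
    """
    if record.application != "case_generation":
        raise ValueError("record is not a case_generation response")
    fields = _payload_fields(record.payload)
    if "disease" not in fields or "residence" not in fields:
        return ParsedCase(None, None, False, "unparseable")
    disease = fields["disease"]
    if fields["residence"] != "domestic":
        return ParsedCase(disease, None, False, "outside_china")
    values: dict[str, str] = {}
    for attr in ATTRIBUTES:
        value = fields.get(attr)
        if value is None or value == "":
            return ParsedCase(disease, None, False, "missing_field")
        if value not in LEVELS[attr]:
            return ParsedCase(disease, None, False, "unparseable")
        values[attr] = value
    return ParsedCase(disease, DemographicProfile(**values), True, "none")


@lru_cache(maxsize=512)
def _coding_table(
    expert_list: tuple[str, ...], synonyms: tuple[tuple[str, str], ...]
) -> dict[str, int]:
    """Normalised label -> expert code, with synonyms folded in."""
    norm_expert = [normalize_label(x) for x in expert_list]
    if len(set(norm_expert)) != len(norm_expert):
        raise ValueError("duplicate expert labels")
    table = {lbl: i + 1 for i, lbl in enumerate(norm_expert)}
    for alt, target in synonyms:
        code = table.get(normalize_label(target))
        if code is not None:
            table.setdefault(normalize_label(alt), code)
    return table


def code_diagnosis_list(
    record: ResponseRecord,
    expert_list: Sequence[str],
    synonym_map: Optional[Mapping[str, str]] = None,
) -> CodedDiagnosisList:
    """Map a ranked diagnosis response onto expert codes 1..10 (11 = absent).

    Matching is by normalised-label equality after synonym substitution.
    Only the first ten returned positions are considered; if an expert
    label appears twice, the earliest position wins.
    """
    if not 1 <= len(expert_list) <= 10:
        raise ValueError("expert list must have 1-10 entries")
    code_of_label = _coding_table(
        tuple(expert_list), tuple(sorted((synonym_map or {}).items()))
    )
    n_expert = len(expert_list)

    listed = _extract_numbered_list(record.payload)[:10]
    codes: list[int] = []
    rank_of_code: dict[int, int] = {}
    for pos, label in enumerate(listed, start=1):
        code = code_of_label.get(label) or code_of_label.get(normalize_label(label), CODE_ABSENT)
        if code != CODE_ABSENT and code in rank_of_code:
            code = CODE_ABSENT  # repeat of an already-matched expert label
        elif code != CODE_ABSENT:
            rank_of_code[code] = pos
        codes.append(code)
    for code in range(1, n_expert + 1):
        rank_of_code.setdefault(code, CODE_ABSENT)
    return CodedDiagnosisList(
        case_id=record.case_id or "",
        codes_in_response_order=tuple(codes),
        rank_of_code=rank_of_code,
    )


def _extract_numbered_list(payload: str) -> list[str]:
    labels = []
    in_list = False
    for line in payload.splitlines():
        stripped = line.strip()
        if stripped == "diagnoses:":
            in_list = True
            continue
        if in_list:
            head, _, rest = stripped.partition(".")
            if head.isdigit():
                labels.append(rest.strip())
            else:
                break
    return labels


def _section_value(payload: str, key: str) -> Optional[str]:
    prefix = key + ":"
    for line in payload.splitlines():
        if line.startswith(prefix):
            return line[len(prefix):].strip()
    return None


def _keyword_hit(text: str, keywords: Iterable[str]) -> bool:
    low = text.casefold()
    for kw in keywords:
        if re.search(rf"\b{re.escape(kw.casefold())}\b", low):
            return True
    return False


def extract_treatment_flags(
    record: ResponseRecord, keyword_config: Optional[KeywordConfig] = None
) -> TreatmentFlags:
    """Flag referral / advanced-imaging recommendations by keyword match."""
    if record.application != "diagnosis":
        raise ValueError("record is not a diagnosis response")
    cfg = keyword_config or KeywordConfig()
    diag = _section_value(record.payload, "diagnostic_steps")
    treat = _section_value(record.payload, "treatment_steps")
    if diag is None or treat is None:
        logger.warning(
            "missing diagnostic/treatment section in response for case %s; "
            "flags default to False", record.case_id,
        )
        return TreatmentFlags(referral=False, advanced_imaging=False)
    return TreatmentFlags(
        referral=_keyword_hit(treat, cfg.referral),
        advanced_imaging=_keyword_hit(diag, cfg.imaging),
    )


_STANCE_TO_POLARITY = {"agree": "agree_like", "disagree": "disagree_like", "neutral": "neutral"}


def parse_needs_ratings(
    record: ResponseRecord,
    contradiction_rule: Optional[ContradictionRule] = None,
    expected_statements: Optional[Sequence[str]] = None,
) -> list[LikertResponse]:
    """Parse one needs response into per-statement Likert records.

    Statements whose polarity token contradicts the numeric rating are
    marked invalid with reason ``contradiction``; out-of-range ratings with
    ``out_of_range``; malformed lines with ``unparseable``. Exclusion is
    data, not failure.
    """
    if record.application != "needs":
        raise ValueError("record is not a needs response")
    rule = contradiction_rule or ContradictionRule()
    case_id = record.case_id or ""
    out: list[LikertResponse] = []
    seen: set[str] = set()
    for line in record.payload.splitlines():
        m = re.match(r"^(S\d+):\s*(.*)$", line.strip())
        if not m:
            continue
        sid, body = m.group(1), m.group(2)
        seen.add(sid)
        rm = re.match(r"rating=(-?\d+);\s*stance=(\w+)$", body)
        if not rm or rm.group(2) not in _STANCE_TO_POLARITY:
            out.append(LikertResponse(case_id, sid, None, "neutral", False, "unparseable"))
            continue
        rating = int(rm.group(1))
        polarity = _STANCE_TO_POLARITY[rm.group(2)]
        if not 1 <= rating <= 5:
            out.append(LikertResponse(case_id, sid, rating, polarity, False, "out_of_range"))
            continue
        contradictory = (
            polarity == "disagree_like" and rating >= rule.disagree_min
        ) or (polarity == "agree_like" and rating <= rule.agree_max)
        if contradictory:
            out.append(LikertResponse(case_id, sid, rating, polarity, False, "contradiction"))
        else:
            out.append(LikertResponse(case_id, sid, rating, polarity, True, "none"))
    if expected_statements:
        for sid in expected_statements:
            if sid not in seen:
                out.append(LikertResponse(case_id, sid, None, "neutral", False, "unparseable"))
    return out
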