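"""End-to-end audit orchestration: plan -> responder -> parsing -> tests.

One call to :func:`run_audit` executes a full application audit against any
responder satisfying the ``(task) -> ResponseRecord`` contract, applies the
cleaning rules, computes the indicators, runs the demographic contrasts
with per-family Benjamini-Hochberg correction, and returns a report bundle
that is fully reproducible from ``(config, master_seed)``.

Test families follow the per-instrument convention: one family per
(indicator x case) or per statement, spanning the five demographic
contrasts. Referral and imaging contrasts are additionally run pooled over
cases.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import bias_indicators as bi
from . import response_parsing as rp
from . import stats as st
from .fixtures import Fixtures, default_fixtures
from .study_design import (
    ATTRIBUTES,
    LEVELS,
    DesignParams,
    StudyPlan,
    build_plan,
    enumerate_profiles,
)
from .synthetic_responder import ResponseRecord

__all__ = ["AuditConfig", "AuditReport", "run_audit", "export_report"]

logger = logging.getLogger(__name__)

Responder = Callable[..., ResponseRecord]
ResponderArg = Union[Responder, Mapping[str, Responder]]


@dataclass(frozen=True)
class AuditConfig:
    """Everything (besides the responder and seed) a run depends on."""

    fixtures: Fixtures = field(default_factory=default_fixtures)
    replicates: Optional[int] = None          # override application default
    model_tags: Optional[tuple[str, ...]] = None
    cases: Optional[tuple[str, ...]] = None   # restrict diagnosis/needs cases
    alpha: float = 0.05
    keyword_config: rp.KeywordConfig = field(default_factory=rp.KeywordConfig)
    contradiction_rule: rp.ContradictionRule = field(default_factory=rp.ContradictionRule)

    def tags(self) -> tuple[str, ...]:
        return self.model_tags if self.model_tags is not None else self.fixtures.model_tags

    def digest(self) -> str:
        """Stable cryptographic hash of the run configuration."""
        from dataclasses import asdict

        payload = {
            "fixtures": asdict(self.fixtures),
            "replicates": self.replicates,
            "model_tags": self.model_tags,
            "cases": self.cases,
            "alpha": self.alpha,
            "keywords": asdict(self.keyword_config),
            "contradiction_rule": asdict(self.contradiction_rule),
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()


@dataclass
class AuditReport:
    application: str
    master_seed: int
    config_digest: str
    responder_name: str
    task_count: int
    retention: dict
    indicators: pd.DataFrame
    tests: pd.DataFrame
    distributions: Optional[pd.DataFrame] = None
    deviations: Optional[pd.DataFrame] = None
    needs_summary: Optional[pd.DataFrame] = None
    records: list[ResponseRecord] = field(default_factory=list)

    def rejections(self, alpha: Optional[float] = None) -> pd.DataFrame:
        """Contrasts whose BH-adjusted p falls below alpha."""
        a = alpha if alpha is not None else 0.05
        return self.tests[self.tests["p_adjusted"] < a]


def _plan_for(application: str, config: AuditConfig, master_seed: int) -> StudyPlan:
    fx = config.fixtures
    tags = config.tags()
    if application == "case_generation":
        reps = config.replicates or fx.case_gen_replicates
        design = DesignParams(
            templates=fx.case_gen_templates, model_tags=tags,
            replicates=reps, diseases=fx.diseases,
        )
    elif application == "diagnosis":
        reps = config.replicates or fx.diagnosis_replicates
        templates = fx.diagnosis_templates
        if config.cases is not None:
            templates = tuple(t for t in templates if t.case_id in config.cases)
        design = DesignParams(
            templates=templates, model_tags=tags, replicates=reps,
            profiles=enumerate_profiles(),
        )
    elif application == "needs":
        reps = config.replicates or fx.needs_replicates
        templates = fx.needs_templates
        if config.cases is not None:
            templates = tuple(t for t in templates if t.case_id in config.cases)
        design = DesignParams(
            templates=templates, model_tags=tags, replicates=reps,
            profiles=enumerate_profiles(),
        )
    else:
        raise ValueError(f"unknown application {application!r}")
    return build_plan(application, design, master_seed=master_seed)


def _execute(
    plan: StudyPlan, responder: ResponderArg
) -> tuple[list[ResponseRecord], int]:
    """Run every task; responder failures are tolerated up to 50%."""
    if callable(responder):
        get = lambda tag: responder  # noqa: E731
    else:
        get = responder.__getitem__
    records: list[ResponseRecord] = []
    failures = 0
    for task in plan.tasks:
        try:
            records.append(get(task.model_tag)(task))
        except Exception:  # noqa: BLE001 - responder failure is data
            failures += 1
    if failures > 0.5 * len(plan.tasks):
        raise RuntimeError(
            f"responder failed on {failures}/{len(plan.tasks)} tasks; audit aborted"
        )
    if failures:
        logger.warning("responder failed on %d/%d tasks", failures, len(plan.tasks))
    return records, failures


def _contrast_pairs():
    return [(attr, LEVELS[attr][0], LEVELS[attr][1]) for attr in ATTRIBUTES]


# ----------------------------------------------------------------- case gen


def _audit_case_generation(
    config: AuditConfig, records: list[ResponseRecord], failures: int, total: int
) -> tuple[dict, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    fx = config.fixtures
    parsed: list[tuple[ResponseRecord, rp.ParsedCase]] = [
        (r, rp.screen_and_parse_case(r)) for r in records
    ]
    reasons = {"outside_china": 0, "missing_field": 0, "unparseable": failures}
    eligible = 0
    for _, p in parsed:
        if p.eligible:
            eligible += 1
        else:
            reasons[p.exclusion_reason] += 1
    retention = {
        "total": total,
        "eligible": eligible,
        "excluded": reasons,
        "retention_pct": rp.retention_percent(eligible, total) if total else None,
    }

    dist_rows, ind_rows, results = [], [], []
    strata = [("all", None)] + [(tag, tag) for tag in config.tags()]
    for disease in fx.diseases:
        for stratum, tag in strata:
            cases = [
                p for r, p in parsed
                if p.disease == disease and (tag is None or r.model_tag == tag)
            ]
            elig = [c for c in cases if c.eligible]
            if not elig:
                continue
            dist = bi.demographic_distribution(elig, disease)
            for attr, levels in dist.items():
                observed = {lvl: cnt for lvl, (cnt, _) in levels.items()}
                for lvl, (cnt, prop) in levels.items():
                    dist_rows.append(
                        {"disease": disease, "model_tag": stratum, "attribute": attr,
                         "level": lvl, "count": cnt, "proportion": prop}
                    )
                    ind_rows.append(
                        {"indicator": "level_proportion", "case_id": disease,
                         "target": f"{attr}={lvl}", "subgroup": stratum,
                         "value": prop, "n": len(elig)}
                    )
                reference = st.ReferenceDistribution(
                    disease=disease, attribute=attr,
                    proportions=dict(fx.reference_prevalence[disease][attr]),
                )
                res = st.chisq_gof(observed, reference)
                results.append(
                    (res, f"case_gen|{disease}|{stratum}", disease, attr, stratum)
                )
    tests = _finalize_tests(results, indicator="level_proportion")
    return retention, pd.DataFrame(ind_rows), tests, pd.DataFrame(dist_rows)


# ---------------------------------------------------------------- diagnosis


def _audit_diagnosis(
    config: AuditConfig, records: list[ResponseRecord], failures: int, total: int
) -> tuple[dict, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    fx = config.fixtures
    by_case: dict[str, dict] = {}
    for r in records:
        coded = rp.code_diagnosis_list(
            r, fx.vignette(r.case_id).expert_list, fx.synonym_map
        )
        flags = rp.extract_treatment_flags(r, config.keyword_config)
        slot = by_case.setdefault(
            r.case_id, {"coded": [], "flags": [], "profiles": []}
        )
        slot["coded"].append(coded)
        slot["flags"].append(flags)
        slot["profiles"].append(r.profile)

    retention = {
        "total": total,
        "eligible": total - failures,
        "excluded": {"unparseable": failures},
        "retention_pct": rp.retention_percent(total - failures, total) if total else None,
    }

    ind_rows, results, dev_frames = [], [], []
    pooled = {"referral": {}, "imaging": {}}  # attr -> level -> [hit, miss]
    for case_id, slot in sorted(by_case.items()):
        expert = fx.vignette(case_id).expert_list
        coded_profiles = list(zip(slot["coded"], slot["profiles"]))
        flag_profiles = list(zip(slot["flags"], slot["profiles"]))
        n_codes = len(expert)

        subgroups = [("all", None)] + [
            (f"{a}={lvl}", (a, lvl)) for a in ATTRIBUTES for lvl in LEVELS[a]
        ]
        for name, flt in subgroups:
            try:
                mean_rank, top3, n = bi.primary_rank_stats(coded_profiles, flt)
                ref_rate, img_rate, n2 = bi.treatment_rates(flag_profiles, flt)
            except bi.InsufficientDataError:
                continue
            ind_rows += [
                {"indicator": "mean_rank_primary", "case_id": case_id, "target": "1",
                 "subgroup": name, "value": mean_rank, "n": n},
                {"indicator": "top3_inclusion", "case_id": case_id, "target": "1",
                 "subgroup": name, "value": top3, "n": n},
                {"indicator": "referral_rate", "case_id": case_id, "target": None,
                 "subgroup": name, "value": ref_rate, "n": n2},
                {"indicator": "imaging_rate", "case_id": case_id, "target": None,
                 "subgroup": name, "value": img_rate, "n": n2},
            ]
            if flt is None:
                profile = bi.expert_list_rank_profile(coded_profiles, expert, None)
                for code, (mean, nn) in profile.items():
                    ind_rows.append(
                        {"indicator": "mean_rank_dx", "case_id": case_id,
                         "target": str(code), "subgroup": name, "value": mean, "n": nn}
                    )

        for attr in ATTRIBUTES:
            try:
                dev_frames.append(
                    bi.subgroup_rank_deviation(coded_profiles, attr, n_codes, case_id)
                )
            except bi.InsufficientDataError:
                logger.warning("case %s: single level for %s; skipped", case_id, attr)

        # contrasts
        ranks = np.array(
            [[c.rank_of_code[k] for k in range(1, n_codes + 1)] for c in slot["coded"]],
            dtype=np.int8,
        )
        referral = np.array([f.referral for f in slot["flags"]], dtype=bool)
        imaging = np.array([f.advanced_imaging for f in slot["flags"]], dtype=bool)
        level_masks = {
            a: np.array([p.level(a) == LEVELS[a][0] for p in slot["profiles"]])
            for a in ATTRIBUTES
        }
        for attr, lv0, lv1 in _contrast_pairs():
            m = level_masks[attr]
            if m.all() or not m.any():
                continue
            contrast = f"{lv0}_vs_{lv1}"
            r1 = ranks[m, 0]
            r2 = ranks[~m, 0]
            results.append(
                (st.mann_whitney(r1, r2), f"mean_rank_primary|{case_id}",
                 case_id, f"{attr}:{contrast}", "mean_rank_primary")
            )
            top3_tab = [
                [int((r1 <= 3).sum()), int((r1 > 3).sum())],
                [int((r2 <= 3).sum()), int((r2 > 3).sum())],
            ]
            results.append(
                (st.assoc_test_2x2(top3_tab), f"top3_inclusion|{case_id}",
                 case_id, f"{attr}:{contrast}", "top3_inclusion")
            )
            for flag, kind in ((referral, "referral_rate"), (imaging, "imaging_rate")):
                tab = [
                    [int(flag[m].sum()), int((~flag[m]).sum())],
                    [int(flag[~m].sum()), int((~flag[~m]).sum())],
                ]
                results.append(
                    (st.assoc_test_2x2(tab), f"{kind}|{case_id}",
                     case_id, f"{attr}:{contrast}", kind)
                )
                acc = pooled[kind.split("_")[0]].setdefault(
                    attr, {lv0: [0, 0], lv1: [0, 0]}
                )
                acc[lv0][0] += tab[0][0]
                acc[lv0][1] += tab[0][1]
                acc[lv1][0] += tab[1][0]
                acc[lv1][1] += tab[1][1]
            for code in range(1, n_codes + 1):
                results.append(
                    (st.mann_whitney(ranks[m, code - 1], ranks[~m, code - 1]),
                     f"mean_rank_dx|{case_id}|{code}",
                     case_id, f"{attr}:{contrast}|code={code}", "mean_rank_dx")
                )

    for kind, by_attr in pooled.items():
        for attr, levels in by_attr.items():
            (lv0, c0), (lv1, c1) = levels.items()
            results.append(
                (st.assoc_test_2x2([c0, c1]), f"{kind}_rate|pooled",
                 "pooled", f"{attr}:{lv0}_vs_{lv1}", f"{kind}_rate_pooled")
            )

    tests = _finalize_tests(results)
    deviations = (
        pd.concat(dev_frames, ignore_index=True) if dev_frames else pd.DataFrame()
    )
    return retention, pd.DataFrame(ind_rows), tests, deviations


# -------------------------------------------------------------------- needs


def _audit_needs(
    config: AuditConfig, records: list[ResponseRecord], failures: int, total_tasks: int
) -> tuple[dict, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    fx = config.fixtures
    statement_case = {s.statement_id: c.case_id for c in fx.needs_cases for s in c.statements}
    statement_domain = {s.statement_id: s.domain for c in fx.needs_cases for s in c.statements}
    per_statement: dict[str, dict] = {
        sid: {"ratings": [], "profiles": []} for sid in statement_case
    }
    reasons = {"contradiction": 0, "out_of_range": 0, "unparseable": 0}
    valid = 0
    total_statements = 0
    for r in records:
        expected = tuple(
            s.statement_id for s in fx.needs_case(r.case_id).statements
        )
        for resp in rp.parse_needs_ratings(r, config.contradiction_rule, expected):
            total_statements += 1
            if resp.valid:
                valid += 1
                slot = per_statement[resp.statement_id]
                slot["ratings"].append(resp.rating)
                slot["profiles"].append(r.profile)
            else:
                reasons[resp.exclusion_reason] += 1
    # responder-failed tasks contribute their statements to the denominator
    if failures and total_tasks:
        per_task = total_statements / max(len(records), 1)
        extra = int(round(per_task * failures))
        total_statements += extra
        reasons["unparseable"] += extra

    retention = {
        "total": total_statements,
        "eligible": valid,
        "excluded": reasons,
        "retention_pct": (
            rp.retention_percent(valid, total_statements) if total_statements else None
        ),
    }

    summary_rows, results = [], []
    for sid in sorted(per_statement):
        slot = per_statement[sid]
        ratings = np.asarray(slot["ratings"], dtype=float)
        if ratings.size == 0:
            continue
        case_id = statement_case[sid]
        summary_rows.append(
            {"statement_id": sid, "case_id": case_id,
             "domain": statement_domain[sid], "subgroup": "all",
             "mean": float(ratings.mean()), "sd": float(ratings.std(ddof=1)) if ratings.size > 1 else 0.0,
             "n": int(ratings.size)}
        )
        level_masks = {
            a: np.array([p.level(a) == LEVELS[a][0] for p in slot["profiles"]])
            for a in ATTRIBUTES
        }
        for attr, lv0, lv1 in _contrast_pairs():
            m = level_masks[attr]
            for lvl, mask in ((lv0, m), (lv1, ~m)):
                if mask.any():
                    sub = ratings[mask]
                    summary_rows.append(
                        {"statement_id": sid, "case_id": case_id,
                         "domain": statement_domain[sid], "subgroup": f"{attr}={lvl}",
                         "mean": float(sub.mean()),
                         "sd": float(sub.std(ddof=1)) if sub.size > 1 else 0.0,
                         "n": int(sub.size)}
                    )
            if m.all() or not m.any():
                continue
            results.append(
                (st.mann_whitney(ratings[m], ratings[~m]), f"needs|{sid}",
                 case_id, f"{attr}:{lv0}_vs_{lv1}|{sid}", "likert_rating")
            )
    tests = _finalize_tests(results)
    return retention, pd.DataFrame(), tests, pd.DataFrame(summary_rows)


def _finalize_tests(
    results: list[tuple[st.TestResult, str, str, str, str]],
    indicator: Optional[str] = None,
) -> pd.DataFrame:
    """Apply BH within families and flatten to the export table."""
    tagged = [
        st.TestResult(
            test=r.test, statistic=r.statistic, p_raw=r.p_raw, df=r.df,
            family_id=family, label=label, n=r.n,
        )
        for r, family, _, label, _ in results
    ]
    adjusted = st.bh_adjust(tagged)
    rows = []
    for (orig, family, case_id, label, kind), r in zip(results, adjusted):
        rows.append(
            {"family_id": family, "case_id": case_id,
             "indicator": indicator or kind, "contrast": label, "test": r.test,
             "statistic": r.statistic, "df": r.df, "n": r.n,
             "p_raw": r.p_raw, "p_adjusted": r.p_adjusted,
             "significant_05": r.significant_05, "significant_001": r.significant_001}
        )
    columns = ["family_id", "case_id", "indicator", "contrast", "test", "statistic",
               "df", "n", "p_raw", "p_adjusted", "significant_05", "significant_001"]
    return pd.DataFrame(rows, columns=columns)


def run_audit(
    application: str,
    config: AuditConfig,
    responder: ResponderArg,
    master_seed: int,
    keep_records: bool = False,
) -> AuditReport:
    """Execute a complete audit for one application.

    ``responder`` is either a single callable used for every model tag or a
    mapping from model tag to callable. The returned report is a pure
    function of ``(config, responder config, master_seed)``.
    """
    plan = _plan_for(application, config, master_seed)
    records, failures = _execute(plan, responder)
    total = len(plan.tasks)
    distributions = deviations = needs_summary = None
    if application == "case_generation":
        retention, indicators, tests, distributions = _audit_case_generation(
            config, records, failures, total
        )
    elif application == "diagnosis":
        retention, indicators, tests, deviations = _audit_diagnosis(
            config, records, failures, total
        )
    else:
        retention, indicators, tests, needs_summary = _audit_needs(
            config, records, failures, total
        )
    name = getattr(responder, "name", None) or (
        "mapping" if isinstance(responder, Mapping) else getattr(
            type(responder), "__name__", "responder"
        )
    )
    return AuditReport(
        application=application,
        master_seed=master_seed,
        config_digest=config.digest(),
        responder_name=str(name),
        task_count=total,
        retention=retention,
        indicators=indicators,
        tests=tests,
        distributions=distributions,
        deviations=deviations,
        needs_summary=needs_summary,
        records=records if keep_records else [],
    )


def export_report(report: AuditReport, out_dir: Union[str, Path]) -> dict[str, int]:
    """Write the report bundle; returns a manifest of file -> row count.

    Re-exporting the same report yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}

    def write_csv(name: str, df: Optional[pd.DataFrame], columns: list[str]) -> None:
        frame = df if df is not None and not df.empty else pd.DataFrame(columns=columns)
        frame.to_csv(out / name, index=False, float_format="%.10g")
        manifest[name] = len(frame)

    write_csv("indicators.csv", report.indicators,
              ["indicator", "case_id", "target", "subgroup", "value", "n"])
    write_csv("tests.csv", report.tests,
              ["family_id", "case_id", "indicator", "contrast", "test", "statistic",
               "df", "n", "p_raw", "p_adjusted", "significant_05", "significant_001"])
    if report.application == "case_generation":
        write_csv("distributions.csv", report.distributions,
                  ["disease", "model_tag", "attribute", "level", "count", "proportion"])
    if report.application == "diagnosis":
        write_csv("deviations.csv", report.deviations,
                  ["case_id", "code", "attribute", "level", "deviation", "n"])
    if report.application == "needs":
        write_csv("needs_summary.csv", report.needs_summary,
                  ["statement_id", "case_id", "domain", "subgroup", "mean", "sd", "n"])
    if report.records:
        path = out / "responses.jsonl"
        with path.open("w") as fh:
            for r in report.records:
                fh.write(r.to_json() + "\n")
        manifest["responses.jsonl"] = len(report.records)
    metadata = {
        "application": report.application,
        "master_seed": report.master_seed,
        "config_digest": report.config_digest,
        "responder": report.responder_name,
        "task_count": report.task_count,
        "retention": report.retention,
    }
    (out / "metadata.json").write_text(json.dumps(metadata, indent=2, sort_keys=True))
    manifest["metadata.json"] = 1
    return manifest
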