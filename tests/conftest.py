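from __future__ import annotations

import pytest

from clinaudit.fixtures import default_fixtures
from clinaudit.study_design import DemographicProfile, Task, derive_seed
from clinaudit.synthetic_responder import make_null_config


@pytest.fixture(scope="session")
def fx():
    return default_fixtures()


@pytest.fixture(scope="session")
def null_config(fx):
    return make_null_config("llm-a", fx)


def make_task(
    application: str,
    *,
    case_id: str | None = None,
    disease: str | None = None,
    profile: DemographicProfile | None = None,
    replicate: int = 1,
    model_tag: str = "llm-a",
    master_seed: int = 0,
) -> Task:
    """Construct a single task with its properly derived seed."""
    template_id = {
        "case_generation": "cg-v01",
        "diagnosis": f"dx-{case_id}",
        "needs": f"needs-{case_id}",
    }[application]
    seed = derive_seed(
        master_seed, application, case_id or disease, template_id,
        profile, replicate, model_tag,
    )
    return Task(
        application=application, template_id=template_id, case_id=case_id,
        disease=disease, profile=profile, replicate_index=replicate,
        model_tag=model_tag, derived_seed=seed,
    )
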