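import pytest

from dqaudit.checks import DefectItem, DefectProfile, Finding, run_checklist
from dqaudit.model import Capture, EntryMode, Phase, StudyMeta
from dqaudit.synth import (
    GeneratorConfig,
    PAPER_POST_SPEC,
    PAPER_PRE_SPEC,
    build_fixture,
    generate_clean,
)

META = StudyMeta(
    capture=Capture.SINGLE,
    coordinator_on_board=False,
    returning_pi=False,
    phase=Phase.PRE,
    entry_mode=EntryMode.MANUAL,
)


def make_profile(items, submission_id="p", meta=META):
    """A DefectProfile with one finding per requested item."""
    items = [DefectItem(i) if not isinstance(i, DefectItem) else i for i in items]
    findings = [Finding(item=i) for i in items]
    return DefectProfile.from_findings(submission_id, findings, meta)


@pytest.fixture
def clean_submission():
    return generate_clean(GeneratorConfig(seed=7))


@pytest.fixture
def clean_multi_submission():
    return generate_clean(GeneratorConfig(seed=7, capture=Capture.MULTI))


@pytest.fixture(scope="session")
def pre_fixture():
    """Baseline collection: 45 submissions, 105 defects, with truth labels."""
    return build_fixture(PAPER_PRE_SPEC, seed=11)


@pytest.fixture(scope="session")
def post_fixture():
    """Follow-up collection: 21 submissions, 12 defects, with truth labels."""
    return build_fixture(PAPER_POST_SPEC, seed=12)


@pytest.fixture(scope="session")
def pre_profiles(pre_fixture):
    return [run_checklist(sub) for sub, _ in pre_fixture]


@pytest.fixture(scope="session")
def post_profiles(post_fixture):
    return [run_checklist(sub) for sub, _ in post_fixture]
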