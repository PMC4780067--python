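import pytest

from casevar import CaseConfig, generate_case, run_pipeline


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic case: 7 somatic + 205 germline + 50 decoys."""
    return generate_case(CaseConfig())


@pytest.fixture(scope="session")
def default_result(default_bundle):
    return run_pipeline(default_bundle)


@pytest.fixture(scope="session")
def truth_by_key(default_bundle):
    return {t.variant_key: t for t in default_bundle.truth}
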