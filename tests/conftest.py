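import pytest

from cnegrn.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study bundle, shared across the session."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    """The same bundle written out in standard formats."""
    out = tmp_path_factory.mktemp("bundle")
    bundle.write(out)
    return out
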