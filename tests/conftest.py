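import logging

import pytest

from snplink.cascade import run_cascade
from snplink.fixtures import FixtureSpec, generate, load_bundle

logging.getLogger("snplink").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One standard synthetic bundle (seed 11), generated once per session."""
    directory = tmp_path_factory.mktemp("bundle")
    return generate(FixtureSpec(seed=11), directory)


@pytest.fixture(scope="session")
def bundle_data(bundle):
    return load_bundle(bundle.directory)


@pytest.fixture(scope="session")
def cascade_results(bundle_data):
    return run_cascade(
        bundle_data["variants"],
        bundle_data["collapsed_peaks"],
        bundle_data["interactions"],
        bundle_data["regulatory"],
        bundle_data["tf_peaks"],
        genes=bundle_data["genes"],
    )
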