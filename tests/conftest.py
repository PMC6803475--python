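"""Shared fixtures: the study-condition runs, computed once per session."""

import pytest

import hhsync as hs


@pytest.fixture(scope="session")
def default_cfg():
    """Resolved bundled default configuration (the study conditions)."""
    return hs.validate_config({})


@pytest.fixture(scope="session")
def default_run():
    """Full closed-loop run of the funnel controller under the defaults."""
    return hs.run({})


@pytest.fixture(scope="session")
def uncontrolled_run():
    """Open-loop run (no feedback input); 3 time units suffice to show the
    two neurons drifting apart."""
    return hs.run({"controller": {"type": "none"}, "sim": {"duration": 3.0}})


@pytest.fixture(scope="session")
def observer_run():
    """Observer-baseline run over the default horizon."""
    return hs.run({"controller": {"type": "observer"}})


@pytest.fixture(scope="session")
def mec_run():
    """Modelling-error-compensation baseline run over the default horizon."""
    return hs.run({"controller": {"type": "mec"}})
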