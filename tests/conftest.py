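"""Shared fixtures: the hawkmoth-like defaults and cached baseline runs."""

import pytest

import flapsim as fs


@pytest.fixture(scope="session")
def default_cfg():
    cfg, _ = fs.default_config()
    return cfg


@pytest.fixture(scope="session")
def geometry(default_cfg):
    return default_cfg.wing


@pytest.fixture(scope="session")
def baseline_fws(default_cfg):
    """50-wingbeat flexible-wing run at the default parameters."""
    return fs.integrate(default_cfg)


@pytest.fixture(scope="session")
def baseline_rws(default_cfg):
    """50-wingbeat rigid-wing run at the default parameters."""
    return fs.integrate(default_cfg.rigid())


@pytest.fixture(scope="session")
def metrics_fws(baseline_fws):
    return fs.summarize(baseline_fws)


@pytest.fixture(scope="session")
def metrics_rws(baseline_rws):
    return fs.summarize(baseline_rws)
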