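"""Shared fixtures: small synthetic geometries and default parameters."""

import numpy as np
import pytest

import vasrem as vr
from vasrem.dynamics import make_synthetic_timelapse


@pytest.fixture(scope="session")
def channel_spec():
    return vr.GeometrySpec(template="channel", width=50.0, length=300.0,
                           inlet_speed=500.0, viscosity=0.003)


@pytest.fixture(scope="session")
def channel_mask(channel_spec):
    return vr.make_vessel_mask(channel_spec, pixel_size=1.0)


@pytest.fixture(scope="session")
def channel_fields(channel_spec, channel_mask):
    return vr.analytic_flow(channel_mask, channel_spec)


@pytest.fixture(scope="session")
def honeycomb_spec():
    # small plexus: ~14 avascular islands, ~1800 agents, tractable at 4 h
    return vr.GeometrySpec(template="honeycomb", width=25.0, length=300.0,
                           height=260.0, pitch=100.0, inlet_speed=500.0)


@pytest.fixture(scope="session")
def honeycomb_mask(honeycomb_spec):
    return vr.make_vessel_mask(honeycomb_spec, pixel_size=1.0)


@pytest.fixture(scope="session")
def honeycomb_fields(honeycomb_spec, honeycomb_mask):
    return vr.analytic_flow(honeycomb_mask, honeycomb_spec)


@pytest.fixture(scope="session")
def honeycomb_truth(honeycomb_mask, honeycomb_fields):
    """A 4-h ground-truth time-lapse simulated with the default parameters."""
    return make_synthetic_timelapse(honeycomb_mask, honeycomb_fields,
                                    vr.ModelParams(), duration=4.0, seed=1000)


@pytest.fixture
def params():
    return vr.ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
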