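"""Shared fixtures: small ground-truthed synthetic sessions."""

from __future__ import annotations

import numpy as np
import pytest

from slopecell.geometry import Condition, DOWNHILL, UPHILL
from slopecell.pipeline import analyze_session
from slopecell.synthetic import (PrecessionSpec, ScenarioConfig, Tuning,
                                 UnitSpec, generate_session)


def handcrafted_units() -> list[UnitSpec]:
    """A small, fixed ensemble covering every programmed remap type."""
    c = lambda t, d: Condition(t, d)
    g = lambda x, p=15.0: Tuning(x, 6.0, p)
    prec = PrecessionSpec(phi0_deg=200.0, slope_deg_per_field=-360.0, kappa=4.0)
    return [
        # stable, uphill, with precession
        UnitSpec("stable_up", {c(0, UPHILL): g(40), c(15, UPHILL): g(40),
                               c(25, UPHILL): g(40)}, 0.3, prec),
        # stable, downhill
        UnitSpec("stable_down", {c(0, DOWNHILL): g(70), c(15, DOWNHILL): g(70),
                                 c(25, DOWNHILL): g(70)}, 0.3),
        # rate remap x2 from 0 to tilted, uphill
        UnitSpec("rate_up", {c(0, UPHILL): g(55), c(15, UPHILL): g(55, 30.0),
                             c(25, UPHILL): g(55, 30.0)}, 0.3),
        # field remap +30 cm, downhill
        UnitSpec("field_down", {c(0, DOWNHILL): g(35), c(15, DOWNHILL): g(65),
                                c(25, DOWNHILL): g(65)}, 0.3),
        # turns on with tilt, uphill
        UnitSpec("on_up", {c(15, UPHILL): g(80), c(25, UPHILL): g(80)}, 0.3),
        # turns off with tilt, downhill
        UnitSpec("off_down", {c(0, DOWNHILL): g(50)}, 0.3),
        # silent unit
        UnitSpec("silent", {}, 0.0),
    ]


@pytest.fixture(scope="session")
def mixed_session():
    session, truth = generate_session(ScenarioConfig(), handcrafted_units(), seed=42)
    return session, truth


@pytest.fixture(scope="session")
def mixed_results(mixed_session):
    session, _ = mixed_session
    return analyze_session(session, n_shuffles=200, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
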