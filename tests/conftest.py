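"""Shared fixtures: the synthetic reference bundle and small toy systems."""

from __future__ import annotations

import numpy as np
import pytest

import slmdesign as sd
from slmdesign.profiles import ExpressionProfile, TfProfile

BUNDLE_SEED = 0


@pytest.fixture(scope="session")
def bundle() -> sd.SyntheticBundle:
    return sd.build_reference_bundle(BUNDLE_SEED)


@pytest.fixture(scope="session")
def catalogue(bundle):
    return bundle.catalogue


@pytest.fixture(scope="session")
def background():
    return sd.Background()


@pytest.fixture(scope="session")
def parameter_sets():
    return sd.load_all_parameter_sets()


@pytest.fixture(scope="session")
def toy_grid():
    return np.linspace(35.5, 54.5, 20)


@pytest.fixture(scope="session")
def toy_system(toy_grid):
    """A minimal one-activator system for fast design/path tests: one 6 bp
    activator PWM, an anterior gradient, a small parameter set."""
    cat = sd.make_pwm_catalogue(["bcd"])
    atlas = (TfProfile("bcd", toy_grid, 100.0 * np.exp(-(toy_grid - 35.5) / 12.0)),)
    ps = sd.load_parameter_set(id=1)
    # restrict the set to the single factor present in the toy catalogue
    from dataclasses import replace

    ps = replace(ps, factors={"bcd": ps.factors["bcd"]})
    return cat, atlas, ps
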