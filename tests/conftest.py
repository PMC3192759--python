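"""Shared fixtures: phantom templates and small cohorts, built once."""

import numpy as np
import pytest

from admri.phantom import EffectSpec, make_template, sample_subject
from admri.segment_hippo import AtlasEntry


@pytest.fixture(scope="session")
def template48():
    """48^3 template with 84 parcels (the full-size stated world)."""
    return make_template((48, 48, 48), n_parcels=84, seed=7)


@pytest.fixture(scope="session")
def template32():
    """Small, fast template for registration/segmentation unit tests."""
    return make_template((32, 32, 32), n_parcels=12, seed=3)


@pytest.fixture(scope="session")
def atlas_pool32(template32):
    """Mixed-group atlas pool on the small template."""
    tpl, lm = template32
    eff = EffectSpec()
    pool = []
    for i, grp in enumerate(["HC", "S-MCI", "P-MCI", "AD", "HC", "AD"]):
        s = sample_subject(tpl, lm, grp, 75.0, "F", eff, seed=300 + i,
                           subject_id=f"{grp}_atlas{i}")
        pool.append(AtlasEntry(s.image, s.labels, s.id))
    return pool


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
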