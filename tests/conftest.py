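"""Shared fixtures: small, fast synthetic smears.

Unit tests run on down-scaled smears (cell radii and image size shrunk by
the same factor, so the auto-scaled area cutoffs stay consistent); the
acceptance tests use the full-size presets.
"""

from __future__ import annotations

import numpy as np
import pytest

from wbcseg.synthetic import SmearSpec, generate


TINY_KW = dict(shape=(342, 428), wbc_radius_px=(14.5, 1.0),
               rbc_radius_px=(10.0, 1.5))


def tiny_spec(**overrides) -> SmearSpec:
    kw = dict(TINY_KW)
    kw.update(overrides)
    return SmearSpec(**kw)


@pytest.fixture(scope="session")
def tiny_smear():
    """One small smear with 5 disjoint leukocytes and its ground truth."""
    img, truth, n = generate(tiny_spec(n_wbc=5, seed=11))
    return img, truth, n


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
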