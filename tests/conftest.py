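import math

import pytest
from hypothesis import HealthCheck, settings

from idrmem import (
    DISORDERED_PARAMS,
    HELIX_PARAMS,
    ResidueClass,
    distance_factor,
)

settings.register_profile(
    "ci",
    database=None,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def disordered():
    return DISORDERED_PARAMS


@pytest.fixture
def helix():
    return HELIX_PARAMS


def naive_weight(n: int, classes, params) -> float:
    """Direct-product oracle for the statistical weight (no log space).

    Multiplies the contributing factor of every residue plus any terminal
    pseudo-sites, exactly as the model definition states.
    """
    w = 1.0
    for i, cls in enumerate(classes.classes, start=1):
        w *= distance_factor(cls, abs(i - n), params)
    if classes.n_term_site:
        w *= distance_factor(ResidueClass.POSITIVE, abs(1 - n), params)
    if classes.c_term_site:
        w *= distance_factor(ResidueClass.NEGATIVE, abs(len(classes) - n), params)
    assert math.isfinite(w)
    return w
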