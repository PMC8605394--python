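"""Shared fixtures: toy models and solved communities.

Heavy objects (conditioned communities and their solutions) are
session-scoped; tests that mutate models work on copies.
"""

import warnings

import pytest

from camp import (
    NutrientCondition,
    apply_community_condition,
    build_pair_community,
    self_pair,
    solve_steadycom,
)
from camp.synthetic import (
    FIXTURE_MEDIUM,
    crossfeed_auxotroph,
    crossfeed_donor,
    heterofermenter,
    homofermenter,
)

warnings.filterwarnings("ignore", message=".*zero substrate uptake.*")


@pytest.fixture(scope="session")
def minimal():
    return NutrientCondition.minimal()


@pytest.fixture()
def homo():
    return homofermenter()


@pytest.fixture()
def hetero():
    return heterofermenter()


def _conditioned_pair(model_a, model_b, condition):
    cm = build_pair_community(model_a, model_b,
                              product_exchange="EX_lac_D(e)")
    apply_community_condition(cm, condition, FIXTURE_MEDIUM)
    return cm


@pytest.fixture(scope="session")
def hetero_homo_community(minimal):
    """Heterofermenter + homofermenter under the minimal condition."""
    return _conditioned_pair(heterofermenter(), homofermenter(), minimal)


@pytest.fixture(scope="session")
def hetero_homo_solution(hetero_homo_community):
    return solve_steadycom(hetero_homo_community)


@pytest.fixture(scope="session")
def homo_self_community(minimal):
    cm = self_pair(homofermenter(), product_exchange="EX_lac_D(e)")
    apply_community_condition(cm, minimal, FIXTURE_MEDIUM)
    return cm


@pytest.fixture(scope="session")
def donor_auxotroph_community():
    """Obligate acetate cross-feeding pair: donor secretes 2 acetate per
    glucose, the auxotroph grows on acetate only.  Glucose at -1.5 puts
    the forced acetate exchange (3 mmol/gDW/h) above the reporting
    threshold."""
    condition = NutrientCondition(
        "crossfeed_demo", {"EX_glc_D(e)": -1.5, "EX_xyl_D(e)": 0.0})
    cm = build_pair_community(
        crossfeed_donor(), crossfeed_auxotroph(),
        product_exchange="EX_lac_D(e)")
    apply_community_condition(cm, condition, FIXTURE_MEDIUM)
    return cm
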