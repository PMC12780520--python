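"""Shared fixtures: toy growth reference, small synthetic populations, and an
independent predicate-table classifier used as the oracle for the taxonomy."""

from __future__ import annotations

import pytest

from cfmkit.synthetic import default_global_config, generate_population, generate_reference_fixture

# ---------------------------------------------------------------------------
# Independent brute-force classifier oracle
# ---------------------------------------------------------------------------
# Every reachable truth pattern of the five threshold predicates
# (stunted, wasted, underweight, waz>=+2, whz>=+2) is listed explicitly with
# its category and conflict flag.  Patterns combining waz<=-2 with waz>=+2
# (or whz<=-2 with whz>=+2) cannot occur.  This table was written out by hand
# from the taxonomy definitions and is deliberately a lookup, not logic.

PREDICATE_TABLE = {
    # (S, W, U, Ow, Oh): (category, conflict_flag)
    (0, 0, 0, 0, 0): ("normal", "none"),
    (0, 0, 1, 0, 0): ("underweight", "none"),
    (0, 0, 0, 1, 0): ("overweight_obese", "none"),
    (0, 1, 0, 0, 0): ("wasting", "none"),
    (0, 1, 1, 0, 0): ("CUW", "none"),
    (0, 1, 0, 1, 0): ("wasting", "multiple_standalone"),
    (0, 0, 0, 0, 1): ("overweight_obese", "none"),
    (0, 0, 1, 0, 1): ("underweight", "underweight_with_overfeeding_pattern"),
    (0, 0, 0, 1, 1): ("overweight_obese", "none"),
    (1, 0, 0, 0, 0): ("stunting", "none"),
    (1, 0, 1, 0, 0): ("CUS", "none"),
    (1, 0, 0, 1, 0): ("CSO", "none"),
    (1, 1, 0, 0, 0): ("stunting", "stunted_wasted_not_underweight"),
    (1, 1, 1, 0, 0): ("CUWS", "none"),
    (1, 1, 0, 1, 0): ("CSO", "multiple_standalone"),
    (1, 0, 0, 0, 1): ("CSO", "none"),
    (1, 0, 1, 0, 1): ("CUS", "underweight_with_overfeeding_pattern"),
    (1, 0, 0, 1, 1): ("CSO", "none"),
}

CFM_SET = {"CUW", "CUS", "CUWS", "CSO"}


def brute_force_classify(haz: float, waz: float, whz: float):
    """Oracle classification via the hand-written predicate lookup table."""
    key = (
        int(haz <= -2.0),
        int(whz <= -2.0),
        int(waz <= -2.0),
        int(waz >= 2.0),
        int(whz >= 2.0),
    )
    category, flag = PREDICATE_TABLE[key]
    return {
        "category": category,
        "conflict_flag": flag,
        "cfm": category in CFM_SET,
        "sfm": category != "normal" and category not in CFM_SET,
        "malnourished": category != "normal",
    }


@pytest.fixture(scope="session")
def toy_refs():
    return generate_reference_fixture(seed=0)


@pytest.fixture(scope="session")
def small_population():
    """~3,000-child z-score-mode population with planted covariate effects."""
    config = default_global_config(seed=11, clusters_per_country=20)
    return generate_population(config)


@pytest.fixture(scope="session")
def measurement_population():
    """Raw-measurement-mode population for end-to-end pipeline tests."""
    config = default_global_config(seed=17, clusters_per_country=8, emit="measurements")
    return generate_population(config)
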