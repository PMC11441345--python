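"""Shared fixtures: catalogs and seeded synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import symptomnet as sn

#: The three most prevalent community profiles: all symptoms; all but
#: suicidal ideation (item 9); all but psychomotor change and suicidal
#: ideation (items 8-9).
HEADLINE_PATTERNS = ("111111111", "111111110", "111111100")


def headline_spec(n_respondents: int, seed: int) -> sn.SyntheticSpec:
    """Three-subpopulation cohort planted on the headline profiles with
    sparse random ground-truth networks (weights 0.2-0.35)."""
    rng = np.random.default_rng(7)
    subs = []
    for pattern, weight in zip(HEADLINE_PATTERNS, (0.5, 0.3, 0.2)):
        profile = sn.SymptomProfile.from_pattern(pattern)
        m = profile.n_present
        net = sn.random_network(m, m - 1, (0.2, 0.35), rng)
        subs.append(sn.Subpopulation(profile, weight, net))
    return sn.SyntheticSpec(
        n_respondents=n_respondents, subpopulations=tuple(subs), seed=seed
    )


@pytest.fixture(scope="session")
def phq_rule() -> sn.ProfileRule:
    return sn.ProfileRule()


@pytest.fixture(scope="session")
def phq_catalog(phq_rule) -> sn.ProfileCatalog:
    return sn.enumerate_catalog(phq_rule)


@pytest.fixture(scope="session")
def three_profile_cohort(phq_catalog) -> sn.ResponseMatrix:
    """Matched cohort of 1,200 respondents planted on the headline
    profiles with mixture weights 0.5 / 0.3 / 0.2 (seed 42)."""
    rm = sn.sample_cohort(headline_spec(1200, seed=42))
    return sn.match_profiles(rm, phq_catalog)


@pytest.fixture()
def planted_scores() -> pd.DataFrame:
    """2,000 x 9 ordinal scores from a single all-present subpopulation
    with 8 planted edges of weight 0.25-0.35 (seed 11)."""
    rng = np.random.default_rng(11)
    net = sn.random_network(9, 8, (0.25, 0.35), rng)
    spec = sn.SyntheticSpec(
        n_respondents=2000,
        subpopulations=(
            sn.Subpopulation(sn.SymptomProfile.from_pattern("111111111"), 1.0, net),
        ),
        seed=11,
    )
    rm = sn.sample_cohort(spec)
    return pd.DataFrame(rm.scores, columns=rm.item_labels)
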