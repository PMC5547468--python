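"""Shared fixtures.

The ``study`` fixture is the reference power experiment reused across the
attack, model-agreement and privacy-utility tests: a 100,000-SNP neutral
panel for a population of 20,000 diploids, a beacon of 1,000 members, and
cohorts of 100 in-beacon and 100 out-of-beacon targets attacked at
budgets up to 10,000 queries with mismatch rate 1e-3. Only the genotypes
the experiment touches (members + controls) are materialised; genotypes
are independent given the frequencies, so this is distributionally
identical to drawing the full population.
"""

from dataclasses import dataclass, field

import numpy as np
import pytest
from hypothesis import settings

import beaconrisk as br

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

BUDGETS = [0, 500, 1000, 2500, 5000, 10000]


@dataclass
class Study:
    panel: br.SNPPanel
    genotypes: br.GenotypeMatrix
    db: br.BeaconDB
    cases: np.ndarray
    controls: np.ndarray
    profile: br.RiskProfile
    budgets: list
    outcomes: list = field(default_factory=list)

    def outcome_at(self, budget: int) -> br.AttackOutcome:
        return next(o for o in self.outcomes if o.budget == budget)


@pytest.fixture(scope="session")
def study() -> Study:
    panel = br.sample_neutral_frequencies(100_000, 20_000, seed=1729)
    genotypes = br.sample_genotypes(panel, 1_100, seed=1730)
    members = np.arange(1_000)
    db = br.build_beacon(genotypes, members)
    cases = np.arange(100)
    controls = np.arange(1_000, 1_100)
    profile = br.profile_from_panel(panel, 1_000, delta=1e-3, alpha=0.05)
    outcomes = br.run_attack_cohort(
        db, panel, genotypes, cases, controls, BUDGETS,
        profile=profile, delta=1e-3, seed=1731,
    )
    return Study(
        panel=panel, genotypes=genotypes, db=db, cases=cases,
        controls=controls, profile=profile, budgets=BUDGETS, outcomes=outcomes,
    )


@pytest.fixture(scope="session")
def small_sim():
    """A quick 20k-SNP simulation for unit-level end-to-end checks."""
    panel = br.sample_neutral_frequencies(20_000, 20_000, seed=41)
    genotypes = br.sample_genotypes(panel, 260, seed=42)
    db = br.build_beacon(genotypes, np.arange(200))
    return panel, genotypes, db
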