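"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

from famjoint.datamodel import Family, FamilyCohort, MarkerInfo
from famjoint.simulate import SimulationConfig, simulate_cohort


def make_markers(L, start=0):
    return [MarkerInfo(f"m{start + i}", "1", (i + 0.5) / L, i + 1, "A", "G")
            for i in range(L)]


def manual_cohort(father, mother, children, traits, L=None, ancestry=None):
    """Build a trio-per-row cohort from plain lists.

    father/mother: list of genotype vectors (one per family); children: list of
    (m, L) arrays; traits: list of (father, mother, [child...]) tuples.
    """
    fams = []
    L = len(father[0]) if L is None else L
    for i, (f, m, c, t) in enumerate(zip(father, mother, children, traits)):
        fams.append(Family(
            family_id=f"F{i + 1}",
            father_genotypes=np.asarray(f, dtype=float),
            mother_genotypes=np.asarray(m, dtype=float),
            child_genotypes=np.atleast_2d(np.asarray(c, dtype=float)),
            father_trait=float(t[0]), mother_trait=float(t[1]),
            child_traits=np.asarray(t[2:], dtype=float),
            ancestry=None if ancestry is None else np.asarray(ancestry[i]),
        ))
    return FamilyCohort(fams, make_markers(L))


@pytest.fixture(scope="session")
def small_null_cohort():
    """200 homogeneous trios, 300 markers, null traits."""
    cfg = SimulationConfig(population="homogeneous", n_families=200,
                           n_markers=300, map_length=1.0, seed=101)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def structured_cohort():
    """300 structured trios (Fst 0.15, 70/30), mu = 2 null shift, 400 markers."""
    cfg = SimulationConfig(population="structured", n_families=300,
                           n_markers=400, map_length=1.0, mu=2.0, seed=202)
    return simulate_cohort(cfg)
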