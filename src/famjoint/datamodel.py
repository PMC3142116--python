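"""Domain types for nuclear-family genotype/phenotype cohorts.

Genotypes are stored as minor-allele counts in {0, 1, 2} with ``nan`` as the
missing sentinel.  A :class:`FamilyCohort` is the unit every statistical test
consumes; it exposes cached cohort-level arrays so the per-marker tests can be
vectorised over the whole panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Optional, Sequence

import numpy as np

__all__ = ["MarkerInfo", "Family", "FamilyCohort"]


@dataclass(frozen=True)
class MarkerInfo:
    """A single biallelic marker on the genotyping panel."""

    marker_id: str
    chromosome: str
    genetic_pos: float  # Morgans
    physical_pos: int   # base pairs
    allele_minor: str
    allele_major: str

    def __post_init__(self) -> None:
        if self.genetic_pos < 0:
            raise ValueError(f"marker {self.marker_id}: genetic_pos must be >= 0")
        if self.allele_minor == self.allele_major:
            raise ValueError(f"marker {self.marker_id}: minor and major alleles coincide")


@dataclass
class Family:
    """A nuclear family: two parents plus ``m >= 1`` children.

    Genotype vectors hold minor-allele counts over the L panel markers
    (``nan`` = missing).  Mendelian consistency is not enforced here; use
    :func:`famjoint.io.validate_mendelian` to audit it.
    """

    family_id: str
    father_genotypes: np.ndarray          # (L,)
    mother_genotypes: np.ndarray          # (L,)
    child_genotypes: np.ndarray           # (m, L)
    father_trait: float
    mother_trait: float
    child_traits: np.ndarray              # (m,)
    ancestry: Optional[np.ndarray] = None  # (2 + m,) in [0, 1]; father, mother, children
    father_id: str = "1"
    mother_id: str = "2"
    child_ids: Sequence[str] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.father_genotypes = np.asarray(self.father_genotypes, dtype=float)
        self.mother_genotypes = np.asarray(self.mother_genotypes, dtype=float)
        self.child_genotypes = np.atleast_2d(np.asarray(self.child_genotypes, dtype=float))
        self.child_traits = np.atleast_1d(np.asarray(self.child_traits, dtype=float))
        m = self.child_genotypes.shape[0]
        if m < 1:
            raise ValueError(f"family {self.family_id}: at least one child required")
        L = self.father_genotypes.shape[0]
        if self.mother_genotypes.shape[0] != L or self.child_genotypes.shape[1] != L:
            raise ValueError(f"family {self.family_id}: genotype vectors differ in length")
        if self.child_traits.shape[0] != m:
            raise ValueError(f"family {self.family_id}: {m} children but "
                             f"{self.child_traits.shape[0]} child traits")
        if not self.child_ids:
            self.child_ids = tuple(str(3 + j) for j in range(m))

    @property
    def n_children(self) -> int:
        return self.child_genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.father_genotypes.shape[0]


class FamilyCohort:
    """A collection of families genotyped on a shared marker panel.

    Treated as immutable after construction: the array views below are cached.
    """

    def __init__(self, families: Sequence[Family], markers: Sequence[MarkerInfo]):
        families = list(families)
        markers = list(markers)
        L = len(markers)
        for fam in families:
            if fam.n_markers != L:
                raise ValueError(
                    f"family {fam.family_id} has {fam.n_markers} markers, panel has {L}")
        self.families: list[Family] = families
        self.markers: list[MarkerInfo] = markers

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_members(self) -> int:
        return sum(2 + f.n_children for f in self.families)

    # ---- cohort-level arrays (member-major layout: per family, father,
    # mother, then children, families in order) ----

    @cached_property
    def member_family(self) -> np.ndarray:
        """Family index of each member row."""
        return np.repeat(np.arange(self.n_families),
                         [2 + f.n_children for f in self.families])

    @cached_property
    def member_is_parent(self) -> np.ndarray:
        out = np.zeros(self.n_members, dtype=bool)
        i = 0
        for f in self.families:
            out[i] = out[i + 1] = True
            i += 2 + f.n_children
        return out

    @cached_property
    def member_is_father(self) -> np.ndarray:
        out = np.zeros(self.n_members, dtype=bool)
        i = 0
        for f in self.families:
            out[i] = True
            i += 2 + f.n_children
        return out

    @cached_property
    def genotype_matrix(self) -> np.ndarray:
        """(n_members, L) minor-allele counts, nan = missing."""
        out = np.empty((self.n_members, self.n_markers))
        i = 0
        for f in self.families:
            out[i] = f.father_genotypes
            out[i + 1] = f.mother_genotypes
            out[i + 2:i + 2 + f.n_children] = f.child_genotypes
            i += 2 + f.n_children
        return out

    @cached_property
    def trait_vector(self) -> np.ndarray:
        vals = []
        for f in self.families:
            vals.append(f.father_trait)
            vals.append(f.mother_trait)
            vals.extend(f.child_traits.tolist())
        return np.asarray(vals, dtype=float)

    @cached_property
    def ancestry_vector(self) -> Optional[np.ndarray]:
        if any(f.ancestry is None for f in self.families):
            return None
        return np.concatenate([np.asarray(f.ancestry, dtype=float) for f in self.families])

    @cached_property
    def children_per_family(self) -> np.ndarray:
        return np.asarray([f.n_children for f in self.families])

    def parental_allele_freq(self) -> np.ndarray:
        """Per-marker minor-allele frequency among founders (nan-aware)."""
        G = self.genotype_matrix[self.member_is_parent]
        with np.errstate(invalid="ignore"):
            return np.nanmean(G, axis=0) / 2.0

    def with_traits(self, traits: np.ndarray) -> "FamilyCohort":
        """Return a new cohort sharing genotypes but with replaced traits.

        ``traits`` follows the member-major layout of :attr:`trait_vector`.
        """
        traits = np.asarray(traits, dtype=float)
        if traits.shape[0] != self.n_members:
            raise ValueError("trait vector length mismatch")
        fams = []
        i = 0
        for f in self.families:
            m = f.n_children
            fams.append(Family(
                family_id=f.family_id,
                father_genotypes=f.father_genotypes,
                mother_genotypes=f.mother_genotypes,
                child_genotypes=f.child_genotypes,
                father_trait=float(traits[i]),
                mother_trait=float(traits[i + 1]),
                child_traits=traits[i + 2:i + 2 + m].copy(),
                ancestry=f.ancestry,
                father_id=f.father_id,
                mother_id=f.mother_id,
                child_ids=f.child_ids,
            ))
            i += 2 + m
        return FamilyCohort(fams, self.markers)
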