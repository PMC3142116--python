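"""Between-family screening tests.

Both statistics contrast each family's parental-mean genotype score (the
between-family information, a function of the founders only) with the trait
deviations of all family members, parental phenotypes included:

    U_i = [ sum_k (y_ik - ybar) ] * (b_i - bbar),      b_i = (x_fa + x_mo) / 2
    z   = sum_i U_i / sqrt( sum_i U_i^2 )

Families are independent sampling units, so the self-normalized sum is
asymptotically N(0, 1) when E[U_i] = 0 — which holds in a homogeneous
population (unadjusted test) or after PC residualization of traits and
genotype scores (admixture screening test), where the same form is evaluated
on residual quantities.  Because b_i depends only on parental genotypes, both
screening statistics are independent of the transmission-based association
test conditional on the founders, which is what licenses the joint stage-2
combination.

p-values are two-sided standard-normal tails.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .datamodel import FamilyCohort
from .stratification import AdjustedCohort

__all__ = ["ScreeningResult", "b_screen", "a_screen", "screen_all",
           "screening_table", "MIN_PARENTAL_MAF"]

MIN_PARENTAL_MAF = 0.01


@dataclass
class ScreeningResult:
    marker_id: str
    z: float
    p: float
    n_used: int
    flagged: bool = False

    @property
    def ok(self) -> bool:
        return not self.flagged


def _family_parent_rows(cohort: FamilyCohort):
    par = cohort.member_is_parent
    fa = cohort.member_is_father
    return np.nonzero(fa)[0], np.nonzero(par & ~fa)[0]


def _screen_stats(cohort: FamilyCohort, traits: np.ndarray,
                  scores: np.ndarray) -> tuple:
    """Vectorized screening z over a (n_members, M) score matrix.

    Returns (z, n_used) arrays of length M.  Families with a missing parental
    score at a marker are dropped at that marker; trait and genotype means are
    recomputed over the included families per marker.
    """
    fa_rows, mo_rows = _family_parent_rows(cohort)
    B = (scores[fa_rows] + scores[mo_rows]) / 2.0            # (F, M)
    valid = ~np.isnan(B)                                     # (F, M)
    nmem = (2 + cohort.children_per_family).astype(float)    # (F,)

    fam_idx = cohort.member_family
    F = cohort.n_families
    ysum = np.bincount(fam_idx, weights=traits, minlength=F)  # (F,)

    n_used = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = (ysum[:, None] * valid).sum(axis=0) / (nmem[:, None] * valid).sum(axis=0)
        Bbar = np.where(valid, B, 0.0).sum(axis=0) / n_used
        Yt = ysum[:, None] - nmem[:, None] * ybar            # (F, M)
        Bt = np.where(valid, B - Bbar, 0.0)
        U = Yt * Bt
        num = U.sum(axis=0)
        den = np.sqrt((U ** 2).sum(axis=0))
        z = num / den
    return z, n_used


def _flags(cohort: FamilyCohort) -> np.ndarray:
    """Markers excluded from screening: parental MAF below threshold."""
    cached = getattr(cohort, "_screen_flags", None)
    if cached is not None:
        return cached
    freq = cohort.parental_allele_freq()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(freq, 1.0 - freq)
    flags = ~(maf >= MIN_PARENTAL_MAF)  # nan -> flagged
    cohort._screen_flags = flags
    return flags


def _check_traits(cohort: FamilyCohort) -> None:
    y = cohort.trait_vector
    if np.isnan(y[cohort.member_is_parent]).any():
        raise ValueError("parental phenotypes are required for the screening test")
    if np.isnan(y).any():
        raise ValueError("missing trait values")
    if np.ptp(y) < 1e-12:
        raise ValueError("trait is constant; screening statistic undefined")


def b_screen(cohort: FamilyCohort, marker: int) -> ScreeningResult:
    """Unadjusted between-family screening test at one marker."""
    return screen_all(cohort, method="b", markers=[marker])[0]


def a_screen(adjusted: AdjustedCohort, cohort: FamilyCohort,
             marker: int) -> ScreeningResult:
    """Admixture (PC-adjusted) screening test at one marker."""
    return screen_all(cohort, adjusted=adjusted, method="a", markers=[marker])[0]


def screen_all(cohort: FamilyCohort, adjusted: Optional[AdjustedCohort] = None,
               method: str = "b", markers=None) -> List[ScreeningResult]:
    """Screening results for every requested marker (default: whole panel).

    Markers failing the polymorphism precondition are flagged with missing
    z/p, never aborting the sweep.
    """
    _check_traits(cohort)
    if method not in {"a", "b"}:
        raise ValueError("method must be 'a' or 'b'")
    if method == "a":
        if adjusted is None:
            raise ValueError("method 'a' requires an AdjustedCohort")
        traits = adjusted.residual_traits
        scores_full = adjusted.residual_scores
        cand = list(adjusted.candidate_indices)
        if markers is None:
            sel = np.arange(len(cand))
            marker_ids = [cohort.markers[i].marker_id for i in cand]
            flags = _flags(cohort)[np.asarray(cand)]
        else:
            pos = {c: j for j, c in enumerate(cand)}
            try:
                sel = np.array([pos[m] for m in markers])
            except KeyError as e:
                raise ValueError(f"marker {e} not among candidate_indices") from None
            marker_ids = [cohort.markers[m].marker_id for m in markers]
            flags = _flags(cohort)[np.asarray(markers)]
        scores = scores_full[:, sel]
    else:
        traits = cohort.trait_vector
        idx = np.arange(cohort.n_markers) if markers is None else np.asarray(markers)
        scores = cohort.genotype_matrix[:, idx]
        marker_ids = [cohort.markers[i].marker_id for i in idx]
        flags = _flags(cohort)[idx]

    z, n_used = _screen_stats(cohort, traits, scores)
    with np.errstate(invalid="ignore"):
        pvals = 2.0 * ndtr(-np.abs(z))
    out = []
    for j, mid in enumerate(marker_ids):
        if flags[j] or not np.isfinite(z[j]):
            out.append(ScreeningResult(mid, np.nan, np.nan, int(n_used[j]), True))
        else:
            out.append(ScreeningResult(mid, float(z[j]),
                                       float(max(pvals[j], 5e-324)),
                                       int(n_used[j]), False))
    return out


def screening_table(cohort: FamilyCohort,
                    results: List[ScreeningResult]) -> pd.DataFrame:
    """Tabular form: marker_id chrom pos z_screen p_screen flag."""
    by_id = {mk.marker_id: mk for mk in cohort.markers}
    rows = [(r.marker_id, by_id[r.marker_id].chromosome,
             by_id[r.marker_id].physical_pos, r.z, r.p, int(r.flagged))
            for r in results]
    return pd.DataFrame(rows, columns=["marker_id", "chrom", "pos",
                                       "z_screen", "p_screen", "flag"])
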