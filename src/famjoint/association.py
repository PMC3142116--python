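"""Within-family QPTD association test.

The quantitative pedigree transmission-disequilibrium statistic contrasts each
child's genotype score with its Mendelian expectation given the parents (the
midparent value), weighted by the child's trait deviation:

    V_i = sum_{children j} (y_ij - ybar_c) * (x_ij - (x_fa + x_mo)/2)
    z   = sum_i V_i / sqrt( sum_i sum_j (y_ij - ybar_c)^2 * (het_fa + het_mo)/4 )

Conditional on parental genotypes and all trait values, the transmissions are
the only randomness under the null: E[V_i] = 0 regardless of population
structure, and the variance of each child's transmission deviation is exactly
(het_fa + het_mo)/4, a quarter per heterozygous parent (a homozygous parent
transmits deterministically).  Transmissions to different children are
conditionally independent given the parents, so the denominator is the exact
null standard deviation of the numerator and z is asymptotically N(0, 1) —
immune to stratification by design.  Sib trait correlation enters only
through the fixed weights (y_ij - ybar_c), never as an independence
assumption.  ybar_c is the mean trait of the children entering the sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .datamodel import FamilyCohort

__all__ = ["AssociationResult", "qptd", "qptd_all", "association_table"]


@dataclass
class AssociationResult:
    marker_id: str
    z: float
    p: float
    n_informative: int   # children with at least one heterozygous parent
    flagged: bool = False

    @property
    def ok(self) -> bool:
        return not self.flagged


def _qptd_stats(cohort: FamilyCohort, markers: np.ndarray) -> tuple:
    """Vectorized QPTD over the requested marker columns.

    Returns (z, n_informative) arrays.  A family with any missing trio-member
    genotype at a marker is dropped at that marker (transmission expectation
    undefined); no imputation.
    """
    y = cohort.trait_vector
    if np.isnan(y).any():
        raise ValueError("missing trait values")
    if np.ptp(y) < 1e-12:
        raise ValueError("trait is constant; QPTD statistic undefined")

    G = cohort.genotype_matrix[:, markers]
    par = cohort.member_is_parent
    fa = cohort.member_is_father
    fa_rows = np.nonzero(fa)[0]
    mo_rows = np.nonzero(par & ~fa)[0]
    ch_rows = np.nonzero(~par)[0]
    ch_fam = cohort.member_family[ch_rows]
    F = cohort.n_families

    Gf, Gm = G[fa_rows], G[mo_rows]                       # (F, M)
    Gc = G[ch_rows]                                       # (C, M)
    mid = (Gf + Gm) / 2.0

    trios_only = Gc.shape[0] == F  # one child per family -> ch_fam is arange(F)

    # family-marker validity: both parents and every child observed
    if trios_only:
        child_nan = np.isnan(Gc)
    else:
        child_nan = np.zeros((F, G.shape[1]), dtype=bool)
        np.logical_or.at(child_nan, ch_fam, np.isnan(Gc))
    valid = ~(np.isnan(mid) | child_nan)                  # (F, M)

    het = ((Gf == 1) | (Gm == 1)) & valid                 # informative families
    # informative-child count: children of informative families
    n_children = cohort.children_per_family
    n_informative = (het * n_children[:, None]).sum(axis=0)

    dev = Gc - mid[ch_fam]                                # (C, M)
    yc = y[ch_rows]

    w = valid[ch_fam]                                     # child-level inclusion
    vfac = ((Gf == 1).astype(float) + (Gm == 1).astype(float)) / 4.0  # (F, M)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_inc = w.sum(axis=0).astype(float)
        ybar = np.where(w, yc[:, None], 0.0).sum(axis=0) / n_inc
        ydev = yc[:, None] - ybar
        num = np.where(w, ydev * dev, 0.0).sum(axis=0)
        var = np.where(w, ydev ** 2 * vfac[ch_fam], 0.0).sum(axis=0)
        z = num / np.sqrt(var)
    z[n_informative == 0] = np.nan
    return z, n_informative


def qptd(cohort: FamilyCohort, marker: int) -> AssociationResult:
    """QPTD test at one marker."""
    return qptd_all(cohort, markers=[marker])[0]


def qptd_all(cohort: FamilyCohort, markers=None) -> List[AssociationResult]:
    """QPTD results for every requested marker (default: whole panel).

    Markers with zero informative families (or a degenerate variance) are
    flagged rather than aborting the sweep.
    """
    idx = np.arange(cohort.n_markers) if markers is None else np.asarray(markers)
    z, n_inf = _qptd_stats(cohort, idx)
    with np.errstate(invalid="ignore"):
        pvals = 2.0 * ndtr(-np.abs(z))
    out = []
    for j, m in enumerate(idx):
        mid = cohort.markers[m].marker_id
        if not np.isfinite(z[j]):
            out.append(AssociationResult(mid, np.nan, np.nan, int(n_inf[j]), True))
        else:
            out.append(AssociationResult(mid, float(z[j]),
                                         float(max(pvals[j], 5e-324)),
                                         int(n_inf[j]), False))
    return out


def association_table(results: List[AssociationResult]) -> pd.DataFrame:
    """Tabular form: marker_id z_assoc p_assoc n_informative."""
    return pd.DataFrame(
        [(r.marker_id, r.z, r.p, r.n_informative) for r in results],
        columns=["marker_id", "z_assoc", "p_assoc", "n_informative"])
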