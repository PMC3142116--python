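"""Stage-1 selection, the joint statistic, and its selection-conditional p-value.

Stage 1 keeps the R markers with the smallest screening p-values; this is
equivalent to a threshold C on |z_screen| (C = the |z| of the R-th selected
marker).  Stage 2 then tests each selected marker, Bonferroni-corrected at
alpha / R, with one of:

* FTSA   — unadjusted screening selection, within-family QPTD p-value;
* AFTSA  — PC-adjusted (admixture) screening selection, QPTD p-value;
* joint  — admixture screening selection and the combined statistic
  z_joint = w * z_screen + sqrt(1 - w^2) * z_assoc, whose p-value conditions
  on the selection event |Z_s| >= C.

With the screening and association statistics independent N(0, 1) under the
null, z_joint is N(0, 1) unconditionally; the conditional p-value

    P(|w Z_s + sqrt(1 - w^2) Z_a| >= |z_obs|  |  |Z_s| >= C)

is computed by adaptive quadrature over the truncated screening variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import ndtr

_SQRT_2PI = math.sqrt(2.0 * math.pi)

from .association import AssociationResult, qptd_all
from .datamodel import FamilyCohort
from .screening import ScreeningResult, screen_all
from .stratification import adjust_cohort

__all__ = ["StageOneSelection", "JointResult", "select_top_r", "z_joint",
           "conditional_p", "run_pipeline", "PipelineOutput", "DEFAULT_WEIGHT"]

DEFAULT_WEIGHT = 1.0 / math.sqrt(2.0)


@dataclass
class StageOneSelection:
    selected: np.ndarray        # marker indices, R smallest screening p-values
    threshold_C: float          # |z| of the R-th selected marker
    screening_method: str       # 'b' or 'a'


@dataclass
class JointResult:
    marker_id: str
    z_joint: float
    p_joint: float
    significant: bool


@dataclass
class PipelineOutput:
    table: pd.DataFrame
    selection: StageOneSelection
    method: str

    @property
    def any_significant(self) -> bool:
        return bool(self.table["significant"].fillna(False).any())


def select_top_r(screening: Sequence[ScreeningResult], R: int,
                 method: str = "a",
                 marker_indices: Optional[Sequence[int]] = None) -> StageOneSelection:
    """Select the R markers with the smallest screening p-values.

    Ties are broken by marker index ascending.  If fewer than R unflagged
    markers exist, all of them are selected.  ``marker_indices`` maps result
    positions to panel indices (defaults to 0..len-1).
    """
    if marker_indices is None:
        marker_indices = np.arange(len(screening))
    marker_indices = np.asarray(marker_indices)
    ok = [(r.p, int(marker_indices[j]), abs(r.z))
          for j, r in enumerate(screening) if not r.flagged]
    if not ok:
        raise ValueError("no unflagged markers to select from")
    ok.sort(key=lambda t: (t[0], t[1]))
    chosen = ok[:R]
    selected = np.array([t[1] for t in chosen])
    threshold_C = float(chosen[-1][2])
    return StageOneSelection(selected, threshold_C, method)


def z_joint(z_screen: float, z_assoc: float, w: float = DEFAULT_WEIGHT):
    """Weighted combination w*z_screen + sqrt(1-w^2)*z_assoc.

    With independent N(0,1) inputs the output is N(0,1) for any |w| < 1.
    """
    if abs(w) >= 1.0:
        raise ValueError("weight w must satisfy |w| < 1")
    return w * np.asarray(z_screen) + math.sqrt(1.0 - w * w) * np.asarray(z_assoc)


def conditional_p(z_obs: float, C: float, w: float = DEFAULT_WEIGHT,
                  tol: float = 1e-10) -> float:
    """P(|w Z_s + s Z_a| >= |z_obs| given |Z_s| >= C), s = sqrt(1 - w^2).

    Z_s, Z_a independent standard normal.  Computed as

        int_{C}^{C+10} [ Phibar((t - w x)/s) + Phi((-t - w x)/s) ] phi(x) dx
        -----------------------------------------------------------------
                                Phi(-C)

    using the evenness of the integrand pair (x -> -x matched with
    Z_a -> -Z_a) to fold the negative tail; the region beyond C + 10 is below
    double-precision relevance relative to Phi(-C).
    """
    if abs(w) >= 1.0:
        raise ValueError("weight w must satisfy |w| < 1")
    if C < 0:
        raise ValueError("threshold C must be >= 0")
    tail = float(ndtr(-C))
    if tail == 0.0:
        raise ValueError("P(|Z_s| >= C) underflows; use a smaller C")
    t = abs(float(z_obs))
    if t == 0.0:
        return 1.0
    s = math.sqrt(1.0 - w * w)

    def integrand(x):
        phi = math.exp(-0.5 * x * x) / _SQRT_2PI
        return (ndtr((w * x - t) / s) + ndtr((-t - w * x) / s)) * phi

    val, _ = integrate.quad(integrand, C, C + 10.0, epsabs=tol, epsrel=1e-10,
                            limit=200)
    p = val / tail
    return float(min(max(p, 5e-324), 1.0))


def run_pipeline(cohort: FamilyCohort, method: str, R: int = 10,
                 alpha: float = 0.05, K: int = 10, l: int = 800,
                 seed: int = 0, w: float = DEFAULT_WEIGHT) -> PipelineOutput:
    """Run one full two-stage analysis on a cohort.

    method: 'ftsa' (unadjusted screen + QPTD), 'aftsa' (admixture screen +
    QPTD), or 'joint' (admixture screen + conditional joint test).  Stage-2
    significance is Bonferroni alpha / R.
    """
    method = method.lower()
    if method not in {"ftsa", "aftsa", "joint"}:
        raise ValueError("method must be one of: ftsa, aftsa, joint")

    if method == "ftsa":
        screening = screen_all(cohort, method="b")
    else:
        adjusted = adjust_cohort(cohort, K=K, l=l, seed=seed)
        screening = screen_all(cohort, adjusted=adjusted, method="a")

    sel = select_top_r(screening, R,
                       method="b" if method == "ftsa" else "a")
    assoc = qptd_all(cohort)
    thresh = alpha / R

    rows = []
    sel_set = set(int(i) for i in sel.selected)
    for m, (scr, asc) in enumerate(zip(screening, assoc)):
        is_sel = m in sel_set
        zj = pj = np.nan
        sig = False
        if is_sel and not asc.flagged:
            if method == "joint":
                zj = float(z_joint(scr.z, asc.z, w))
                pj = conditional_p(zj, sel.threshold_C, w)
                sig = pj < thresh
            else:
                sig = asc.p < thresh
        rows.append((scr.marker_id, scr.z, scr.p, is_sel,
                     asc.z, asc.p, zj, pj, sig))
    table = pd.DataFrame(rows, columns=[
        "marker_id", "z_screen", "p_screen", "selected",
        "z_assoc", "p_assoc", "z_joint", "p_joint", "significant"])
    return PipelineOutput(table, sel, method)
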