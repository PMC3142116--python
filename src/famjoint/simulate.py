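"""Synthetic-data generator for family-based association studies.

Emulates three study conditions:

* a **homogeneous** population (one haplotype panel, per-site frequencies
  uniform on ``maf_range``);
* a **structured** population of two subpopulations diverged under the
  Balding–Nichols model at a given Fst, families sampled 70%/30% with every
  member of a family from the same subpopulation;
* an **admixed** population of two ancestral populations with admixture
  proportions (0.8, 0.2) laid down as ancestry tracks at the crossover rate
  (equivalent to ~6 generations of admixture).

Parental haplotypes are mosaics of the panel haplotypes with crossover counts
Poisson(6 per Morgan) and uniform breakpoint locations; children receive one
recombined gamete from each parent, so Mendelian consistency holds by
construction.  Null traits are exchangeably correlated within families
(parents independent N(0,1); parent–child and sib–sib correlation rho) and
genetic/stratification effects are added on top: a disease-locus term
beta * X(genotype) with beta calibrated so the locus explains heritability h
of the unit background variance, a subpopulation mean shift mu (structured),
or mu times the member's ancestry proportion (admixed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .datamodel import Family, FamilyCohort, MarkerInfo

__all__ = [
    "CROSSOVER_RATE", "SimulationConfig", "HaplotypePanel", "make_panel",
    "recombine", "meiosis", "make_families", "simulate_null_traits",
    "effect_coding", "beta_from_h", "simulate_alt_traits",
    "choose_disease_marker", "simulate_cohort",
]

CROSSOVER_RATE = 6.0  # expected crossovers per Morgan


@dataclass
class SimulationConfig:
    """Complete description of one simulated scenario."""

    population: str = "homogeneous"       # homogeneous | structured | admixed
    n_families: int = 400
    children_per_family: int = 1
    n_markers: int = 2000
    map_length: float = 2.8               # Morgans (~ human chromosome 1)
    rho: float = 0.4                      # parent-child and sib-sib correlation
    h: float = 0.0                        # locus heritability
    disease_model: str = "none"           # dominant | recessive | additive | none
    mu: float = 0.0                       # subpopulation / ancestry trait shift
    admixture_props: Tuple[float, float] = (0.8, 0.2)
    subpop_fractions: Tuple[float, float] = (0.7, 0.3)
    fst: float = 0.15
    maf_range: Tuple[float, float] = (0.05, 0.5)
    disease_maf_range: Tuple[float, float] = (0.1, 0.3)
    panel_haplotypes: int = 120           # chromosomes per source panel
    ld_blocks: bool = False               # optional block-LD panel mode
    ld_block_mean_markers: float = 10.0
    ld_block_haplotypes: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population not in {"homogeneous", "structured", "admixed"}:
            raise ValueError(f"unknown population model {self.population!r}")
        if not (0.0 <= self.h < 1.0):
            raise ValueError("heritability h must lie in [0, 1)")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        for pair, name in ((self.admixture_props, "admixture_props"),
                           (self.subpop_fractions, "subpop_fractions")):
            if abs(sum(pair) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo < hi <= 0.5")


@dataclass
class HaplotypePanel:
    """Source haplotypes per population plus the shared genetic map."""

    haplotypes: list                      # per population: (H, L) uint8
    allele_freqs: np.ndarray              # (n_pops, L) population frequencies
    genetic_map: np.ndarray               # (L,) positions in Morgans
    map_length: float

    @property
    def n_pops(self) -> int:
        return len(self.haplotypes)

    @property
    def n_markers(self) -> int:
        return self.haplotypes[0].shape[1]


def make_panel(config: SimulationConfig,
               rng: Optional[np.random.Generator] = None) -> HaplotypePanel:
    """Build the source haplotype panel(s) for a scenario.

    Homogeneous: one panel with per-marker frequency ~ Uniform(maf_range).
    Structured/admixed: two panels with Balding–Nichols divergence — ancestral
    frequency p0 ~ Uniform(maf_range), population frequency
    ~ Beta(p0 (1-Fst)/Fst, (1-p0)(1-Fst)/Fst).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L, H = config.n_markers, config.panel_haplotypes
    pos = (np.arange(L) + 0.5) / L * config.map_length

    lo, hi = config.maf_range
    p0 = rng.uniform(lo, hi, size=L)
    if config.population == "homogeneous":
        freqs = p0[None, :]
    else:
        F = config.fst
        a = p0 * (1.0 - F) / F
        b = (1.0 - p0) * (1.0 - F) / F
        freqs = np.clip(rng.beta(a, b, size=(2, L)), 1e-4, 1.0 - 1e-4)

    haps = []
    for k in range(freqs.shape[0]):
        if config.ld_blocks:
            haps.append(_block_ld_haplotypes(freqs[k], H, config, rng))
        else:
            haps.append((rng.random((H, L)) < freqs[k]).astype(np.uint8))
    return HaplotypePanel(haps, freqs, pos, config.map_length)


def _block_ld_haplotypes(freq: np.ndarray, H: int, config: SimulationConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Markers in geometric-length blocks share draws from a small set of
    block haplotypes, creating local LD."""
    L = freq.size
    out = np.empty((H, L), dtype=np.uint8)
    nb = config.ld_block_haplotypes
    start = 0
    while start < L:
        blen = min(int(rng.geometric(1.0 / config.ld_block_mean_markers)), L - start)
        block = (rng.random((nb, blen)) < freq[start:start + blen]).astype(np.uint8)
        pick = rng.integers(nb, size=H)
        out[:, start:start + blen] = block[pick]
        start += blen
    return out


def recombine(panel_haps: np.ndarray, genetic_map: np.ndarray,
              map_length: float, rng: np.random.Generator) -> np.ndarray:
    """One recombinant of the panel haplotypes.

    Crossover count ~ Poisson(rate * map_length); breakpoint locations
    uniform; each segment copies a uniformly chosen panel haplotype.
    """
    H = panel_haps.shape[0]
    k = rng.poisson(CROSSOVER_RATE * map_length)
    if k == 0:
        return panel_haps[rng.integers(H)].copy()
    bp = np.sort(rng.uniform(0.0, map_length, size=k))
    seg = np.searchsorted(bp, genetic_map)
    src = rng.integers(H, size=k + 1)
    return panel_haps[src[seg], np.arange(genetic_map.size)]


def _admixed_haplotype(panel: HaplotypePanel, props: Sequence[float],
                       rng: np.random.Generator) -> tuple:
    """A haplotype whose ancestry tracks alternate between the two source
    populations; returns (haplotype, fraction of genetic length from pop 1)."""
    Lm = panel.map_length
    k = rng.poisson(CROSSOVER_RATE * Lm)
    bp = np.sort(rng.uniform(0.0, Lm, size=k)) if k else np.empty(0)
    anc = (rng.random(k + 1) >= props[0]).astype(int)   # 0 = population 1
    seg = np.searchsorted(bp, panel.genetic_map)
    edges = np.concatenate([[0.0], bp, [Lm]])
    seg_len = np.diff(edges)
    frac_pop1 = float(seg_len[anc == 0].sum() / Lm)
    # within each ancestry segment, copy a recombinant of that source panel
    hap = np.empty(panel.n_markers, dtype=np.uint8)
    for pop in (0, 1):
        mask = anc[seg] == pop
        if mask.any():
            hap[mask] = recombine(panel.haplotypes[pop], panel.genetic_map,
                                  Lm, rng)[mask]
    return hap, frac_pop1


def meiosis(hap1: np.ndarray, hap2: np.ndarray, genetic_map: np.ndarray,
            map_length: float, rng: np.random.Generator) -> np.ndarray:
    """Transmit one gamete: recombine the parent's two haplotypes."""
    k = rng.poisson(CROSSOVER_RATE * map_length)
    start = int(rng.integers(2))
    if k == 0:
        return (hap1 if start == 0 else hap2).copy()
    bp = np.sort(rng.uniform(0.0, map_length, size=k))
    use = (np.searchsorted(bp, genetic_map) + start) % 2
    return np.where(use == 0, hap1, hap2)


def make_families(config: SimulationConfig,
                  rng: Optional[np.random.Generator] = None,
                  panel: Optional[HaplotypePanel] = None) -> FamilyCohort:
    """Generate a cohort of nuclear families (genotypes only; traits = nan).

    Structured: each family's subpopulation drawn by ``subpop_fractions``
    (label stored on the Family as ``subpop``).  Admixed: each member's
    ancestry proportion (genome fraction from population 1) is recorded.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if panel is None:
        panel = make_panel(config, rng)
    gmap, Lm = panel.genetic_map, panel.map_length
    markers = [MarkerInfo(f"m{m}", "1", float(gmap[m]), int(m + 1), "A", "G")
               for m in range(panel.n_markers)]

    families = []
    m_child = config.children_per_family
    for i in range(config.n_families):
        anc = None
        if config.population == "admixed":
            haps, fracs = [], []
            for _ in range(4):
                h, f = _admixed_haplotype(panel, config.admixture_props, rng)
                haps.append(h)
                fracs.append(f)
            subpop = -1
        else:
            if config.population == "structured":
                subpop = int(rng.random() >= config.subpop_fractions[0])
            else:
                subpop = 0
            src = panel.haplotypes[subpop]
            haps = [recombine(src, gmap, Lm, rng) for _ in range(4)]
            fracs = None
        fh1, fh2, mh1, mh2 = haps

        child_g = np.empty((m_child, panel.n_markers))
        for j in range(m_child):
            gp = meiosis(fh1, fh2, gmap, Lm, rng)
            gm = meiosis(mh1, mh2, gmap, Lm, rng)
            child_g[j] = gp + gm
        if fracs is not None:
            # parents: mean of their two haplotypes' track fractions;
            # children: the midparent value (their conditional expectation)
            anc = np.array([fracs[0] + fracs[1], fracs[2] + fracs[3]]) / 2.0
            anc = np.concatenate([anc, np.full(m_child, (anc[0] + anc[1]) / 2.0)])

        fam = Family(
            family_id=f"F{i + 1}",
            father_genotypes=(fh1 + fh2).astype(float),
            mother_genotypes=(mh1 + mh2).astype(float),
            child_genotypes=child_g,
            father_trait=np.nan, mother_trait=np.nan,
            child_traits=np.full(m_child, np.nan),
            ancestry=anc,
        )
        fam.subpop = subpop
        families.append(fam)
    cohort = FamilyCohort(families, markers)
    cohort.panel = panel
    return cohort


def simulate_null_traits(cohort: FamilyCohort, rho: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Null traits: parents iid N(0,1); children from the conditional MVN.

    The family covariance has unit variances, parent–parent covariance 0, and
    parent–child and sib–sib covariance rho; conditioning on the parents gives
    child mean rho * (y_f + y_m) and covariance
    (1 - rho) I + (rho - 2 rho^2) J, which must be positive semi-definite.
    Returns a member-major trait vector (use ``cohort.with_traits``).
    """
    m_max = int(cohort.children_per_family.max())
    lam_min = (1.0 - rho) + m_max * (rho - 2.0 * rho ** 2)
    if rho < 0 or rho >= 1 or lam_min < -1e-12 or (m_max > 1 and (1.0 - rho) < 0):
        raise ValueError(
            f"infeasible trait covariance for rho={rho} with {m_max} children")

    chols = {}
    traits = np.empty(cohort.n_members)
    i = 0
    # group by family size for vectorized sampling
    sizes = cohort.children_per_family
    offsets = np.concatenate([[0], np.cumsum(2 + sizes)])
    for m in np.unique(sizes):
        fams = np.nonzero(sizes == m)[0]
        n = fams.size
        yp = rng.standard_normal((n, 2))
        cov = (1.0 - rho) * np.eye(m) + (rho - 2.0 * rho ** 2) * np.ones((m, m))
        if m not in chols:
            # guard tiny negative eigenvalues at the PSD boundary
            w, V = np.linalg.eigh(cov)
            chols[m] = V * np.sqrt(np.clip(w, 0.0, None))
        yc = rho * yp.sum(axis=1, keepdims=True) + \
            rng.standard_normal((n, m)) @ chols[m].T
        for j, fi in enumerate(fams):
            o = offsets[fi]
            traits[o:o + 2] = yp[j]
            traits[o + 2:o + 2 + m] = yc[j]
    return traits


def effect_coding(genotype, model: str):
    """Numerical code of the risk-allele count under a penetrance model.

    ``genotype`` counts copies of the high-risk allele.  additive -> the count
    itself; dominant -> 1 if at least one copy; recessive -> 1 only for two
    copies.
    """
    g = np.asarray(genotype, dtype=float)
    if model == "additive":
        return g
    if model == "dominant":
        return (g >= 1).astype(float)
    if model == "recessive":
        return (g >= 2).astype(float)
    raise ValueError(f"unknown disease model {model!r}")


def beta_from_h(h: float, model: str, risk_allele_freq: float) -> float:
    """Effect size beta so the locus explains heritability h.

    With unit background variance and HWE genotype frequencies, beta satisfies
    beta^2 Var(X) / (beta^2 Var(X) + 1) = h, i.e.
    beta = sqrt( h / ((1 - h) Var(X)) ) with Var(X) the HWE variance of the
    model coding (additive 2p(1-p); dominant q(1-q), q = p^2 + 2p(1-p);
    recessive r(1-r), r = p^2).
    """
    if not (0.0 <= h < 1.0):
        raise ValueError("h must lie in [0, 1)")
    p = risk_allele_freq
    if not (0.0 < p < 1.0):
        raise ValueError("risk allele frequency must lie in (0, 1)")
    if h == 0.0:
        return 0.0
    if model == "additive":
        var_x = 2.0 * p * (1.0 - p)
    elif model == "dominant":
        q = p * p + 2.0 * p * (1.0 - p)
        var_x = q * (1.0 - q)
    elif model == "recessive":
        r = p * p
        var_x = r * (1.0 - r)
    else:
        raise ValueError(f"unknown disease model {model!r}")
    if var_x <= 0:
        raise ValueError("degenerate genotype variance at this frequency")
    return math.sqrt(h / ((1.0 - h) * var_x))


def choose_disease_marker(panel: HaplotypePanel, config: SimulationConfig,
                          rng: np.random.Generator) -> int:
    """Random disease locus with population-1 MAF inside ``disease_maf_range``."""
    lo, hi = config.disease_maf_range
    f = panel.allele_freqs[0]
    maf = np.minimum(f, 1.0 - f)
    ok = np.nonzero((maf > lo) & (maf < hi))[0]
    if ok.size == 0:
        raise ValueError("no marker with population-1 MAF in the disease window")
    return int(rng.choice(ok))


def _risk_coding(cohort: FamilyCohort, panel: HaplotypePanel,
                 marker: int, model: str):
    """Risk-allele counts at the disease locus plus the per-population risk
    allele frequencies.

    The minor allele (in population 1) is the high-risk allele for dominant
    and additive models; the major allele for the recessive model.  Stored
    genotypes count the panel '1' allele, so flip when needed.
    """
    f1 = panel.allele_freqs[:, marker]           # coded-allele freq per pop
    minor_is_coded = f1[0] <= 0.5
    risk_is_coded = minor_is_coded if model in ("dominant", "additive") \
        else not minor_is_coded
    g = cohort.genotype_matrix[:, marker]
    counts = g if risk_is_coded else 2.0 - g
    risk_freq = f1 if risk_is_coded else 1.0 - f1
    return counts, risk_freq


def simulate_alt_traits(cohort: FamilyCohort, config: SimulationConfig,
                        disease_marker: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Traits under the alternative: background + beta*X + structure shift.

    beta is calibrated per subpopulation from that subpopulation's risk-allele
    frequency (admixed: the admixture-weighted frequency); with h = 0 this is
    a pure null with only the structure shift.  Structured populations add mu
    to subpopulation 2; admixed populations add mu times each member's
    ancestry proportion.
    """
    panel = getattr(cohort, "panel", None)
    if panel is None:
        raise ValueError("cohort lacks an attached simulation panel")

    y = simulate_null_traits(cohort, config.rho, rng)
    model = config.disease_model

    if config.h > 0:
        if model == "none":
            raise ValueError("h > 0 requires a disease model")
        founder_maf = cohort.parental_allele_freq()[disease_marker]
        if founder_maf <= 0.0 or founder_maf >= 1.0 or np.isnan(founder_maf):
            raise ValueError("disease marker is monomorphic among founders")
        counts, risk_freq = _risk_coding(cohort, panel, disease_marker, model)
        X = effect_coding(counts, model)
        if config.population == "structured":
            betas = np.array([beta_from_h(config.h, model, rf)
                              for rf in risk_freq])
            member_pop = np.array([f.subpop for f in cohort.families])[
                cohort.member_family]
            y = y + betas[member_pop] * X
        elif config.population == "admixed":
            pf = float(np.dot(config.admixture_props, risk_freq))
            y = y + beta_from_h(config.h, model, pf) * X
        else:
            y = y + beta_from_h(config.h, model, float(risk_freq[0])) * X

    if config.mu != 0.0:
        if config.population == "structured":
            member_pop = np.array([f.subpop for f in cohort.families])[
                cohort.member_family]
            y = y + config.mu * (member_pop == 1)
        elif config.population == "admixed":
            anc = cohort.ancestry_vector
            if anc is None:
                raise ValueError("admixed cohort lacks ancestry proportions")
            y = y + config.mu * anc
    return y


def simulate_cohort(config: SimulationConfig,
                    rng: Optional[np.random.Generator] = None,
                    disease_marker: Optional[int] = None) -> FamilyCohort:
    """One replicate: genotypes plus traits per the scenario.

    Under h = 0 and mu = 0 this is the plain null; otherwise
    :func:`simulate_alt_traits` supplies the trait model.  When h > 0 and no
    disease marker is given, one is drawn per the MAF-window rule and stored
    as ``cohort.disease_marker``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cohort = make_families(config, rng)
    if config.h > 0 and disease_marker is None:
        disease_marker = choose_disease_marker(cohort.panel, config, rng)
    if config.h > 0 or config.mu != 0.0:
        traits = simulate_alt_traits(cohort, config, disease_marker
                                     if disease_marker is not None else 0, rng)
    else:
        traits = simulate_null_traits(cohort, config.rho, rng)
    out = cohort.with_traits(traits)
    out.panel = cohort.panel
    out.disease_marker = disease_marker
    for f_old, f_new in zip(cohort.families, out.families):
        f_new.subpop = getattr(f_old, "subpop", 0)
    return out
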