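"""Readers/writers for PLINK-style text PED/MAP plus phenotype and ancestry TSVs.

PED layout: ``FID IID PAT MAT SEX PHENO`` followed by 2L allele columns
(characters in {A, C, G, T}, ``0`` = missing).  Individuals with
``PAT == MAT == 0`` are parents; everyone else is a child and must reference
both parents by IID within the same family.  Genotypes are recoded to
minor-allele counts, where the minor allele is determined from the loaded
cohort's founders (ties at MAF 0.5 broken lexicographically).

MAP layout: ``chrom  marker_id  genetic_pos  physical_pos`` with genetic
positions in Morgans by default (``centimorgan=True`` divides by 100).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .datamodel import Family, FamilyCohort, MarkerInfo

__all__ = [
    "read_ped_map",
    "write_ped_map",
    "validate_mendelian",
    "recode_to_founder_minor",
    "MendelianReport",
]

_VALID_ALLELES = {"A", "C", "G", "T", "0"}


@dataclass
class MendelianViolation:
    family_id: str
    child_id: str
    marker_id: str
    father: float
    mother: float
    child: float


@dataclass
class MendelianReport:
    violations: list

    @property
    def n_violations(self) -> int:
        return len(self.violations)

    def __bool__(self) -> bool:  # truthy when clean
        return self.n_violations == 0


def read_ped_map(ped_path, map_path, pheno_path, *, ancestry_path=None,
                 centimorgan: bool = False) -> FamilyCohort:
    """Load a PED/MAP pair plus a phenotype TSV into a :class:`FamilyCohort`."""
    markers = _read_map(map_path, centimorgan=centimorgan)
    L = len(markers)

    ped = pd.read_csv(ped_path, sep=r"\s+", header=None, dtype=str)
    if ped.shape[1] != 6 + 2 * L:
        raise ValueError(
            f"PED has {ped.shape[1]} columns; expected {6 + 2 * L} for {L} markers")
    ped.columns = ["FID", "IID", "PAT", "MAT", "SEX", "PHENO"] + [
        f"a{i}" for i in range(2 * L)]

    alle = ped.iloc[:, 6:].to_numpy(dtype="U1")
    bad = ~np.isin(alle, sorted(_VALID_ALLELES))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid allele character {alle[r, c]!r} for individual "
            f"{ped.iloc[r]['FID']}/{ped.iloc[r]['IID']} at marker column {c // 2}")

    pheno = pd.read_csv(pheno_path, sep="\t", dtype={"FID": str, "IID": str})
    if not {"FID", "IID", "TRAIT"}.issubset(pheno.columns):
        raise ValueError("phenotype TSV must have columns FID, IID, TRAIT")
    trait_map = {(r.FID, r.IID): float(r.TRAIT) for r in pheno.itertuples()}

    anc_map = {}
    if ancestry_path is not None:
        anc = pd.read_csv(ancestry_path, sep="\t", dtype={"FID": str, "IID": str})
        anc_map = {(r.FID, r.IID): float(r.ANCESTRY) for r in anc.itertuples()}

    is_parent = (ped["PAT"] == "0") & (ped["MAT"] == "0")

    # Minor allele per marker from founders only.
    par_alle = alle[is_parent.to_numpy()]
    minor = np.empty(L, dtype="U1")
    major = np.empty(L, dtype="U1")
    for m in range(L):
        col = par_alle[:, 2 * m:2 * m + 2].ravel()
        col = col[col != "0"]
        chars, counts = np.unique(col, return_counts=True)
        if len(chars) == 0:
            minor[m], major[m] = markers[m].allele_minor, markers[m].allele_major
            continue
        if len(chars) == 1:
            # monomorphic among founders: observed allele is major
            major[m] = chars[0]
            minor[m] = next(a for a in "ACGT" if a != chars[0])
            continue
        if len(chars) > 2:
            raise ValueError(f"marker {markers[m].marker_id}: more than two alleles")
        order = np.argsort(counts, kind="stable")
        if counts[0] == counts[1]:  # MAF 0.5 tie -> lexicographically smaller is minor
            minor[m], major[m] = sorted(chars)
        else:
            minor[m], major[m] = chars[order[0]], chars[order[1]]

    markers = [MarkerInfo(mk.marker_id, mk.chromosome, mk.genetic_pos,
                          mk.physical_pos, str(minor[i]), str(major[i]))
               for i, mk in enumerate(markers)]

    # score = count of minor allele; any '0' allele -> missing
    a1 = alle[:, 0::2]
    a2 = alle[:, 1::2]
    scores = (a1 == minor).astype(float) + (a2 == minor).astype(float)
    scores[(a1 == "0") | (a2 == "0")] = np.nan

    missing_trait = [f"{r.FID}/{r.IID}" for r in ped.itertuples()
                     if (r.FID, r.IID) not in trait_map]
    if missing_trait:
        raise ValueError("missing trait values for: " + ", ".join(missing_trait))

    families = []
    for fid, grp in ped.groupby("FID", sort=False):
        gp = grp.reset_index()
        par = gp[(gp["PAT"] == "0") & (gp["MAT"] == "0")]
        if len(par) != 2:
            raise ValueError(f"family {fid} has {len(par)} parents; expected 2")
        kids = gp[~((gp["PAT"] == "0") & (gp["MAT"] == "0"))]
        if len(kids) < 1:
            raise ValueError(f"family {fid} has no children")
        par_ids = set(par["IID"])
        for r in kids.itertuples():
            if r.PAT not in par_ids or r.MAT not in par_ids:
                raise ValueError(
                    f"family {fid}: child {r.IID} references absent parent")
        # father = the one named by PAT of the first child (fall back to order)
        pat_id = kids.iloc[0]["PAT"]
        father = par[par["IID"] == pat_id].iloc[0]
        mother = par[par["IID"] != pat_id].iloc[0]
        fa_row, mo_row = int(father["index"]), int(mother["index"])
        kid_rows = [int(i) for i in kids["index"]]
        anc = None
        if anc_map:
            ids = [(fid, father["IID"]), (fid, mother["IID"])] + \
                  [(fid, ped.loc[i, "IID"]) for i in kid_rows]
            if all(k in anc_map for k in ids):
                anc = np.array([anc_map[k] for k in ids])
        families.append(Family(
            family_id=str(fid),
            father_genotypes=scores[fa_row],
            mother_genotypes=scores[mo_row],
            child_genotypes=scores[kid_rows],
            father_trait=trait_map[(fid, father["IID"])],
            mother_trait=trait_map[(fid, mother["IID"])],
            child_traits=np.array([trait_map[(fid, ped.loc[i, "IID"])] for i in kid_rows]),
            ancestry=anc,
            father_id=str(father["IID"]),
            mother_id=str(mother["IID"]),
            child_ids=tuple(str(ped.loc[i, "IID"]) for i in kid_rows),
        ))
    return FamilyCohort(families, markers)


def _read_map(map_path, *, centimorgan: bool = False) -> list:
    mp = pd.read_csv(map_path, sep=r"\s+", header=None,
                     names=["chrom", "id", "gpos", "bp"],
                     dtype={"chrom": str, "id": str})
    scale = 0.01 if centimorgan else 1.0
    return [MarkerInfo(str(r.id), str(r.chrom), float(r.gpos) * scale, int(r.bp),
                       "A", "G")
            for r in mp.itertuples()]


def write_ped_map(cohort: FamilyCohort, out_prefix) -> dict:
    """Write PED/MAP + phenotype TSV (+ ancestry sidecar when available).

    Missing genotypes are written as ``0 0``.  Returns the paths written.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {"ped": out_prefix.with_suffix(".ped"),
             "map": out_prefix.with_suffix(".map"),
             "pheno": out_prefix.with_suffix(".pheno.tsv")}

    with open(paths["map"], "w") as fh:
        for mk in cohort.markers:
            fh.write(f"{mk.chromosome}\t{mk.marker_id}\t{mk.genetic_pos:.8f}"
                     f"\t{mk.physical_pos}\n")

    minor = np.array([mk.allele_minor for mk in cohort.markers])
    major = np.array([mk.allele_major for mk in cohort.markers])

    def geno_fields(g):
        out = []
        for j, v in enumerate(g):
            if np.isnan(v):
                out.append("0 0")
            elif v == 0:
                out.append(f"{major[j]} {major[j]}")
            elif v == 1:
                out.append(f"{minor[j]} {major[j]}")
            else:
                out.append(f"{minor[j]} {minor[j]}")
        return out

    pheno_rows = []
    anc_rows = []
    with open(paths["ped"], "w") as fh:
        for fam in cohort.families:
            rows = [
                (fam.father_id, "0", "0", "1", fam.father_genotypes, fam.father_trait),
                (fam.mother_id, "0", "0", "2", fam.mother_genotypes, fam.mother_trait),
            ]
            for j in range(fam.n_children):
                rows.append((fam.child_ids[j], fam.father_id, fam.mother_id, "0",
                             fam.child_genotypes[j], float(fam.child_traits[j])))
            for k, (iid, pat, mat, sex, g, trait) in enumerate(rows):
                fields = [fam.family_id, iid, pat, mat, sex, "-9"] + geno_fields(g)
                fh.write(" ".join(fields) + "\n")
                pheno_rows.append((fam.family_id, iid, trait))
                if fam.ancestry is not None:
                    anc_rows.append((fam.family_id, iid, float(fam.ancestry[k])))

    pd.DataFrame(pheno_rows, columns=["FID", "IID", "TRAIT"]).to_csv(
        paths["pheno"], sep="\t", index=False)
    if anc_rows:
        paths["ancestry"] = Path(str(out_prefix) + ".ancestry.tsv")
        pd.DataFrame(anc_rows, columns=["FID", "IID", "ANCESTRY"]).to_csv(
            paths["ancestry"], sep="\t", index=False)
    return paths


def recode_to_founder_minor(cohort: FamilyCohort) -> FamilyCohort:
    """Flip marker coding so scores count the founder minor allele.

    Markers whose coded allele has founder frequency > 0.5 (or exactly 0.5 with
    a lexicographically larger character) are flipped (g -> 2 - g, allele
    labels swapped).  Idempotent; makes a cohort's coding match what
    :func:`read_ped_map` reconstructs, so write-then-read round-trips exactly.
    """
    freq = cohort.parental_allele_freq()
    flip = np.zeros(cohort.n_markers, dtype=bool)
    for m, mk in enumerate(cohort.markers):
        if np.isnan(freq[m]):
            continue
        if freq[m] > 0.5 or (freq[m] == 0.5 and mk.allele_minor > mk.allele_major):
            flip[m] = True
    if not flip.any():
        return cohort
    markers = []
    for m, mk in enumerate(cohort.markers):
        if flip[m]:
            markers.append(MarkerInfo(mk.marker_id, mk.chromosome, mk.genetic_pos,
                                      mk.physical_pos, mk.allele_major, mk.allele_minor))
        else:
            markers.append(mk)

    def rec(g):
        g = np.asarray(g, dtype=float).copy()
        g[..., flip] = 2.0 - g[..., flip]
        return g

    fams = [Family(f.family_id, rec(f.father_genotypes), rec(f.mother_genotypes),
                   rec(f.child_genotypes), f.father_trait, f.mother_trait,
                   f.child_traits.copy(), f.ancestry, f.father_id, f.mother_id,
                   f.child_ids)
            for f in cohort.families]
    return FamilyCohort(fams, markers)


def validate_mendelian(cohort: FamilyCohort) -> MendelianReport:
    """Report impossible transmissions; never mutates the cohort.

    Marker/family combinations with any missing parental or child genotype
    are skipped.  A parent with count g can transmit any allele count in
    [g // 2, (g + 1) // 2], so child count c is feasible iff it lies in the
    sum of those two intervals.
    """
    violations = []
    for fam in cohort.families:
        f, mo = fam.father_genotypes, fam.mother_genotypes
        lo = np.floor(f / 2) + np.floor(mo / 2)
        hi = np.ceil(f / 2) + np.ceil(mo / 2)
        for j in range(fam.n_children):
            c = fam.child_genotypes[j]
            with np.errstate(invalid="ignore"):
                bad = ((c < lo) | (c > hi)) & ~(np.isnan(f) | np.isnan(mo) | np.isnan(c))
            for m in np.nonzero(bad)[0]:
                violations.append(MendelianViolation(
                    fam.family_id, str(fam.child_ids[j]),
                    cohort.markers[m].marker_id, f[m], mo[m], c[m]))
    return MendelianReport(violations)
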