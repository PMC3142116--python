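"""Parental-genotype PCA and regression adjustment for population structure.

Principal components are fit on the parents only (a naive PCA over related
individuals would bias the directions of maximum variability), then every
family member — parents and children alike — is projected with the parental
means and eigenvectors.  Traits and candidate-locus genotypes are regressed on
the top-K PC scores with coefficients estimated from the parents, and each
member's residual is taken at its own PC scores.  The residuals are what the
stratification-robust screening test consumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import FamilyCohort

__all__ = [
    "PCModel",
    "AdjustedCohort",
    "choose_genomic_markers",
    "fit_parental_pca",
    "project_members",
    "residualize",
    "adjust_cohort",
]


@dataclass
class PCModel:
    """Eigenstructure of the parental genotype covariance at the genomic markers."""

    genomic_marker_indices: np.ndarray  # (l,)
    parental_means: np.ndarray          # (l,) overall mean parental score per marker
    eigenvectors: np.ndarray            # (l, K), columns orthonormal
    eigenvalues: np.ndarray             # (K,), non-increasing
    K: int

    def to_tsv(self, out_prefix) -> dict:
        """Serialize to a TSV bundle (means+eigenvalues, eigenvectors)."""
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {"model": Path(str(out_prefix) + ".pcmodel.tsv"),
                 "vectors": Path(str(out_prefix) + ".pcvectors.tsv")}
        pd.DataFrame({"marker_index": self.genomic_marker_indices,
                      "parental_mean": self.parental_means}).to_csv(
            paths["model"], sep="\t", index=False)
        df = pd.DataFrame(self.eigenvectors,
                          columns=[f"PC{k + 1}" for k in range(self.K)])
        df.attrs["eigenvalues"] = self.eigenvalues
        with open(paths["vectors"], "w") as fh:
            fh.write("#eigenvalues\t" + "\t".join(f"{v:.12g}" for v in self.eigenvalues) + "\n")
            df.to_csv(fh, sep="\t", index=False)
        return paths

    @classmethod
    def from_tsv(cls, out_prefix) -> "PCModel":
        paths = {"model": Path(str(Path(out_prefix)) + ".pcmodel.tsv"),
                 "vectors": Path(str(Path(out_prefix)) + ".pcvectors.tsv")}
        meta = pd.read_csv(paths["model"], sep="\t")
        with open(paths["vectors"]) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            eigvals = np.array([float(v) for v in header[1:]])
            vecs = pd.read_csv(fh, sep="\t").to_numpy()
        return cls(meta["marker_index"].to_numpy(), meta["parental_mean"].to_numpy(),
                   vecs, eigvals, K=len(eigvals))


@dataclass
class AdjustedCohort:
    """Residual traits/genotype scores after regression on parental PCs."""

    residual_traits: np.ndarray            # (n_members,)
    residual_scores: np.ndarray            # (n_members, n_candidates)
    pc_scores: np.ndarray                  # (n_members, K)
    candidate_indices: np.ndarray          # (n_candidates,) panel indices


def choose_genomic_markers(cohort: FamilyCohort, l: int, seed: int) -> np.ndarray:
    """Sample l distinct genomic-marker indices uniformly without replacement."""
    L = cohort.n_markers
    if l > L:
        raise ValueError(f"requested l={l} genomic markers but panel has L={L}")
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(L, size=l, replace=False))


def fit_parental_pca(cohort: FamilyCohort, indices: Sequence[int], K: int) -> PCModel:
    """Top-K eigenpairs of the parental genotype covariance at the genomic markers.

    Missing genotypes are mean-imputed (per-marker parental mean) before
    centering.  Eigenvector signs are fixed so the largest-magnitude loading
    of each vector is positive.
    """
    indices = np.asarray(indices)
    Gp = cohort.genotype_matrix[cohort.member_is_parent][:, indices]
    P = Gp.shape[0]
    if P < K + 1:
        raise ValueError(f"need at least K+1={K + 1} parents, have {P}")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(Gp, axis=0)
    if np.isnan(means).any():
        raise ValueError("a genomic marker is missing in every parent")
    Gp = np.where(np.isnan(Gp), means, Gp) - means

    l = Gp.shape[1]
    if K + 2 < min(P, l) and l > 50:
        # large panel: top-K eigenpairs of Sigma via Lanczos on the covariance
        from scipy.sparse.linalg import eigsh

        cov = (Gp.T @ Gp) / (P - 1)
        # deterministic start vector: eigsh's default is drawn from the
        # global RNG, which would make refits differ in the last few ulps
        v0 = np.full(l, 1.0 / np.sqrt(l))
        eigvals, vecs = eigsh(cov, k=K, which="LA", v0=v0)
        order = np.argsort(eigvals)[::-1]
        eigvals, vecs = eigvals[order], vecs[:, order]
        scale = np.trace(cov)
        if eigvals[-1] <= max(P, l) * np.finfo(float).eps * max(scale, 1.0):
            raise ValueError(
                f"K={K} exceeds the rank of the parental covariance; "
                f"use a smaller K")
        eigvals = np.clip(eigvals, 0.0, None)
    else:
        # small problem: exact economy SVD of the centered parent matrix
        _, s, Vt = np.linalg.svd(Gp, full_matrices=False)
        eigvals = s ** 2 / (P - 1)
        tol = max(Gp.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
        rank = int(np.sum(s > tol))
        if K > rank:
            raise ValueError(
                f"K={K} exceeds the rank ({rank}) of the parental covariance; "
                f"use a smaller K")
        eigvals, vecs = eigvals[:K], Vt[:K].T
    # deterministic sign: largest-|loading| entry positive
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(K)])
    signs[signs == 0] = 1.0
    vecs = vecs * signs
    return PCModel(indices, means, vecs, eigvals, K)


def project_members(cohort: FamilyCohort, model: PCModel) -> np.ndarray:
    """PC scores for every member: eigvec . (genomic genotypes - parental means).

    Children are projected with the parental means and eigenvectors; the model
    is never re-fit.  Missing genomic genotypes are imputed at the parental
    mean (zero after centering).
    """
    G = cohort.genotype_matrix[:, model.genomic_marker_indices]
    G = np.where(np.isnan(G), model.parental_means, G) - model.parental_means
    return G @ model.eigenvectors


def residualize(cohort: FamilyCohort, pc_scores: np.ndarray,
                candidate_indices: Optional[Sequence[int]] = None) -> AdjustedCohort:
    """Regress trait and candidate genotypes on PCs (parents only) and residualize.

    Least-squares coefficients (with intercept) are estimated from the parents;
    residuals for parents and children subtract the fitted value at each
    member's own PC scores.  A missing candidate genotype yields a missing
    residual.
    """
    pc_scores = np.atleast_2d(np.asarray(pc_scores, dtype=float))
    if pc_scores.shape[0] != cohort.n_members:
        raise ValueError("pc_scores rows must equal the number of members")
    if candidate_indices is None:
        candidate_indices = np.arange(cohort.n_markers)
    candidate_indices = np.asarray(candidate_indices)

    par = cohort.member_is_parent
    D_all = np.column_stack([np.ones(cohort.n_members), pc_scores])
    Dp = D_all[par]
    if np.linalg.matrix_rank(Dp) < Dp.shape[1]:
        raise ValueError("parental PC design matrix is rank-deficient")

    y = cohort.trait_vector
    G = cohort.genotype_matrix[:, candidate_indices]
    Gp = G[par]

    targets = np.column_stack([y[par], Gp])
    nan_cols = np.isnan(targets).any(axis=0)
    coef = np.zeros((Dp.shape[1], targets.shape[1]))
    if (~nan_cols).any():
        # normal equations: the PC design is well-conditioned by construction
        gram = Dp.T @ Dp
        coef[:, ~nan_cols] = np.linalg.solve(gram, Dp.T @ targets[:, ~nan_cols])
    for j in np.nonzero(nan_cols)[0]:
        mask = ~np.isnan(targets[:, j])
        if mask.sum() > Dp.shape[1]:
            coef[:, j] = np.linalg.lstsq(Dp[mask], targets[mask, j], rcond=None)[0]
        # else: too few observed parents; residuals stay as value - 0 (flagged
        # downstream by the polymorphism filter)

    fitted = D_all @ coef
    residual_traits = y - fitted[:, 0]
    residual_scores = G - fitted[:, 1:]
    return AdjustedCohort(residual_traits, residual_scores, pc_scores,
                          candidate_indices)


def adjust_cohort(cohort: FamilyCohort, *, K: int = 10, l: int = 800,
                  seed: int = 0,
                  candidate_indices: Optional[Sequence[int]] = None) -> AdjustedCohort:
    """Convenience: choose genomic markers, fit parental PCA, project, residualize.

    ``K = 0`` is the degenerate no-PC path (intercept-only residualization),
    in which case the adjusted screening test reduces to the unadjusted one.
    """
    if K == 0:
        pcs = np.zeros((cohort.n_members, 0))
        return residualize(cohort, pcs, candidate_indices)
    idx = choose_genomic_markers(cohort, l, seed)
    model = fit_parental_pca(cohort, idx, K)
    pcs = project_members(cohort, model)
    return residualize(cohort, pcs, candidate_indices)
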