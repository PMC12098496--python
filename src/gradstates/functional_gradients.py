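"""Per-network functional gradients via diffusion-map embedding.

The sequence mirrors the standard gradient toolchain: voxel-to-parcel Fisher-z
connectivity, per-row top-density sparsification (default top 10% of 400
parcels), cosine affinity between voxel profiles, anisotropic diffusion-map
embedding (alpha = 0.5, diffusion time t = 0), Procrustes alignment of
individual embeddings to a group-average template, per-component z-scoring,
and dispersion metrics (centroid-to-centroid Euclidean distances in gradient
space, plus within-region voxel-to-centroid dispersion).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.sparse.csgraph import connected_components

from ._utils import fisher_z

logger = logging.getLogger("gradstates.functional_gradients")


def build_network_fc(voxel_ts: np.ndarray, parcel_ts: np.ndarray) -> np.ndarray:
    """Fisher-z Pearson correlations between each voxel and each parcel mean
    series.  Inputs are T x n_voxels and T x n_parcels; output n_voxels x
    n_parcels.  Constant voxel series yield a zero row (logged)."""
    voxel_ts = np.asarray(voxel_ts, float)
    parcel_ts = np.asarray(parcel_ts, float)
    if voxel_ts.shape[0] != parcel_ts.shape[0]:
        raise ValueError("voxel and parcel series must share T")
    vc = voxel_ts - voxel_ts.mean(axis=0)
    pc = parcel_ts - parcel_ts.mean(axis=0)
    vs = np.sqrt((vc**2).sum(axis=0))
    ps = np.sqrt((pc**2).sum(axis=0))
    const_v = vs <= 0
    const_p = ps <= 0
    vs = np.where(const_v, 1.0, vs)
    ps = np.where(const_p, 1.0, ps)
    r = (vc.T @ pc) / np.outer(vs, ps)
    if const_v.any():
        logger.warning("%d constant voxel series; rows set to 0", const_v.sum())
        r[const_v, :] = 0.0
    if const_p.any():
        r[:, const_p] = 0.0
    return fisher_z(r)


def sparsify_rows(fc: np.ndarray, density: float = 0.10) -> np.ndarray:
    """Keep the ceil(density * n_columns) largest values per row, zero the rest.

    Ties at the retention threshold are broken toward the lower column index,
    making the operation deterministic.
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    fc = np.asarray(fc, float)
    n_keep = int(np.ceil(density * fc.shape[1]))
    if n_keep >= fc.shape[1]:
        return fc.copy()
    out = np.zeros_like(fc)
    # stable argsort of -row: among equal values the lower column index wins
    order = np.argsort(-fc, axis=1, kind="stable")[:, :n_keep]
    rows = np.repeat(np.arange(fc.shape[0]), n_keep)
    out[rows, order.ravel()] = fc[rows, order.ravel()]
    return out


def cosine_affinity(sparse_fc: np.ndarray) -> np.ndarray:
    """Cosine similarity between sparsified voxel profiles; diagonal forced to 1."""
    sparse_fc = np.asarray(sparse_fc, float)
    norms = np.linalg.norm(sparse_fc, axis=1)
    zero = np.flatnonzero(norms <= 0)
    if zero.size:
        raise ValueError(
            f"all-zero sparsified profile for voxel(s) {zero[:5].tolist()} "
            "(constant upstream series?)"
        )
    A = (sparse_fc / norms[:, None]) @ (sparse_fc / norms[:, None]).T
    A = np.clip((A + A.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(A, 1.0)
    return A


@dataclass
class Embedding:
    """Diffusion-map components (columns, non-increasing eigenvalue order)."""

    components: np.ndarray  # n_voxels x n_components
    eigenvalues: np.ndarray
    alpha: float
    diffusion_time: float
    aligned: bool = False
    zscored: bool = False


def diffusion_embedding(affinity: np.ndarray, alpha: float = 0.5,
                        diffusion_time: float = 0.0,
                        n_components: int = 10) -> Embedding:
    """Anisotropic diffusion-map embedding of a non-negative affinity matrix.

    Negative affinities (possible after cosine similarity of signed profiles)
    are clipped to zero (clip rate logged).  W' = D^-a W D^-a is formed, the
    row-stochastic operator's leading nontrivial right eigenvectors are
    returned; with t = 0 component i is scaled by lambda_i / (1 - lambda_i),
    otherwise by lambda_i ** t.
    """
    W = np.asarray(affinity, float)
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    neg = W < 0
    if neg.any():
        logger.info("clipping %.2f%% negative affinities to 0",
                    100.0 * neg.mean())
        W = np.where(neg, 0.0, W)
    n_cc, cc_labels = connected_components(W > 0, directed=False)
    if n_cc > 1:
        sizes = np.bincount(cc_labels).tolist()
        raise ValueError(f"affinity graph is disconnected (component sizes {sizes})")

    d = W.sum(axis=1)
    d_alpha = d ** (-alpha)
    Wp = W * np.outer(d_alpha, d_alpha)
    dp = Wp.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dp)
    S = Wp * np.outer(inv_sqrt, inv_sqrt)  # symmetric conjugate of the operator
    S = (S + S.T) / 2.0
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # right eigenvectors of the row-stochastic operator
    psi = evecs * inv_sqrt[:, None]
    # drop the trivial constant eigenvector (eigenvalue 1)
    lam = evals[1:n_components + 1]
    comp = psi[:, 1:n_components + 1]
    # normalise each eigenvector against the stationary measure for stability
    comp = comp / np.linalg.norm(comp, axis=0)
    if diffusion_time == 0:
        scale = lam / (1.0 - lam)
    else:
        scale = lam ** diffusion_time
    return Embedding(comp * scale, lam, alpha, diffusion_time)


def group_template(fc_matrices: Sequence[np.ndarray], density: float = 0.10,
                   alpha: float = 0.5, diffusion_time: float = 0.0,
                   n_components: int = 10) -> Embedding:
    """Embed the entry-wise average of all subjects' network FC matrices."""
    if len(fc_matrices) < 2:
        raise ValueError("need at least 2 subjects for a group template")
    shapes = {m.shape for m in fc_matrices}
    if len(shapes) > 1:
        raise ValueError(f"subject FC shapes differ: {sorted(shapes)}")
    mean_fc = np.mean(np.stack(fc_matrices), axis=0)
    A = cosine_affinity(sparsify_rows(mean_fc, density))
    return diffusion_embedding(A, alpha, diffusion_time, n_components)


def procrustes_align(individual: Embedding, template: Embedding) -> Embedding:
    """Orthogonal (rotation/reflection, no scaling) alignment to the template.

    Columns are centred, the Frobenius-optimal orthogonal transform applied,
    and each aligned component's sign fixed so its correlation with the
    template component is non-negative.  A rank-deficient cross-product falls
    back to per-component sign matching (logged).
    """
    X = individual.components
    Y = template.components
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    M = Xc.T @ Yc
    if np.linalg.matrix_rank(M) < M.shape[0]:
        logger.warning("rank-deficient cross-product; falling back to sign matching")
        signs = np.sign(np.einsum("ij,ij->j", Xc, Yc))
        signs[signs == 0] = 1.0
        aligned = Xc * signs
    else:
        R, _ = orthogonal_procrustes(Xc, Yc)
        aligned = Xc @ R
    # sign convention: correlation with the template component non-negative
    signs = np.sign(np.einsum("ij,ij->j", aligned, Yc))
    signs[signs == 0] = 1.0
    aligned = aligned * signs
    return replace(individual, components=aligned, aligned=True)


def zscore_gradients(emb: Embedding) -> Embedding:
    """Standardise each aligned component to mean 0, SD 1 across voxels."""
    if not emb.aligned:
        raise ValueError("z-scoring expects an aligned embedding")
    G = emb.components
    sd = G.std(axis=0, ddof=0)
    if np.any(sd <= 0):
        bad = np.flatnonzero(sd <= 0).tolist()
        raise ValueError(f"zero-variance gradient component(s): {bad}")
    return replace(emb, components=(G - G.mean(axis=0)) / sd, zscored=True)


@dataclass
class DispersionMetric:
    """Euclidean distance structure of region centroids in gradient space."""

    regions: list
    centroid_distances: pd.DataFrame  # columns region_a, region_b, distance
    within_dispersion: pd.DataFrame  # columns region, dispersion


def gradient_dispersion(emb: Embedding, region_labels: Sequence,
                        n_components: int = 2) -> DispersionMetric:
    """Centroid-to-centroid distances (and within-region voxel dispersion) in
    the space of the first ``n_components`` gradients."""
    G = emb.components[:, :n_components]
    labels = np.asarray(region_labels)
    if len(labels) != G.shape[0]:
        raise ValueError("one region label per voxel required")
    regions = [r for r in pd.unique(labels)]
    centroids, kept, within = {}, [], []
    for r in regions:
        mask = labels == r
        if not mask.any():
            logger.warning("region %r has no voxels; excluded", r)
            continue
        c = G[mask].mean(axis=0)
        centroids[r] = c
        kept.append(r)
        within.append({"region": r,
                       "dispersion": float(np.linalg.norm(G[mask] - c, axis=1).mean())})
    if len(kept) < 2:
        raise ValueError("need at least 2 non-empty regions")
    rows = []
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            rows.append({
                "region_a": kept[a], "region_b": kept[b],
                "distance": float(np.linalg.norm(centroids[kept[a]] - centroids[kept[b]])),
            })
    return DispersionMetric(kept, pd.DataFrame(rows), pd.DataFrame(within))


def smooth_gradients(emb: Embedding) -> Embedding:
    """Spatial smoothing hook — a no-op here, where voxels carry no geometry."""
    return emb


def embed_subject(fc: np.ndarray, density: float = 0.10, alpha: float = 0.5,
                  diffusion_time: float = 0.0, n_components: int = 10) -> Embedding:
    """Convenience: sparsify -> cosine affinity -> diffusion embedding."""
    return diffusion_embedding(cosine_affinity(sparsify_rows(fc, density)),
                               alpha, diffusion_time, n_components)


def align_cohort(fc_matrices: Sequence[np.ndarray], density: float = 0.10,
                 alpha: float = 0.5, diffusion_time: float = 0.0,
                 n_components: int = 10) -> tuple[Embedding, list[Embedding]]:
    """Template + aligned, smoothed, z-scored individual gradient sets."""
    template = group_template(fc_matrices, density, alpha, diffusion_time,
                              n_components)
    aligned = []
    for fc in fc_matrices:
        emb = embed_subject(fc, density, alpha, diffusion_time, n_components)
        emb = zscore_gradients(smooth_gradients(procrustes_align(emb, template)))
        aligned.append(emb)
    return template, aligned
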