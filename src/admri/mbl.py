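"""Manifold-based learning features via Laplacian eigenmaps.

Subjects are compared through the intensity appearance of a region around
the hippocampus and amygdala after coarse alignment to the template (10 mm
B-spline control-point spacing): pairwise Euclidean distances between
z-scored ROI patches define a k-NN similarity graph with a Gaussian
kernel, and the generalized eigenproblem L y = lambda D y of its graph
Laplacian yields the embedding.  The first ``d`` nontrivial coordinates
(default 20) are the MBL features.  No operation here reads group labels —
the embedding is purely unsupervised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy import ndimage
from scipy.sparse.csgraph import connected_components

from .image import AMYGDALA, LEFT_HIPPO, RIGHT_HIPPO, Image3D, LabelMap
from .register import DeformationField, warp

logger = logging.getLogger(__name__)

DEFAULT_DIMENSIONS = 20  # first 20 manifold dimensions serve as features


def default_roi_mask(labelmap: LabelMap, dilate_vox: int = 4) -> np.ndarray:
    """Template-space ROI: hippocampus + amygdala labels dilated by 4 voxels."""
    m = labelmap.mask(LEFT_HIPPO, RIGHT_HIPPO, AMYGDALA)
    return ndimage.binary_dilation(m, iterations=dilate_vox)


def extract_roi_patch(
    subject: Image3D,
    template_roi_mask: np.ndarray,
    fld: DeformationField | None = None,
) -> np.ndarray:
    """Template-space ROI intensities sampled from the (warped) subject.

    ``fld`` is the coarse template->subject transform; None means the
    subject already lives on the template grid.  The patch is z-scored
    within the ROI, so global intensity scale and offset cancel.
    """
    if fld is not None:
        if fld.domain_shape != template_roi_mask.shape:
            raise ValueError("ROI mask does not match the field domain")
        data = warp(subject, fld).data
    else:
        if subject.shape != template_roi_mask.shape:
            raise ValueError("subject not on the template grid and no field given")
        data = subject.data
    v = data[template_roi_mask].astype(np.float64)
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 1e-12 else 1.0)


@dataclass
class SimilarityGraph:
    """Symmetric nonnegative k-NN weight matrix with Gaussian kernel."""

    W: np.ndarray
    k: int
    bandwidth: float

    def __post_init__(self) -> None:
        if not np.allclose(self.W, self.W.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(self.W) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.W < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def is_connected(self) -> bool:
        ncomp, _ = connected_components(self.W > 0, directed=False)
        return ncomp == 1

    def component_sizes(self) -> list[int]:
        ncomp, lab = connected_components(self.W > 0, directed=False)
        return [int((lab == c).sum()) for c in range(ncomp)]


def build_similarity_graph(
    patches: list[np.ndarray] | np.ndarray,
    k: int = 10,
    bandwidth: float | None = None,
) -> SimilarityGraph:
    """k-NN graph with Gaussian kernel on pairwise patch distances.

    ``W_ij = exp(-d_ij^2 / (2 sigma^2))`` if j is among i's k nearest
    neighbours or vice versa (symmetrized union), else 0.  The default
    bandwidth sigma is the median of the k-NN distances.  Identical patches
    at distance 0 get weight 1.
    """
    X = np.asarray(patches, dtype=np.float64)
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} patches, got {n}")
    sq = np.sum(X * X, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    d = np.sqrt(d2)
    order = np.argsort(d + np.eye(n) * (d.max() + 1), axis=1, kind="stable")
    knn = order[:, :k]
    neighbor = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    neighbor[rows, knn.ravel()] = True
    neighbor |= neighbor.T
    np.fill_diagonal(neighbor, False)
    if bandwidth is None:
        knn_d = np.take_along_axis(d, knn, axis=1)
        bandwidth = float(np.median(knn_d))
    sigma = max(bandwidth, 1e-12)
    W = np.where(neighbor, np.exp(-d2 / (2 * sigma**2)), 0.0)
    return SimilarityGraph(W, k, sigma)


@dataclass
class Embedding:
    """Laplacian-eigenmap coordinates; eigenvalues ascending, 0 excluded."""

    coords: np.ndarray  # (n, d)
    eigenvalues: np.ndarray  # (d,)

    def __post_init__(self) -> None:
        if np.any(self.eigenvalues < -1e-10):
            raise ValueError("generalized eigenvalues must be >= 0")


def laplacian_eigenmaps(graph: SimilarityGraph, d: int = DEFAULT_DIMENSIONS) -> Embedding:
    """Solve L y = lambda D y and return the d smallest nontrivial modes.

    L = D - W with degree matrix D.  The constant eigenvector (lambda = 0)
    is discarded; eigenvector signs are fixed so each column's
    largest-magnitude entry is positive.  Raises on a disconnected graph
    (naming component sizes) and for d >= n - 1.
    """
    n = graph.n
    if d >= n - 1:
        raise ValueError(f"d={d} must be < n-1={n - 1}")
    if not graph.is_connected():
        raise ValueError(
            f"similarity graph is disconnected (component sizes "
            f"{graph.component_sizes()}); increase k"
        )
    deg = graph.W.sum(axis=1)
    L = np.diag(deg) - graph.W
    vals, vecs = sla.eigh(L, np.diag(deg))
    # first eigenvalue is the trivial 0 of the constant vector
    vals = np.maximum(vals, 0.0)
    # renormalize so a uniform rescaling of W leaves coordinates unchanged
    vecs = vecs * np.sqrt(deg.sum() / n)
    coords = vecs[:, 1 : d + 1]
    ev = vals[1 : d + 1]
    flip = np.abs(coords).argmax(axis=0)
    signs = np.sign(coords[flip, np.arange(coords.shape[1])])
    signs[signs == 0] = 1.0
    return Embedding(coords * signs, ev)


def mbl_features(
    patches: list[np.ndarray] | np.ndarray,
    d: int = DEFAULT_DIMENSIONS,
    k: int = 10,
    scale_by_eigenvalue: bool = False,
) -> np.ndarray:
    """Full patch -> graph -> embedding pipeline; (n, d) feature matrix.

    If the k-NN graph is disconnected, k is increased (logged) until it
    connects.  ``scale_by_eigenvalue`` optionally scales coordinate j by
    1/sqrt(lambda_j) (off by default).
    """
    n = len(patches)
    kk = k
    graph = build_similarity_graph(patches, min(kk, n - 1))
    while not graph.is_connected():
        kk += 2
        if kk >= n:
            raise ValueError("graph cannot be connected even with k=n-1")
        logger.info("similarity graph disconnected; increasing k to %d", kk)
        graph = build_similarity_graph(patches, kk)
    emb = laplacian_eigenmaps(graph, d)
    coords = emb.coords
    if scale_by_eigenvalue:
        coords = coords / np.sqrt(np.maximum(emb.eigenvalues, 1e-12))
    return coords


def mbl_features_cohort(
    subjects,
    labelmap: LabelMap,
    fields: dict[str, DeformationField | None] | None = None,
    d: int = DEFAULT_DIMENSIONS,
    k: int = 10,
    dilate_vox: int = 4,
) -> dict[str, np.ndarray]:
    """MBL feature rows per subject id, from the shared transductive graph."""
    roi = default_roi_mask(labelmap, dilate_vox)
    patches = []
    for s in subjects:
        fld = None if fields is None else fields.get(s.id)
        patches.append(extract_roi_patch(s.image, roi, fld))
    feats = mbl_features(patches, d=d, k=k)
    return {s.id: feats[i] for i, s in enumerate(subjects)}
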