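"""Multi-atlas hippocampus segmentation and the hippocampal-volume feature.

Pipeline: rank a pool of atlas images by normalized cross-correlation with
the (affinely aligned) query, FFD-register the top-k atlases to the query,
average their propagated binary hippocampus masks into a spatial prior, and
refine with an EM Gaussian-mixture segmentation that uses the prior as a
voxelwise class prior.  The single HV feature is the bilateral hippocampal
volume in mm^3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import LEFT_HIPPO, RIGHT_HIPPO, Image3D, LabelMap
from .register import (
    AffineTransform,
    DeformationField,
    affine_align,
    ffd_register,
    warp,
)

logger = logging.getLogger(__name__)


@dataclass
class AtlasEntry:
    """An atlas image with aligned labels."""

    image: Image3D
    labels: LabelMap
    id: str

    def __post_init__(self) -> None:
        if self.image.shape != self.labels.shape:
            raise ValueError(f"atlas {self.id}: labels not aligned to image")

    @property
    def hippo_mask(self) -> np.ndarray:
        return self.labels.hippocampus_mask


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    return float(a @ b / ((np.linalg.norm(a) + 1e-12) * (np.linalg.norm(b) + 1e-12)))


def select_atlases(
    query: Image3D,
    pool: list[AtlasEntry],
    k: int,
    affine_iters: int = 20,
) -> list[AtlasEntry]:
    """Top-k atlases by NCC with the affinely aligned query; ties by id.

    Each atlas is affinely aligned to the query before scoring, so gross
    pose differences do not drive the ranking.
    """
    if not pool:
        raise ValueError("atlas pool is empty")
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    scored = []
    for entry in pool:
        if entry.image.shape == query.shape and np.array_equal(
            entry.image.data, query.data
        ):
            score = 1.0  # self-similarity is maximal, skip alignment noise
        else:
            aff = affine_align(entry.image, query, iters=affine_iters, levels=(4, 2))
            fld = DeformationField.identity_for(query, 10.0, aff)
            score = _ncc(warp(entry.image, fld).data, query.data)
        scored.append((-score, entry.id, entry))
    scored.sort(key=lambda x: (x[0], x[1]))
    return [e for _, _, e in scored[:k]]


@dataclass
class SpatialPrior:
    """Per-voxel probability of hippocampus, averaged over warped atlases."""

    prob: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.prob.min() < 0 or self.prob.max() > 1:
            raise ValueError("prior probabilities must lie in [0,1]")


def propagate_labels(
    query: Image3D,
    atlases: list[AtlasEntry],
    control_spacing_mm: float = 10.0,
    levels: tuple[int, ...] = (2,),
    iters: int = 25,
) -> SpatialPrior:
    """FFD-register each atlas to the query; average warped hippocampus masks.

    A failed registration drops that atlas with a warning; an error is
    raised only if every atlas fails.
    """
    if not atlases:
        raise ValueError("need at least one atlas")
    masks = []
    for entry in atlases:
        try:
            aff = affine_align(entry.image, query, iters=20, levels=(4, 2))
            fld = ffd_register(
                entry.image,
                query,
                control_spacing_mm,
                levels=levels,
                iters=iters,
                affine=aff,
            )
            m = warp(
                Image3D(entry.hippo_mask.astype(np.float64), entry.image.spacing),
                fld,
                "linear",
            ).data
            masks.append(np.clip(m, 0.0, 1.0))
        except Exception as exc:  # registration failure: drop, keep going
            logger.warning("atlas %s dropped: %s", entry.id, exc)
    if not masks:
        raise RuntimeError("label propagation failed for every atlas")
    return SpatialPrior(np.mean(masks, axis=0), query.spacing)


def em_segment(
    query: Image3D,
    prior: SpatialPrior,
    n_classes: int = 2,
    iters: int = 50,
    tol: float = 1e-5,
    prior_alpha: float = 0.9,
    support_dilation: int = 2,
    var_floor: float = 1e-3,
):
    """EM refinement of the hippocampus segmentation.

    A two-class Gaussian intensity mixture (hippocampus vs. surrounding
    tissue) is fitted inside the dilated prior support.  The voxelwise class
    prior is the convex blend ``alpha * prior + (1 - alpha) * uniform``,
    which prevents zero-probability lock-in.  E-step posteriors and M-step
    mean/variance updates run until the log-likelihood gain drops below
    ``tol``; returns (LabelMap, params) where params records class means,
    variances and the log-likelihood trace.
    """
    if n_classes != 2:
        raise NotImplementedError("volume feature uses a 2-class mixture")
    support = ndimage.binary_dilation(
        prior.prob > 0.1, iterations=support_dilation
    )
    if not support.any():
        raise ValueError("prior has empty support")
    x = query.data[support]
    p_h = prior_alpha * prior.prob[support] + (1 - prior_alpha) * 0.5
    pri = np.stack([p_h, 1.0 - p_h], axis=1)

    # moment-based init from the prior
    w0 = prior.prob[support]
    mu = np.array(
        [
            np.average(x, weights=w0 + 1e-9),
            np.average(x, weights=(1 - w0) + 1e-9),
        ]
    )
    var = np.array([np.var(x), np.var(x)]) + var_floor

    ll_trace = []
    resp = None
    for _ in range(iters):
        log_pdf = (
            -0.5 * np.log(2 * np.pi * var)[None, :]
            - 0.5 * (x[:, None] - mu[None, :]) ** 2 / var[None, :]
        )
        joint = np.log(pri + 1e-300) + log_pdf
        m = joint.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(joint - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(joint - lse[:, None])
        if ll_trace and ll - ll_trace[-1] < tol * abs(ll_trace[-1] + 1e-12):
            ll_trace.append(ll)
            break
        ll_trace.append(ll)
        nk = resp.sum(axis=0) + 1e-12
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        if (var < var_floor).any():
            logger.warning("variance floored at %g", var_floor)
            var = np.maximum(var, var_floor)

    labels = np.zeros(query.shape, dtype=np.int16)
    hippo = np.zeros(support.sum(), dtype=bool)
    if resp is not None:
        hippo = resp[:, 0] >= resp[:, 1]
    tmp = np.zeros(query.shape, dtype=bool)
    tmp[support] = hippo
    # split left/right by the midplane of the first axis for labelling only
    mid = query.shape[0] // 2
    idx = np.indices(query.shape)[0]
    labels[tmp & (idx < mid)] = LEFT_HIPPO
    labels[tmp & (idx >= mid)] = RIGHT_HIPPO
    params = {"means": mu, "variances": var, "loglik_trace": ll_trace}
    legend = {0: "background", LEFT_HIPPO: "left-hippocampus", RIGHT_HIPPO: "right-hippocampus"}
    return LabelMap(labels, query.spacing, query.origin, legend), params


def hippocampal_volume(labels: LabelMap) -> float:
    """Bilateral hippocampal volume in mm^3 (the HV feature).

    Voxel count times voxel volume, both sides summed; depends on labels
    only, never on image intensities.
    """
    mask = labels.hippocampus_mask
    if not mask.any():
        raise ValueError("no hippocampus label present")
    return float(mask.sum()) * labels.voxel_volume


def segment_hippocampus(
    query: Image3D,
    pool: list[AtlasEntry],
    k: int = 5,
    control_spacing_mm: float = 10.0,
    levels: tuple[int, ...] = (2,),
    iters: int = 25,
    prior_alpha: float = 0.9,
) -> tuple[LabelMap, float]:
    """Full multi-atlas pipeline: select, propagate, EM-refine, measure."""
    chosen = select_atlases(query, pool, k)
    prior = propagate_labels(query, chosen, control_spacing_mm, levels, iters)
    seg, _ = em_segment(query, prior, prior_alpha=prior_alpha)
    return seg, hippocampal_volume(seg)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)
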