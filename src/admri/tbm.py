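"""Multi-template tensor-based morphometry features.

Each template in a stratified library is FFD-registered to the study
subject (template fixed, subject moving), giving a Jacobian-determinant map
on the template grid; maps are then resampled through the stored
template-to-reference transforms into a common reference space and compared
voxelwise between groups.  The per-parcel feature is the p-value-weighted
mean Jacobian over "atrophic" voxels (significant and in the atrophy
direction), averaged over templates.  Under the fixed->moving convention a
planted subject shrinkage appears as J < 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .image import Image3D, LabelMap
from .phantom import Cohort, SubjectRecord
from .register import (
    DeformationField,
    affine_align,
    ffd_register,
    jacobian_map,
    warp,
)

logger = logging.getLogger(__name__)

CONTRASTS = {
    "HCvsAD": ("HC", "AD"),
    "HCvsPMCI": ("HC", "P-MCI"),
    "SMCIvsPMCI": ("S-MCI", "P-MCI"),
}


@dataclass
class TemplateLibrary:
    """Stratified template images with transforms into a mean reference."""

    templates: list[SubjectRecord]
    reference: Image3D
    template_to_reference: dict[str, DeformationField]
    reference_pass1: Image3D | None = None  # affine-only mean, pre-refinement

    def __len__(self) -> int:
        return len(self.templates)


def build_template_library(
    cohort: Cohort,
    n_hc: int = 10,
    n_mci: int = 10,
    n_ad: int = 10,
    seed: int = 0,
    registration: dict | None = None,
) -> TemplateLibrary:
    """Randomly draw a stratified template set and build its mean reference.

    MCI templates are drawn from S-MCI and P-MCI pooled.  The reference is
    the voxelwise mean of the affinely co-aligned templates, refined once by
    re-registering every template to the mean and re-averaging; the
    template-to-reference FFDs from the refinement pass are stored for
    normalizing subject Jacobian maps.
    """
    reg = {"control_spacing_mm": 10.0, "levels": (2,), "iters": 20}
    reg.update(registration or {})
    rng = np.random.default_rng(seed)
    chosen: list[SubjectRecord] = []
    for want, groups in ((n_hc, ("HC",)), (n_mci, ("S-MCI", "P-MCI")), (n_ad, ("AD",))):
        avail = sorted(cohort.by_group(*groups), key=lambda s: s.id)
        if len(avail) < want:
            raise ValueError(
                f"cohort has only {len(avail)} subjects in {groups}, need {want}"
            )
        idx = rng.choice(len(avail), size=want, replace=False)
        chosen.extend(avail[i] for i in sorted(idx))

    geom = chosen[0].image
    # pass 1: affine co-alignment to the first template, voxelwise mean
    aligned = []
    for s in chosen:
        if s is chosen[0]:
            aligned.append(s.image.data)
        else:
            aff = affine_align(s.image, geom, iters=20, levels=(4, 2))
            fld = DeformationField.identity_for(geom, reg["control_spacing_mm"], aff)
            aligned.append(warp(s.image, fld).data)
    reference = Image3D(np.mean(aligned, axis=0), geom.spacing, geom.origin)

    # refinement: non-rigidly re-register to the mean, re-average
    t2r: dict[str, DeformationField] = {}
    refined = []
    for s in chosen:
        fld = ffd_register(
            s.image,
            reference,
            reg["control_spacing_mm"],
            levels=reg["levels"],
            iters=reg["iters"],
            affine=affine_align(s.image, reference, iters=20, levels=(4, 2)),
        )
        t2r[s.id] = fld
        refined.append(warp(s.image, fld).data)
    pass1 = reference
    reference = Image3D(np.mean(refined, axis=0), geom.spacing, geom.origin)
    return TemplateLibrary(chosen, reference, t2r, pass1)


def subject_jacobians(
    subject: SubjectRecord,
    library: TemplateLibrary,
    registration: dict | None = None,
) -> dict[str, np.ndarray]:
    """Per-template Jacobian maps of one subject, in reference space.

    For each template: FFD-register template (fixed) -> subject (moving),
    take the analytic Jacobian determinant on the template grid, and pull it
    back into reference space through the stored template-to-reference
    transform.  A failed registration flags that template's map as missing
    (excluded), with a warning.
    """
    reg = {"control_spacing_mm": 10.0, "levels": (2,), "iters": 20}
    reg.update(registration or {})
    maps: dict[str, np.ndarray] = {}
    for tmpl in library.templates:
        try:
            if subject.id == tmpl.id:
                fld = DeformationField.identity_for(
                    tmpl.image, reg["control_spacing_mm"]
                )
            else:
                aff = affine_align(subject.image, tmpl.image, iters=20, levels=(4, 2))
                fld = ffd_register(
                    subject.image,
                    tmpl.image,
                    reg["control_spacing_mm"],
                    levels=reg["levels"],
                    iters=reg["iters"],
                    affine=aff,
                )
            jmap = jacobian_map(fld).data
            t2r = library.template_to_reference[tmpl.id]
            jref = warp(Image3D(jmap, tmpl.image.spacing), t2r, "linear", pad_value=1.0)
            maps[tmpl.id] = jref.data
        except Exception as exc:
            logger.warning("template %s: Jacobian map missing (%s)", tmpl.id, exc)
    return maps


@dataclass
class StatMap:
    """Voxelwise two-sample t / p maps for a named group contrast.

    ``mean_diff`` is mean(A) - mean(B) per voxel, used for the atrophy
    direction test; voxels outside the mask or with zero pooled variance
    are flagged in ``valid`` (never zero-filled).
    """

    t: np.ndarray
    p: np.ndarray
    mean_diff: np.ndarray
    valid: np.ndarray
    contrast: str
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        pv = self.p[self.valid]
        if pv.size and (pv.min() <= 0 or pv.max() > 1):
            raise ValueError("p-values must lie in (0, 1]")


def voxelwise_ttest(
    maps_a: list[np.ndarray],
    maps_b: list[np.ndarray],
    mask: np.ndarray,
    contrast: str = "",
) -> StatMap:
    """Unequal-variance two-sample t-test at every voxel within the mask."""
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least 2 maps per group")
    A = np.stack(maps_a)
    B = np.stack(maps_b)
    t, p = stats.ttest_ind(A, B, axis=0, equal_var=False)
    valid = mask & np.isfinite(t) & np.isfinite(p)
    t = np.where(valid, t, 0.0)
    p = np.where(valid, p, 1.0)
    # exact zero-difference voxels give p = 1, keep them valid but capped
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return StatMap(
        t=t,
        p=p,
        mean_diff=A.mean(axis=0) - B.mean(axis=0),
        valid=valid,
        contrast=contrast,
        n_a=len(maps_a),
        n_b=len(maps_b),
    )


@dataclass
class StatROI:
    """Voxels passing the significance-and-direction criterion, per parcel."""

    parcel: int
    member_voxels: np.ndarray  # boolean grid
    weights: np.ndarray  # -log10 p on members, 0 elsewhere
    empty: bool = False


def build_stat_rois(
    statmap: StatMap,
    parcellation: np.ndarray,
    alpha: float = 0.05,
    atrophy_sign: float = -1.0,
) -> list[StatROI]:
    """Per-parcel atrophic-voxel sets from a statistical map.

    Member voxels have p < alpha AND a mean difference in the atrophy
    direction: with contrast (less-affected A, more-affected B) and J < 1
    meaning shrinkage, atrophy shows as mean(A) - mean(B) > 0, i.e.
    ``sign(mean_diff) == -atrophy_sign``.  Weights are -log10(p).
    """
    sig = statmap.valid & (statmap.p < alpha)
    if atrophy_sign < 0:
        sig &= statmap.mean_diff > 0
    else:
        sig &= statmap.mean_diff < 0
    rois = []
    for parcel in range(1, int(parcellation.max()) + 1):
        pm = parcellation == parcel
        members = pm & sig
        w = np.where(members, -np.log10(statmap.p), 0.0)
        rois.append(StatROI(parcel, members, w, empty=not members.any()))
    return rois


def roi_features_single(
    jac_map: np.ndarray,
    rois: list[StatROI],
    parcellation: np.ndarray,
) -> np.ndarray:
    """p-weighted mean Jacobian per parcel: sum(w J) / sum(w) over members.

    An empty parcel falls back to the unweighted parcel mean (flagged via a
    debug log), so the feature vector always has one value per parcel.
    """
    out = np.empty(len(rois))
    for i, roi in enumerate(rois):
        if roi.empty:
            pm = parcellation == roi.parcel
            out[i] = jac_map[pm].mean() if pm.any() else 1.0
        else:
            w = roi.weights[roi.member_voxels]
            out[i] = float(np.sum(w * jac_map[roi.member_voxels]) / np.sum(w))
    return out


def stat_roi_features(
    subject_maps: dict[str, np.ndarray],
    statmaps: dict[str, StatMap] | StatMap,
    parcellation: np.ndarray,
    alpha: float = 0.05,
) -> np.ndarray:
    """TBM feature vector for one subject: per-template features, averaged.

    ``statmaps`` is either one StatMap shared by all templates or a dict
    keyed like ``subject_maps`` (per-template statistics).  Raises if every
    parcel is empty in every template (advice: raise alpha).
    """
    feats = []
    all_empty = True
    for tid, jmap in subject_maps.items():
        sm = statmaps if isinstance(statmaps, StatMap) else statmaps[tid]
        rois = build_stat_rois(sm, parcellation, alpha)
        if not all(r.empty for r in rois):
            all_empty = False
        feats.append(roi_features_single(jmap, rois, parcellation))
    if not feats:
        raise ValueError("subject has no Jacobian maps")
    if all_empty:
        raise ValueError(
            f"no voxel passes alpha={alpha} in any parcel; use a larger alpha"
        )
    return np.mean(feats, axis=0)


def tbm_features_cohort(
    subjects: list[SubjectRecord],
    stat_subjects_maps: dict[str, dict[str, np.ndarray]],
    subject_maps: dict[str, dict[str, np.ndarray]],
    groups: tuple[str, str],
    subjects_by_id: dict[str, str],
    parcellation: np.ndarray,
    mask: np.ndarray,
    alpha: float = 0.05,
    contrast: str = "",
):
    """Cohort-level TBM features with ROI statistics from held-out subjects.

    ``stat_subjects_maps`` maps ROI-building subject id -> {template id ->
    Jacobian map}; those subjects must be disjoint from ``subjects`` (the
    featurized set) — enforced upstream by the protocol driver, asserted
    here.
    """
    overlap = {s.id for s in subjects} & set(stat_subjects_maps)
    if overlap:
        raise ValueError(f"ROI subjects overlap featurized subjects: {sorted(overlap)}")
    ga, gb = groups
    mean_maps_a = [
        np.mean(list(m.values()), axis=0)
        for sid, m in stat_subjects_maps.items()
        if subjects_by_id[sid] == ga and m
    ]
    mean_maps_b = [
        np.mean(list(m.values()), axis=0)
        for sid, m in stat_subjects_maps.items()
        if subjects_by_id[sid] == gb and m
    ]
    sm = voxelwise_ttest(mean_maps_a, mean_maps_b, mask, contrast)
    feats = {}
    for s in subjects:
        feats[s.id] = stat_roi_features(subject_maps[s.id], sm, parcellation, alpha)
    return feats, sm
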