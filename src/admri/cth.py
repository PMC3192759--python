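"""Simplified cortical thickness: Laplace-linked surface pairs on the ribbon.

The full deformable-mesh machinery of surface pipelines is replaced by a
voxel-domain equivalent that preserves the t-link *definition* of
thickness: solve Laplace's equation over the GM ribbon (inner WM/GM
boundary held at 0, outer GM/CSF boundary at 1), trace the gradient
streamline from every inner-boundary node to the outer boundary, and take
the Euclidean distance between the linked endpoints as the node thickness,
computed in each subject's native space.  Node-level values are smoothed by
heat diffusion on the surface-node adjacency graph with an FWHM-matched
kernel, and pooled into per-parcel statistical-ROI features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse, stats
from scipy.spatial import cKDTree

from .image import CSF, GM, WM, LabelMap
from .phantom import SubjectRecord

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class CorticalSurfacePair:
    """Linked inner (WM/GM) and outer (GM/CSF) boundary node sets, mm coords.

    ``inner[i]`` and ``outer[i]`` are 1:1 linked; ``valid[i]`` is False for
    nodes whose streamline failed to reach the outer boundary (ribbon hole).
    """

    inner: np.ndarray  # (n, 3) mm
    outer: np.ndarray  # (n, 3) mm
    parcel: np.ndarray  # (n,) parcel id per node
    valid: np.ndarray  # (n,) bool

    def __post_init__(self) -> None:
        if self.inner.shape != self.outer.shape:
            raise ValueError("inner and outer node sets must be linked 1:1")

    def __len__(self) -> int:
        return self.inner.shape[0]


def _solve_laplace(gm: np.ndarray, wm: np.ndarray, outer: np.ndarray, iters: int = 400):
    """Jacobi relaxation of Laplace's equation on the GM ribbon (0=inner, 1=outer)."""
    u = np.zeros(gm.shape)
    u[outer] = 1.0
    u[gm] = 0.5
    k = np.zeros((3, 3, 3))
    k[1, 1, 0] = k[1, 1, 2] = k[1, 0, 1] = k[1, 2, 1] = k[0, 1, 1] = k[2, 1, 1] = 1 / 6
    for _ in range(iters):
        u_new = ndimage.convolve(u, k, mode="nearest")
        u[gm] = u_new[gm]
        u[wm] = 0.0
        u[outer] = 1.0
    return u


def extract_surface_pair(
    labels: LabelMap,
    max_steps: int = 400,
    step_vox: float = 0.2,
) -> CorticalSurfacePair:
    """Inner-surface nodes linked to the outer boundary along Laplace streamlines.

    Inner nodes are GM voxels 6-adjacent to WM (voxel centers, mm).  From
    each node the normalized gradient of the Laplace solution is integrated
    until the streamline leaves GM into CSF/background; the exit point is
    the linked outer node.  Nodes whose streamline stalls are flagged
    invalid (missing thickness); if more than half are flagged the ribbon
    is considered broken and an error is raised.
    """
    lab = labels.labels
    gm = lab == GM
    wm_like = lab >= WM  # WM core plus subcortical structures
    outer = (lab == CSF) | (lab == 0)
    if not gm.any():
        raise ValueError("no GM ribbon present")
    spacing = np.asarray(labels.spacing)

    u = _solve_laplace(gm, wm_like, outer)
    # gradient of u, in voxel coordinates
    gu = np.stack(np.gradient(u), axis=0)

    # inner nodes: GM voxels with a 6-neighbour in WM-like tissue
    st = ndimage.generate_binary_structure(3, 1)
    inner_mask = gm & ndimage.binary_dilation(wm_like, structure=st)
    nodes = np.argwhere(inner_mask).astype(np.float64)
    n = nodes.shape[0]
    # smoothed indicators give sub-voxel 0.5-level boundary localization
    wm_f = ndimage.gaussian_filter(wm_like.astype(np.float64), 0.7)
    outer_f = ndimage.gaussian_filter(outer.astype(np.float64), 0.7)

    def _interp(vol, p):
        return ndimage.map_coordinates(vol, p.T, order=1, mode="nearest")

    def _unit_grad(p):
        g = np.stack([_interp(gu[a], p) for a in range(3)], axis=1)
        norm = np.linalg.norm(g, axis=1)
        ok = norm > 1e-8
        g[ok] /= norm[ok][:, None]
        g[~ok] = 0.0
        return g, ok

    # sub-voxel start: back-trace each node to the 0.5-level of the WM mask
    g0, _ = _unit_grad(nodes)
    start = nodes.copy()
    f_prev = _interp(wm_f, start)
    moved = np.zeros(n, dtype=bool)
    for _ in range(int(1.5 / step_vox)):
        cand = start - step_vox * g0
        f_cur = _interp(wm_f, cand)
        cross = (~moved) & (f_cur >= 0.5)
        if cross.any():
            frac = (0.5 - f_prev[cross]) / np.maximum(f_cur[cross] - f_prev[cross], 1e-9)
            start[cross] -= (step_vox * np.clip(frac, 0, 1))[:, None] * g0[cross]
            moved[cross] = True
        adv = ~moved
        start[adv] = cand[adv]
        f_prev = np.where(moved, f_prev, f_cur)
        if moved.all():
            break
    nodes = np.where(moved[:, None], start, nodes)

    pos = nodes.copy()
    alive = np.ones(n, dtype=bool)
    done = np.zeros(n, dtype=bool)
    o_prev = _interp(outer_f, pos)
    for _ in range(max_steps):
        if not alive.any():
            break
        p = pos[alive]
        g, ok = _unit_grad(p)
        p_new = p + step_vox * g
        o_cur = _interp(outer_f, p_new)
        crossed = o_cur >= 0.5
        idx = np.where(alive)[0]
        if crossed.any():
            op = o_prev[idx[crossed]]
            frac = (0.5 - op) / np.maximum(o_cur[crossed] - op, 1e-9)
            p_new[crossed] = p[crossed] + (step_vox * np.clip(frac, 0, 1))[:, None] * g[crossed]
            done[idx[crossed]] = True
            alive[idx[crossed]] = False
        pos[idx] = p_new
        o_prev[idx] = o_cur
        alive[idx[~ok & ~crossed]] = False  # stalled in a flat region

    valid = done
    frac_bad = 1.0 - valid.mean() if n else 1.0
    if frac_bad > 0.5:
        raise ValueError(
            f"ribbon broken: {frac_bad:.0%} of streamlines failed to reach the outer boundary"
        )
    if frac_bad > 0:
        logger.warning("%d/%d surface nodes flagged missing", int(n - valid.sum()), n)

    parcels = labels.parcels
    if parcels is None:
        parcel_ids = np.zeros(n, dtype=int)
    else:
        parcel_ids = parcels[
            tuple(np.round(nodes).astype(int).T)
        ].astype(int)
        # inherit from nearest labelled parcel where the node sits on 0
        missing = parcel_ids == 0
        if missing.any():
            src = np.argwhere(parcels > 0)
            tree = cKDTree(src)
            _, j = tree.query(nodes[missing])
            parcel_ids[missing] = parcels[tuple(src[j].T)]
    return CorticalSurfacePair(
        inner=nodes * spacing,
        outer=pos * spacing,
        parcel=parcel_ids,
        valid=valid,
    )


def tlink_thickness(pair: CorticalSurfacePair) -> np.ndarray:
    """Euclidean distance between linked nodes (mm); NaN where flagged."""
    t = np.linalg.norm(pair.outer - pair.inner, axis=1)
    t[~pair.valid] = np.nan
    return t


def _adjacency(pair: CorticalSurfacePair, radius_mm: float = 2.5) -> sparse.csr_matrix:
    tree = cKDTree(pair.inner)
    pairs = tree.query_pairs(radius_mm, output_type="ndarray")
    if pairs.size == 0:
        return sparse.csr_matrix((len(pair), len(pair)))
    d = np.linalg.norm(pair.inner[pairs[:, 0]] - pair.inner[pairs[:, 1]], axis=1)
    w = 1.0 / np.maximum(d, 1e-6) ** 2
    i = np.concatenate([pairs[:, 0], pairs[:, 1]])
    j = np.concatenate([pairs[:, 1], pairs[:, 0]])
    W = sparse.csr_matrix(
        (np.concatenate([w, w]), (i, j)), shape=(len(pair), len(pair))
    )
    return W


def smooth_thickness(
    pair: CorticalSurfacePair,
    values: np.ndarray,
    fwhm_mm: float = 20.0,
    neighbor_radius_mm: float = 2.5,
) -> np.ndarray:
    """Heat-kernel smoothing on the surface-node graph.

    Explicit diffusion steps with edge weights 1/d^2 approximate the heat
    equation on the surface; total diffusion time is sigma^2 / 2 with
    sigma = fwhm / sqrt(8 ln 2), so the kernel width matches the requested
    geodesic FWHM.  The operator is symmetric, hence mass-preserving:
    constant input stays constant and the global mean is unchanged.
    fwhm = 0 is the identity.  NaN (missing) entries are ignored and stay
    NaN.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return values.copy()
    sigma = fwhm_mm * FWHM_TO_SIGMA
    W = _adjacency(pair, neighbor_radius_mm)
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sparse.diags(deg) - W
    # effective diffusivity of the graph walk: per unit time the variance
    # grows by mean_i sum_j w_ij l_ij^2 spread over the ~3 dimensions of the
    # voxel-shell node cloud; rescale time so the kernel matches sigma
    ii, jj = W.nonzero()
    l2 = np.sum((pair.inner[ii] - pair.inner[jj]) ** 2, axis=1)
    msd = float(np.bincount(ii, weights=np.asarray(W[ii, jj]).ravel() * l2,
                            minlength=len(pair)).mean())
    kappa = max(msd / 4.0, 1e-12)  # 2 * dim on the (approximately 2D) surface
    t_total = sigma**2 / 2.0 / kappa
    tau = 0.9 / max(deg.max(), 1e-12)
    n_steps = max(int(np.ceil(t_total / tau)), 1)
    tau = t_total / n_steps

    v = values.copy()
    miss = ~np.isfinite(v)
    v[miss] = np.nanmean(values) if np.isfinite(values).any() else 0.0
    for _ in range(n_steps):
        v = v - tau * (L @ v)
    v[miss] = np.nan
    return v


def thickness_on_reference(
    pair: CorticalSurfacePair,
    values: np.ndarray,
    reference_pair: CorticalSurfacePair,
) -> np.ndarray:
    """Resample node thickness onto the reference (template) node set.

    Nearest-inner-node matching in (already coarsely aligned) mm space —
    the phantom cohort shares the template grid up to the small random
    deformation, so nearest-node matching stands in for surface
    registration.
    """
    tree = cKDTree(pair.inner)
    _, j = tree.query(reference_pair.inner)
    return values[j]


def cth_stat_roi_features(
    thickness_by_id: dict[str, np.ndarray],
    group_by_id: dict[str, str],
    groups: tuple[str, str],
    featurize_ids: list[str],
    stat_ids: list[str],
    parcel_per_node: np.ndarray,
    alpha: float = 0.05,
):
    """Statistical-ROI mean-thickness features on a common node set.

    Node-wise two-sample t-tests between the contrast groups are computed
    from ``stat_ids`` only (must be disjoint from ``featurize_ids``); for
    every parcel with any node at p < alpha and thinner in the
    more-affected group, the feature is the plain mean thickness over those
    nodes.  Returns ({id: feature vector}, selected parcel ids).  The
    feature count is contrast- and data-dependent.  alpha = 1 degenerates
    to plain parcel means over all parcels.
    """
    overlap = set(featurize_ids) & set(stat_ids)
    if overlap:
        raise ValueError(f"ROI subjects overlap featurized subjects: {sorted(overlap)}")
    ga, gb = groups
    A = np.stack([thickness_by_id[i] for i in stat_ids if group_by_id[i] == ga])
    B = np.stack([thickness_by_id[i] for i in stat_ids if group_by_id[i] == gb])
    if len(A) < 2 or len(B) < 2:
        raise ValueError("need >= 2 ROI subjects per group")
    t, p = stats.ttest_ind(A, B, axis=0, equal_var=False, nan_policy="omit")
    p = np.where(np.isfinite(p), p, 1.0)
    if alpha >= 1.0:
        sig = np.ones(p.shape, dtype=bool)
    else:
        # thinning in the more-affected group: mean(A) > mean(B)
        sig = (p < alpha) & (np.nanmean(A, axis=0) > np.nanmean(B, axis=0))
    parcels = sorted(set(parcel_per_node[sig].tolist()) - {0})
    if not parcels:
        raise ValueError(f"no node passes alpha={alpha}; use a larger alpha")
    feats = {}
    for sid in featurize_ids:
        v = thickness_by_id[sid]
        row = []
        for parc in parcels:
            m = sig & (parcel_per_node == parc)
            vm = v[m]
            vm = vm[np.isfinite(vm)]
            row.append(float(vm.mean()) if vm.size else np.nan)
        feats[sid] = np.asarray(row)
    return feats, parcels


def flag_missing_cth(subject: SubjectRecord, failed: bool | None = None) -> SubjectRecord:
    """Mark a subject's CTH features as missing (never imputed here).

    ``failed`` overrides the phantom flag; by default the existing
    ``cth_missing`` flag (surface extraction failure or planted missingness)
    is kept.  Any stored CTH features are replaced by NaN.
    """
    if failed is not None:
        subject.cth_missing = bool(failed)
    if subject.cth_missing and "CTH" in subject.features:
        subject.features["CTH"] = subject.features["CTH"] * np.nan
    return subject
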