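"""Synthetic 3D brain-phantom cohorts with analytic ground truth.

The phantom is deliberately geometric rather than anatomical: nested
ellipsoidal CSF / GM / WM compartments with a cortical ribbon of known
thickness, two hippocampus-like ellipsoids with an adjacent amygdala
region, a deep "atrophy nucleus" that carries planted regional volume
change, and a deterministic parcellation of brain tissue.  That is exactly
the structure the downstream feature extractors need (tissue contrast, a
hippocampal pair, a ribbon, parcels) while keeping generation fast and the
planted effects analytic.

Disease effects are planted monotonically over the severity gradient
HC -> S-MCI -> P-MCI -> AD: multiplicative hippocampal volume reduction,
cortical-ribbon thinning in mm, and a regional log-Jacobian shift of the
atrophy nucleus.  Normal ageing and sex effects are applied to ALL groups
with identical coefficients, so that control-trained residualization has
exactly the "normal, not disease-related" variation to remove.  Every
subject additionally receives a random smooth B-spline deformation, a
smooth multiplicative bias field and additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .image import (
    AMYGDALA,
    ATROPHY_NUCLEUS,
    BACKGROUND,
    CSF,
    GM,
    LEFT_HIPPO,
    PARCEL_OFFSET,
    RIGHT_HIPPO,
    WM,
    ANATOMY_LEGEND,
    Image3D,
    LabelMap,
)
from .register import DeformationField, random_smooth_field, warp, warp_labels

GROUPS = ("HC", "S-MCI", "P-MCI", "AD")
REFERENCE_AGE = 75.0

_TISSUE_INTENSITY = {
    BACKGROUND: 0.0,
    CSF: 40.0,
    GM: 100.0,
    WM: 160.0,
    LEFT_HIPPO: 105.0,
    RIGHT_HIPPO: 105.0,
    AMYGDALA: 130.0,
    ATROPHY_NUCLEUS: 70.0,
}

# structure geometry as fractions of the smallest image extent
_FRAC = {
    "brain_out": 0.44,
    "gm_out": 0.40,
    "hippo_center": (0.145, -0.06, -0.04),
    "hippo_semi": (0.104, 0.073, 0.0625),
    "amy_semi": (0.068, 0.052, 0.046),
    "nucleus_center": (0.0, 0.10, 0.11),
    "nucleus_semi": (0.16, 0.12, 0.12),
}


@dataclass
class EffectSpec:
    """Planted group, covariate and nuisance effects for the phantom cohort.

    Group effects are defined relative to HC (the HC entries are the
    identity).  ``hippo_factor`` is multiplicative on bilateral hippocampal
    volume; ``thickness_offset_mm`` is additive on ribbon thickness;
    ``regional_logj_shift`` shifts the log-volume of the atrophy nucleus
    (factor ``exp(shift)``), which is what TBM should recover as Jacobian
    values below 1.
    """

    hippo_factor: dict[str, float] = field(
        default_factory=lambda: {"HC": 1.0, "S-MCI": 0.93, "P-MCI": 0.88, "AD": 0.85}
    )
    thickness_offset_mm: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "S-MCI": -0.15, "P-MCI": -0.3, "AD": -0.5}
    )
    regional_logj_shift: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.0, "S-MCI": -0.08, "P-MCI": -0.15, "AD": -0.22}
    )
    age_slope_hv_per_year: float = -0.003  # fractional volume / year
    age_slope_cth_mm_per_year: float = -0.01
    sex_hv_factor_m: float = 1.05
    sex_cth_offset_mm_m: float = 0.05
    noise_sd: float = 5.0
    bias_amplitude: float = 0.05
    deform_amplitude_mm: float = 0.8
    missing_cth_fraction: float = 0.13
    monotone: bool = True

    def __post_init__(self) -> None:
        for g in GROUPS:
            if self.hippo_factor[g] <= 0:
                raise ValueError(f"hippo factor for {g} must be > 0")
        if self.hippo_factor["HC"] != 1.0 or self.thickness_offset_mm["HC"] != 0.0:
            raise ValueError("HC effects must be the identity")
        if not 0.0 <= self.missing_cth_fraction <= 1.0:
            raise ValueError("missing_cth_fraction must lie in [0,1]")
        if self.monotone:
            for name, d, sign in (
                ("hippo_factor", self.hippo_factor, 1),
                ("thickness_offset_mm", self.thickness_offset_mm, 1),
                ("regional_logj_shift", self.regional_logj_shift, 1),
            ):
                vals = [d[g] for g in GROUPS]
                if any(a < b - 1e-12 for a, b in zip(vals, vals[1:])):
                    raise ValueError(f"{name} must be monotone HC >= ... >= AD")

    @classmethod
    def identity(cls, **overrides) -> "EffectSpec":
        base = dict(
            hippo_factor={g: 1.0 for g in GROUPS},
            thickness_offset_mm={g: 0.0 for g in GROUPS},
            regional_logj_shift={g: 0.0 for g in GROUPS},
            age_slope_hv_per_year=0.0,
            age_slope_cth_mm_per_year=0.0,
            sex_hv_factor_m=1.0,
            sex_cth_offset_mm_m=0.0,
            noise_sd=0.0,
            bias_amplitude=0.0,
            missing_cth_fraction=0.0,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class GroundTruth:
    """Planted per-subject values, recoverable without any pipeline stage."""

    hippo_volume_mm3: float  # planted bilateral volume (analytic target)
    hippo_volume_voxel_mm3: float  # counted from the synthesized label map
    cortical_thickness_mm: float
    atrophy_region_mask: np.ndarray  # template-space nucleus mask
    deformation: DeformationField | None
    hippo_factor: float = 1.0
    regional_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.hippo_volume_mm3 <= 0:
            raise ValueError("planted hippocampal volume must be > 0")


@dataclass
class SubjectRecord:
    id: str
    group: str
    age: float
    sex: str
    image: Image3D | None = None
    labels: LabelMap | None = None
    truth: GroundTruth | None = None
    features: dict[str, pd.Series] = field(default_factory=dict)
    cth_missing: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    template: Image3D | None = None
    labelmap: LabelMap | None = None
    effects: EffectSpec | None = None

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.subjects]

    def by_group(self, *groups: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group in groups]

    def get(self, sid: str) -> SubjectRecord:
        for s in self.subjects:
            if s.id == sid:
                return s
        raise KeyError(sid)

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "cth_missing": [s.cth_missing for s in self.subjects],
            }
        ).set_index("id")


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------


def _ellipsoid_rho(coords_mm: np.ndarray, center: np.ndarray, semi: np.ndarray):
    """Normalized ellipsoid coordinate; <= 1 inside."""
    d = (coords_mm - center.reshape(3, 1, 1, 1)) / semi.reshape(3, 1, 1, 1)
    return np.sqrt((d * d).sum(axis=0))


def _geometry(shape, spacing, gm_thickness_mm, hippo_scale, nucleus_scale):
    ext = min(n * s for n, s in zip(shape, spacing))
    center = (np.asarray(shape) - 1) * np.asarray(spacing) / 2.0
    g: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    brain = ext * np.array([_FRAC["brain_out"]] * 3) * np.array([1.0, 0.95, 0.9])
    gm_out = ext * np.array([_FRAC["gm_out"]] * 3) * np.array([1.0, 0.95, 0.9])
    wm_out = gm_out - 3.0  # WM envelope fixed; the ribbon thins outward-in
    gm_out_subject = wm_out + gm_thickness_mm
    g["brain"] = (center, brain)
    g["gm"] = (center, np.minimum(gm_out_subject, brain - 0.5))
    g["wm"] = (center, wm_out)
    hs = np.asarray(_FRAC["hippo_semi"]) * ext * hippo_scale ** (1.0 / 3.0)
    hc = np.asarray(_FRAC["hippo_center"]) * ext
    g["hippo_L"] = (center + hc * np.array([-1, 1, 1]), hs)
    g["hippo_R"] = (center + hc, hs)
    asemi = np.asarray(_FRAC["amy_semi"]) * ext
    aoff = hc + np.array([0.0, -(hs[1] + asemi[1]) * 0.8, 0.0])
    g["amy_L"] = (center + aoff * np.array([-1, 1, 1]), asemi)
    g["amy_R"] = (center + aoff, asemi)
    g["nucleus"] = (
        center + np.asarray(_FRAC["nucleus_center"]) * ext,
        np.asarray(_FRAC["nucleus_semi"]) * ext * nucleus_scale ** (1.0 / 3.0),
    )
    return g


def _render_labels(shape, spacing, geo, targets: dict[str, float] | None = None) -> np.ndarray:
    """Voxelize the phantom geometry.

    ``targets`` optionally gives a structure an exact target voxel count:
    the ellipsoid field is then thresholded at the k-th smallest normalized
    radius, realizing planted volume factors to +/- half a voxel even when
    the analytic scaling is below the grid resolution.
    """
    targets = targets or {}
    coords = np.indices(shape).astype(np.float64) * np.asarray(spacing).reshape(
        3, 1, 1, 1
    )
    labels = np.zeros(shape, dtype=np.int16)
    order = [
        ("brain", CSF),
        ("gm", GM),
        ("wm", WM),
    ]
    rho = {}
    for name, code in order:
        c, s = geo[name]
        rho[name] = _ellipsoid_rho(coords, c, s)
        labels[rho[name] <= 1.0] = code
    inside_wm = rho["wm"] <= 1.0
    # amygdala first: the hippocampi own any overlap with their neighbour
    for name, code in (
        ("amy_L", AMYGDALA),
        ("amy_R", AMYGDALA),
        ("hippo_L", LEFT_HIPPO),
        ("hippo_R", RIGHT_HIPPO),
        ("nucleus", ATROPHY_NUCLEUS),
    ):
        c, s = geo[name]
        r = _ellipsoid_rho(coords, c, s)
        if name in targets:
            k = int(round(targets[name]))
            if k < 1:
                raise ValueError(f"structure {name!r}: target volume below 1 voxel")
            thr = np.partition(r.ravel(), k - 1)[k - 1]
            m = r <= thr
        else:
            m = r <= 1.0
        if not m.any():
            raise ValueError(f"image too small: structure {name!r} has no voxels")
        if not inside_wm[m].all():
            raise ValueError(
                f"image too small: structure {name!r} does not fit inside WM"
            )
        labels[m] = code
    return labels


def _render_intensity(labels: np.ndarray, smooth_vox: float = 0.6) -> np.ndarray:
    img = np.zeros(labels.shape, dtype=np.float64)
    for code, val in _TISSUE_INTENSITY.items():
        img[labels == code] = val
    return ndimage.gaussian_filter(img, smooth_vox)


def _parcellate(labels: np.ndarray, spacing, n_parcels: int, seed: int) -> np.ndarray:
    """Deterministic compact partition of brain tissue into n_parcels parcels."""
    from sklearn.cluster import KMeans

    tissue = labels >= GM
    pts = np.argwhere(tissue).astype(np.float64) * np.asarray(spacing)
    km = KMeans(n_clusters=n_parcels, n_init=1, random_state=int(seed) % (2**31))
    assign = km.fit_predict(pts)
    parcels = np.zeros(labels.shape, dtype=np.int16)
    parcels[tissue] = assign + 1
    return parcels


def make_template(
    shape: tuple[int, int, int] = (48, 48, 48),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_parcels: int = 84,
    seed: int = 0,
    gm_thickness_mm: float = 3.0,
) -> tuple[Image3D, LabelMap]:
    """Build the phantom template image and its label map.

    The label legend carries the anatomical labels plus ``parcel_1`` ..
    ``parcel_R``.  Same arguments and seed give bit-identical output.
    """
    if n_parcels < 2:
        raise ValueError("n_parcels must be >= 2")
    geo = _geometry(shape, spacing, gm_thickness_mm, 1.0, 1.0)
    labels = _render_labels(shape, spacing, geo)
    img = _render_intensity(labels)
    parcels = _parcellate(labels, spacing, n_parcels, seed)
    legend = dict(ANATOMY_LEGEND)
    for r in range(1, n_parcels + 1):
        legend[PARCEL_OFFSET + r] = f"parcel_{r}"
    lm = LabelMap(labels, spacing, (0.0, 0.0, 0.0), legend, parcels)
    return Image3D(img, spacing), lm


def template_hippo_volume(labelmap: LabelMap) -> float:
    return float(labelmap.hippocampus_mask.sum()) * labelmap.voxel_volume


# ---------------------------------------------------------------------------
# subject synthesis
# ---------------------------------------------------------------------------


def _smooth_random_field_3d(shape, rng, sigma_vox=6.0):
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma_vox)
    f /= max(np.abs(f).max(), 1e-12)
    return f


def sample_subject(
    template: Image3D,
    labelmap: LabelMap,
    group: str,
    age: float,
    sex: str,
    effects: EffectSpec,
    seed: int | np.random.Generator = 0,
    subject_id: str = "subj",
    gm_thickness_mm: float = 3.0,
) -> SubjectRecord:
    """Synthesize one subject image with planted, recorded effects.

    Applies, in order: subject-specific geometry (group hippocampal volume
    factor, ribbon thinning, nucleus shrinkage, age/sex effects), a random
    smooth B-spline deformation, a smooth multiplicative bias field, and
    additive Gaussian noise.  All planted values are recorded in
    :class:`GroundTruth`.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    shape, spacing = template.shape, template.spacing

    hv_factor = (
        effects.hippo_factor[group]
        * (1.0 + effects.age_slope_hv_per_year * (age - REFERENCE_AGE))
        * (effects.sex_hv_factor_m if sex == "M" else 1.0)
    )
    thickness = (
        gm_thickness_mm
        + effects.thickness_offset_mm[group]
        + effects.age_slope_cth_mm_per_year * (age - REFERENCE_AGE)
        + (effects.sex_cth_offset_mm_m if sex == "M" else 0.0)
    )
    if thickness < min(spacing):
        raise ValueError(f"requested ribbon thickness {thickness:.2f} mm < 1 voxel")
    regional_factor = float(np.exp(effects.regional_logj_shift[group]))

    geo = _geometry(shape, spacing, thickness, 1.0, 1.0)
    targets = {
        "hippo_L": hv_factor * (labelmap.labels == LEFT_HIPPO).sum(),
        "hippo_R": hv_factor * (labelmap.labels == RIGHT_HIPPO).sum(),
        "nucleus": regional_factor * (labelmap.labels == ATROPHY_NUCLEUS).sum(),
    }
    subj_labels = _render_labels(shape, spacing, geo, targets)

    # verify the planted hippocampal factor is reachable at this resolution
    n_template = labelmap.hippocampus_mask.sum()
    n_subj = np.isin(subj_labels, (LEFT_HIPPO, RIGHT_HIPPO)).sum()
    achieved = n_subj / n_template
    if abs(achieved - hv_factor) > 0.03 * hv_factor:
        raise ValueError(
            f"hippocampal volume factor {hv_factor:.3f} unreachable at this "
            f"resolution (achieved {achieved:.3f})"
        )

    img = _render_intensity(subj_labels)

    fld = random_smooth_field(
        Image3D(np.zeros(shape) + 1, spacing),
        control_spacing=8.0 * min(spacing),
        amplitude_mm=effects.deform_amplitude_mm,
        seed=rng,
    )
    warped = warp(Image3D(img, spacing), fld, "linear")
    warped_labels = warp_labels(subj_labels, fld)

    data = warped.data
    if effects.bias_amplitude > 0:
        bias = 1.0 + effects.bias_amplitude * _smooth_random_field_3d(shape, rng)
        data = data * bias
    if effects.noise_sd > 0:
        data = data + rng.normal(0.0, effects.noise_sd, shape)

    vv = float(np.prod(spacing))
    truth = GroundTruth(
        hippo_volume_mm3=hv_factor * float(n_template) * vv,
        hippo_volume_voxel_mm3=float(
            np.isin(warped_labels, (LEFT_HIPPO, RIGHT_HIPPO)).sum()
        )
        * vv,
        cortical_thickness_mm=thickness,
        atrophy_region_mask=labelmap.labels == ATROPHY_NUCLEUS,
        deformation=fld,
        hippo_factor=hv_factor,
        regional_factor=regional_factor,
    )
    lm = LabelMap(
        warped_labels.astype(np.int16),
        spacing,
        (0.0, 0.0, 0.0),
        dict(labelmap.legend),
        labelmap.parcels,
    )
    return SubjectRecord(subject_id, group, age, sex, Image3D(data, spacing), lm, truth)


def sample_cohort(
    template: Image3D,
    labelmap: LabelMap,
    n_per_group: dict[str, int],
    effects: EffectSpec | None = None,
    age_dist: tuple[float, float, float, float] = (75.0, 6.0, 55.0, 90.0),
    sex_ratio: float = 0.5,
    seed: int = 0,
    gm_thickness_mm: float = 3.0,
) -> Cohort:
    """Draw an independent synthetic cohort; deterministic given the seed.

    Ages are Gaussian (mean, sd) truncated to [lo, hi]; ``sex_ratio`` is the
    probability of 'M'.  A fraction ``effects.missing_cth_fraction`` of
    subjects is flagged CTH-missing using the deterministic count
    ``floor(n * f + 0.5)``.
    """
    effects = effects or EffectSpec()
    rng = np.random.default_rng(seed)
    mu, sd, lo, hi = age_dist
    subjects: list[SubjectRecord] = []
    for group in GROUPS:
        n = n_per_group.get(group, 0)
        if n < 0:
            raise ValueError("n per group must be >= 0")
        for i in range(n):
            age = float(np.clip(rng.normal(mu, sd), lo, hi))
            sex = "M" if rng.random() < sex_ratio else "F"
            sid = f"{group}_{i:03d}"
            subjects.append(
                sample_subject(
                    template, labelmap, group, age, sex, effects, rng, sid,
                    gm_thickness_mm,
                )
            )
    n_missing = int(np.floor(len(subjects) * effects.missing_cth_fraction + 0.5))
    for idx in rng.permutation(len(subjects))[:n_missing]:
        subjects[idx].cth_missing = True
    return Cohort(subjects, template, labelmap, effects)


# ---------------------------------------------------------------------------
# image-free feature tables (fast test bed for harmonize / classify / crossval)
# ---------------------------------------------------------------------------


def sample_feature_table(
    n_per_group: dict[str, int],
    n_features: int,
    informative: set[int] | None = None,
    effect_size_d: float = 1.0,
    age_slope: float = 0.0,
    sex_offset: float = 0.0,
    missing_spec: dict | None = None,
    seed: int = 0,
    feature_prefix: str = "f",
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Gaussian feature table with planted group, age and sex structure.

    Features are unit-variance Gaussian.  Features in ``informative``
    (0-based column indices) carry a between-group mean difference of
    ``effect_size_d`` across the severity contrast (equally spaced over the
    sampled groups, ordered HC < S-MCI < P-MCI < AD).  ALL features carry
    the configured age slope (per year, centered at age 75) and male sex
    offset.  ``missing_spec`` is ``{"columns": [names-or-indices],
    "fraction": f}``; exactly ``floor(n * f + 0.5)`` subjects get missing
    values in those columns.

    Returns (features, labels, covariates) indexed by subject id.
    """
    if effect_size_d < 0:
        raise ValueError("effect size d must be >= 0")
    informative = set() if informative is None else set(informative)
    if informative and (min(informative) < 0 or max(informative) >= n_features):
        raise ValueError("informative indices out of range")
    rng = np.random.default_rng(seed)
    groups_present = [g for g in GROUPS if n_per_group.get(g, 0) > 0]
    if len(groups_present) < 1:
        raise ValueError("need at least one non-empty group")
    sev = {g: i for i, g in enumerate(groups_present)}
    denom = max(len(groups_present) - 1, 1)

    rows, labels, ages, sexes = [], [], [], []
    ids = []
    for g in groups_present:
        for i in range(n_per_group[g]):
            ids.append(f"{g}_{i:03d}")
            labels.append(g)
            age = float(np.clip(rng.normal(75.0, 6.0), 55.0, 90.0))
            sex = "M" if rng.random() < 0.5 else "F"
            ages.append(age)
            sexes.append(sex)
            x = rng.normal(0.0, 1.0, n_features)
            shift = effect_size_d * sev[g] / denom
            for j in informative:
                x[j] -= shift  # atrophy-ward: more severe groups have lower values
            x += age_slope * (age - REFERENCE_AGE)
            if sex == "M":
                x += sex_offset
            rows.append(x)

    cols = [f"{feature_prefix}{j:03d}" for j in range(n_features)]
    X = pd.DataFrame(np.asarray(rows), index=ids, columns=cols)
    y = pd.Series(labels, index=ids, name="group")
    cov = pd.DataFrame({"age": ages, "sex": sexes}, index=ids)

    if missing_spec:
        columns = [
            c if isinstance(c, str) else cols[c] for c in missing_spec["columns"]
        ]
        f = missing_spec["fraction"]
        n_miss = int(np.floor(len(ids) * f + 0.5))
        miss_rows = rng.permutation(len(ids))[:n_miss]
        X.iloc[miss_rows, [X.columns.get_loc(c) for c in columns]] = np.nan
    return X, y, cov
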