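"""End-to-end orchestration: phantom cohort -> features -> evaluation report.

This module wires the image stages together at configurable scale: it
synthesizes a cohort, extracts all four feature families (HV via
multi-atlas segmentation, CTH via linked-surface thickness, TBM via
multi-template Jacobians, MBL via Laplacian eigenmaps), and runs the
feature-family comparison protocol.  CTH and TBM statistical ROIs are
rebuilt per outer part from the ROI subjects only, through feature
providers handed to the protocol driver.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cth as cth_mod
from . import mbl as mbl_mod
from . import tbm as tbm_mod
from .classify import EvalResult
from .crossval import ProtocolSpec, run_feature_comparison
from .phantom import Cohort, EffectSpec, make_template, sample_cohort, sample_subject
from .segment_hippo import AtlasEntry, segment_hippocampus

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Full configuration; every stage draws randomness from ``seed``."""

    shape: tuple[int, int, int] = (32, 32, 32)
    n_parcels: int = 20
    n_per_group: dict = field(
        default_factory=lambda: {"HC": 15, "S-MCI": 0, "P-MCI": 0, "AD": 15}
    )
    n_atlases: int = 8
    atlas_k: int = 3
    n_templates_per_group: int = 1
    mbl_dims: int = 10
    mbl_k: int = 10
    cth_fwhm_mm: float = 6.0
    alpha: float = 0.05
    contrast: str = "HCvsAD"
    classifier: str = "lda"
    n_reps: int = 20
    seed: int = 0
    registration: dict = field(
        default_factory=lambda: {"control_spacing_mm": 10.0, "levels": (2,), "iters": 20}
    )

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def make_cohort(config: PipelineConfig, effects: EffectSpec | None = None) -> tuple[Cohort, list[AtlasEntry]]:
    """Template, study cohort, and a held-out mixed-group atlas pool."""
    effects = effects or EffectSpec()
    template, labelmap = make_template(
        config.shape, n_parcels=config.n_parcels, seed=config.seed
    )
    cohort = sample_cohort(
        template, labelmap, config.n_per_group, effects, seed=config.seed + 1
    )
    rng = np.random.default_rng(config.seed + 2)
    pool = []
    groups = [g for g in ("HC", "S-MCI", "P-MCI", "AD")]
    for i in range(config.n_atlases):
        g = groups[i % 4]
        s = sample_subject(
            template,
            labelmap,
            g,
            float(np.clip(rng.normal(75, 6), 55, 90)),
            "M" if rng.random() < 0.5 else "F",
            effects,
            rng,
            subject_id=f"atlas_{g}_{i:02d}",
        )
        pool.append(AtlasEntry(s.image, s.labels, s.id))
    return cohort, pool


def extract_hv(cohort: Cohort, pool: list[AtlasEntry], config: PipelineConfig) -> pd.DataFrame:
    rows = {}
    for s in cohort:
        _, hv = segment_hippocampus(
            s.image, pool, k=config.atlas_k,
            control_spacing_mm=config.registration["control_spacing_mm"],
            levels=tuple(config.registration["levels"]),
            iters=config.registration["iters"],
        )
        rows[s.id] = {"HV": hv}
    return pd.DataFrame.from_dict(rows, orient="index")


def extract_cth_data(cohort: Cohort, config: PipelineConfig):
    """Per-subject smoothed thickness on the template node set."""
    ref_pair = cth_mod.extract_surface_pair(cohort.labelmap)
    thickness = {}
    for s in cohort:
        if s.cth_missing:
            thickness[s.id] = np.full(len(ref_pair), np.nan)
            continue
        pair = cth_mod.extract_surface_pair(s.labels)
        th = cth_mod.tlink_thickness(pair)
        th = cth_mod.smooth_thickness(pair, th, config.cth_fwhm_mm)
        thickness[s.id] = cth_mod.thickness_on_reference(pair, th, ref_pair)
    return ref_pair, thickness


def extract_tbm_maps(cohort: Cohort, config: PipelineConfig):
    """Template library + per-subject per-template Jacobian maps."""
    n = config.n_templates_per_group
    library = tbm_mod.build_template_library(
        cohort,
        min(n, len(cohort.by_group("HC"))),
        min(n, len(cohort.by_group("S-MCI", "P-MCI"))),
        min(n, len(cohort.by_group("AD"))),
        seed=config.seed + 3,
        registration=config.registration,
    )
    maps = {
        s.id: tbm_mod.subject_jacobians(s, library, config.registration)
        for s in cohort
    }
    return library, maps


def extract_mbl(cohort: Cohort, config: PipelineConfig) -> pd.DataFrame:
    feats = mbl_mod.mbl_features_cohort(
        cohort.subjects, cohort.labelmap, None, d=config.mbl_dims, k=config.mbl_k
    )
    return pd.DataFrame.from_dict(feats, orient="index").rename(
        columns=lambda j: f"mbl_{j:02d}"
    )


def run_all(config: PipelineConfig, effects: EffectSpec | None = None, out_dir: str | Path | None = None):
    """Full pipeline; returns (results, comparisons, provenance dict)."""
    t_start = time.time()
    cohort, pool = make_cohort(config, effects)
    labels = cohort.manifest()["group"]
    cov = cohort.manifest()[["age", "sex"]]
    ga, gb = tbm_mod.CONTRASTS[config.contrast]

    logger.info("extracting HV features")
    hv = extract_hv(cohort, pool, config)
    logger.info("extracting MBL features")
    mblf = extract_mbl(cohort, config)
    logger.info("extracting CTH data")
    ref_pair, thickness = extract_cth_data(cohort, config)
    logger.info("extracting TBM maps")
    library, jmaps = extract_tbm_maps(cohort, config)

    group_by_id = labels.to_dict()
    mask = cohort.labelmap.brain_mask
    parcellation = cohort.labelmap.parcels

    hc_ids = [i for i in labels.index if labels[i] == "HC"]

    def _with_controls(roi_ids, eval_ids):
        # correction training controls must be featurized too (never in test)
        return sorted(set(eval_ids) | (set(hc_ids) - set(roi_ids)))

    def tbm_provider(roi_ids, eval_ids):
        feats, _ = tbm_mod.tbm_features_cohort(
            [cohort.get(i) for i in _with_controls(roi_ids, eval_ids)],
            {i: jmaps[i] for i in roi_ids},
            jmaps,
            (ga, gb),
            group_by_id,
            parcellation,
            mask,
            config.alpha,
            config.contrast,
        )
        return pd.DataFrame.from_dict(feats, orient="index").rename(
            columns=lambda j: f"tbm_p{j + 1:03d}"
        )

    def cth_provider(roi_ids, eval_ids):
        roi_ok = [i for i in roi_ids if np.isfinite(thickness[i]).any()]
        feats, parcels = cth_mod.cth_stat_roi_features(
            thickness,
            group_by_id,
            (ga, gb),
            _with_controls(roi_ids, eval_ids),
            roi_ok,
            ref_pair.parcel,
            config.alpha,
        )
        return pd.DataFrame.from_dict(feats, orient="index").rename(
            columns=lambda j: f"cth_p{parcels[j]:03d}"
        )

    spec = ProtocolSpec(
        contrast=config.contrast,
        classifier=config.classifier,
        n_reps=config.n_reps,
        seed=config.seed,
    )
    from .classify import compare_runs
    from .crossval import run_dataset1

    def static_provider(table):
        return lambda roi_ids, eval_ids: table

    providers = {
        "MBL": static_provider(mblf),
        "HV": static_provider(hv),
        "TBM": tbm_provider,
        "CTH": cth_provider,
    }

    def all_provider(roi_ids, eval_ids):
        parts = []
        for fam, prov in providers.items():
            try:
                parts.append(prov(roi_ids, eval_ids).add_prefix(f"{fam}:"))
            except ValueError as exc:
                logger.warning("%s excluded from combined set: %s", fam, exc)
        return pd.concat(parts, axis=1, join="inner")

    results: dict[str, EvalResult] = {}
    ledgers = {}
    index_table = hv  # only the index is used when a provider is given
    for fam, provider in {**providers, "All": all_provider}.items():
        try:
            res, led = run_dataset1(index_table, labels, cov, spec, provider, hc_ids)
            led.audit()
            results[fam], ledgers[fam] = res, led
        except ValueError as exc:
            logger.warning("%s evaluation skipped: %s", fam, exc)
    comparisons = {
        fam: compare_runs(results["All"].ccrs, results[fam].ccrs)
        for fam in results
        if fam != "All" and "All" in results
    }

    provenance = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t_start, 1),
        "n_subjects": len(cohort),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cohort.manifest().to_csv(out / "manifest.csv")
        for fam in results:
            pd.DataFrame(
                results[fam].runs, columns=["ccr", "sen", "spe"]
            ).to_csv(out / f"runs_{fam}.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
        (out / "report.txt").write_text(format_report(results, comparisons))
    return results, comparisons, provenance


def format_report(
    results: dict[str, EvalResult],
    comparisons: dict | None = None,
) -> str:
    """Human-readable per-contrast table: family x (CCR [CI], SEN, SPE).

    A dagger marks families whose run distribution differs significantly
    from the combined ('All') result.
    """
    lines = [f"{'Feature':<8}{'CCR':>6} {'95% CI':>10} {'SEN':>6} {'SPE':>6}"]
    order = [f for f in ("MBL", "HV", "CTH", "TBM", "All") if f in results]
    for fam in order:
        r = results[fam]
        lo, hi = r.ci
        dag = ""
        if comparisons and fam in comparisons and comparisons[fam][2]:
            dag = "†"
        lines.append(
            f"{fam:<8}{r.ccr:>5.0f}{dag:<1}[{lo:.0f} {hi:.0f}]".ljust(26)
            + f"{r.sen:>6.0f} {r.spe:>6.0f}"
        )
    return "\n".join(lines)
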