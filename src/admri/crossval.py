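"""Evaluation protocols: three-part statistical-ROI rotation (dataset 1),
fixed-split evaluation (dataset 2), and feature-family comparison — all
leakage-audited.

Dataset-1 protocol: the cohort is divided into three equally sized parts;
each part in turn supplies the subjects for the CTH/TBM statistical ROIs,
while the remaining two thirds are evaluated with repeated random 5%-test /
95%-train splits (100 repetitions per part, 300 runs total, averaged).
Within every repetition the covariate correction is fitted on the training
controls, imputation statistics come from the training set only, and
stepwise selection runs inside the training fold (a 'global' mode selecting
once per part on all evaluation subjects is available as the alternative
reading).  A :class:`RunLedger` records every id each fitted object
touched; ``audit`` asserts stat-ROI ids never meet evaluation ids and train
never meets test.

Repetition randomness is counter-based: each (seed, part, rep) triple
seeds an independent generator, so runs are reproducible and order-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import (
    EvalResult,
    compare_runs,
    evaluate,
    fit_classifier,
    positive_class_of,
    predict_classifier,
)
from .harmonize import (
    apply_correction,
    fit_correction,
    impute_missing,
    stepwise_select,
)
from .tbm import CONTRASTS

FAMILIES = ("MBL", "HV", "CTH", "TBM")


@dataclass
class ProtocolSpec:
    """Configuration of an evaluation protocol run."""

    mode: str = "dataset1"
    contrast: str = "HCvsAD"
    n_outer_parts: int = 3
    test_fraction: float = 0.05
    n_reps: int = 100
    families: tuple = FAMILIES
    classifier: str = "lda"
    seed: int = 0
    stratified: bool = True
    p_enter: float = 0.05
    p_remove: float = 0.10
    impute_strategy: str = "train-mean"
    selection: str = "nested"  # 'nested' (per training fold) or 'global'
    select_features: bool = True
    ci_method: str = "percentile"

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 0.5:
            raise ValueError("test_fraction must lie in (0, 0.5)")
        if self.n_outer_parts < 2:
            raise ValueError("n_outer_parts must be >= 2")
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")

    @property
    def groups(self) -> tuple[str, str]:
        return CONTRASTS[self.contrast]


@dataclass
class RunLedger:
    """Per-repetition bookkeeping for the leakage audit."""

    records: list[dict] = field(default_factory=list)

    def add(self, **rec) -> None:
        self.records.append(rec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    **{k: v for k, v in r.items() if not isinstance(v, (set, list))},
                    **{
                        k: ";".join(sorted(map(str, v)))
                        for k, v in r.items()
                        if isinstance(v, (set, list))
                    },
                }
                for r in self.records
            ]
        )

    def audit(self) -> None:
        """Raise on any leakage violation across all recorded runs."""
        for i, r in enumerate(self.records):
            roi = set(r.get("roi_ids", ()))
            train = set(r["train_ids"])
            test = set(r["test_ids"])
            if roi & (train | test):
                raise AssertionError(f"run {i}: ROI ids leak into evaluation ids")
            if train & test:
                raise AssertionError(f"run {i}: train/test overlap")
            for key in ("correction_ids", "impute_ids", "selection_ids"):
                fitted = set(r.get(key, ()))
                if fitted & test:
                    raise AssertionError(f"run {i}: {key} touched test subjects")


def _rng(seed: int, *counters: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), *map(int, counters)]))


def _stratified_parts(ids: list[str], labels: pd.Series, n_parts: int, rng) -> list[list[str]]:
    parts: list[list[str]] = [[] for _ in range(n_parts)]
    for g in sorted(pd.unique(labels.loc[ids])):
        gids = [i for i in ids if labels[i] == g]
        perm = rng.permutation(len(gids))
        for j, pi in enumerate(perm):
            parts[j % n_parts].append(gids[pi])
    return [sorted(p) for p in parts]


def _draw_test(
    eval_ids: list[str],
    labels: pd.Series,
    fraction: float,
    rng,
    stratified: bool,
    max_attempts: int = 100,
) -> list[str]:
    n_test = max(int(round(fraction * len(eval_ids))), 2)
    classes = sorted(pd.unique(labels.loc[eval_ids]))
    if stratified:
        test: list[str] = []
        remaining = n_test
        for j, g in enumerate(classes):
            gids = [i for i in eval_ids if labels[i] == g]
            want = max(int(round(n_test * len(gids) / len(eval_ids))), 1)
            if j == len(classes) - 1:
                want = max(remaining, 1)
            pick = rng.choice(len(gids), size=min(want, len(gids)), replace=False)
            test.extend(gids[k] for k in pick)
            remaining -= len(pick)
        return sorted(test)
    for _ in range(max_attempts):
        pick = rng.choice(len(eval_ids), size=n_test, replace=False)
        test = [eval_ids[k] for k in pick]
        if len(set(labels.loc[test])) == len(classes):
            return sorted(test)
    raise RuntimeError("could not draw a test set containing every class")


def _one_run(
    features: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame,
    train_ids: list[str],
    test_ids: list[str],
    control_ids: list[str],
    spec: ProtocolSpec,
    preselected: list[str] | None = None,
):
    """Correct, impute, select, fit, predict, score — one repetition."""
    corr = None
    for terms in (("age", "sex"), ("age",), ()):
        try:
            corr = fit_correction(features, covariates, control_ids, terms)
            break
        except ValueError:
            continue  # e.g. single-sex control draw: drop the term
    if corr is None:
        raise ValueError("covariate correction unfittable on this training set")
    corrected = apply_correction(features, corr, covariates)
    work_ids = train_ids + test_ids
    completed = impute_missing(
        corrected.loc[work_ids], spec.impute_strategy, train_ids
    )
    train = completed.loc[[i for i in train_ids if i in completed.index]]
    test = completed.loc[[i for i in test_ids if i in completed.index]]

    selection_ids: list[str] = []
    if preselected is not None:
        selected = preselected
    elif spec.select_features and features.shape[1] > 1:
        rep = stepwise_select(
            train, labels.loc[train.index], spec.p_enter, spec.p_remove
        )
        selected = rep.selected
        selection_ids = rep.train_ids
        if not selected:
            # no candidate reached p_enter: fall back to the single best
            pv = {
                c: abs(train[c].corr(
                    (labels.loc[train.index] == spec.groups[1]).astype(float)
                ))
                for c in train.columns
            }
            selected = [max(pv, key=lambda c: (pv[c], c))]
    else:
        selected = list(features.columns)

    model = fit_classifier(spec.classifier, train[selected].to_numpy(),
                           labels.loc[train.index].to_numpy())
    pred = predict_classifier(model, test[selected].to_numpy())
    pos = positive_class_of(spec.groups)
    ccr, sen, spe = evaluate(pred, labels.loc[test.index].to_numpy(), pos)
    return (ccr, sen, spe), selected, corr.train_ids, selection_ids


def run_dataset1(
    features: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame,
    spec: ProtocolSpec,
    feature_provider=None,
    extra_control_ids: list[str] | None = None,
) -> tuple[EvalResult, RunLedger]:
    """Three-part rotation with repeated random 5%/95% splits per part.

    ``feature_provider(roi_ids, eval_ids) -> DataFrame`` recomputes
    statistical-ROI features (CTH/TBM) from the ROI part only; None uses
    the fixed ``features`` table (appropriate for HV/MBL and table-scale
    studies).  ``extra_control_ids`` supplies control subjects outside the
    contrast (used to train the covariate correction when HC is not one of
    the contrast groups).
    """
    ga, gb = spec.groups
    contrast_ids = sorted(i for i in features.index if labels[i] in (ga, gb))
    parts = _stratified_parts(contrast_ids, labels, spec.n_outer_parts, _rng(spec.seed, 0))
    result = EvalResult()
    ledger = RunLedger()
    extra_control_ids = extra_control_ids or []

    for part_idx, roi_part in enumerate(parts):
        eval_ids = sorted(set(contrast_ids) - set(roi_part))
        feats = (
            features
            if feature_provider is None
            else feature_provider(roi_part, eval_ids)
        )
        preselected = None
        if spec.selection == "global" and spec.select_features:
            table = impute_missing(feats.loc[eval_ids], spec.impute_strategy, eval_ids)
            preselected = stepwise_select(
                table, labels.loc[eval_ids], spec.p_enter, spec.p_remove
            ).selected or None
        for rep in range(spec.n_reps):
            rng = _rng(spec.seed, part_idx + 1, rep)
            test_ids = _draw_test(
                eval_ids, labels, spec.test_fraction, rng, spec.stratified
            )
            train_ids = sorted(set(eval_ids) - set(test_ids))
            if "HC" in (ga, gb):
                control_ids = [i for i in train_ids if labels[i] == "HC"]
            else:
                control_ids = [i for i in extra_control_ids if i not in test_ids]
            metrics, selected, corr_ids, sel_ids = _one_run(
                feats.loc[sorted(set(eval_ids) | set(control_ids))],
                labels,
                covariates,
                train_ids,
                test_ids,
                control_ids,
                spec,
                preselected,
            )
            result.add(*metrics)
            ledger.add(
                part=part_idx,
                rep=rep,
                roi_ids=roi_part,
                train_ids=train_ids,
                test_ids=test_ids,
                correction_ids=corr_ids,
                impute_ids=train_ids,
                selection_ids=sel_ids,
                selected=selected,
                ccr=metrics[0],
                sen=metrics[1],
                spe=metrics[2],
            )
    return result, ledger


def run_dataset2(
    features: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame,
    train_ids: list[str],
    test_ids: list[str],
    roi_source_ids: list[str],
    spec: ProtocolSpec,
    feature_provider=None,
    extra_control_ids: list[str] | None = None,
) -> tuple[tuple[float, float, float], RunLedger]:
    """Single fixed-split evaluation with ROIs from held-out subjects."""
    sets = [set(train_ids), set(test_ids), set(roi_source_ids)]
    for i in range(3):
        for j in range(i + 1, 3):
            if sets[i] & sets[j]:
                raise ValueError("train/test/ROI-source id sets must be disjoint")
    feats = (
        features
        if feature_provider is None
        else feature_provider(list(roi_source_ids), sorted(sets[0] | sets[1]))
    )
    ga, gb = spec.groups
    if "HC" in (ga, gb):
        control_ids = [i for i in train_ids if labels[i] == "HC"]
    else:
        control_ids = [i for i in (extra_control_ids or []) if i not in test_ids]
    metrics, selected, corr_ids, sel_ids = _one_run(
        feats.loc[sorted(sets[0] | sets[1] | set(control_ids))],
        labels,
        covariates,
        sorted(train_ids),
        sorted(test_ids),
        control_ids,
        spec,
    )
    ledger = RunLedger()
    ledger.add(
        part=0,
        rep=0,
        roi_ids=sorted(roi_source_ids),
        train_ids=sorted(train_ids),
        test_ids=sorted(test_ids),
        correction_ids=corr_ids,
        impute_ids=sorted(train_ids),
        selection_ids=sel_ids,
        selected=selected,
        ccr=metrics[0],
        sen=metrics[1],
        spe=metrics[2],
    )
    ledger.audit()
    return metrics, ledger


def run_feature_comparison(
    family_tables: dict[str, pd.DataFrame],
    labels: pd.Series,
    covariates: pd.DataFrame,
    spec: ProtocolSpec,
    feature_providers: dict | None = None,
    extra_control_ids: list[str] | None = None,
    alpha: float = 1e-4,
):
    """Dataset-1 evaluation per feature family plus the combined set.

    Returns (results, comparisons): ``results`` maps family (and 'All') to
    its EvalResult; ``comparisons`` maps family to the compare_runs tuple
    of 'All' vs that family.  Identical counter-based seeds mean every
    family sees the same splits, so run distributions are pairable.
    """
    families = [f for f in spec.families if f in family_tables]
    tables = {f: family_tables[f] for f in families}
    common = None
    for t in tables.values():
        common = set(t.index) if common is None else common & set(t.index)
    common = sorted(common)
    all_table = pd.concat(
        [tables[f].loc[common].add_prefix(f"{f}:") for f in families], axis=1
    )

    results: dict[str, EvalResult] = {}
    ledgers: dict[str, RunLedger] = {}
    for fam in families:
        res, led = run_dataset1(
            tables[fam].loc[common], labels, covariates, spec,
            None if feature_providers is None else feature_providers.get(fam),
            extra_control_ids,
        )
        results[fam], ledgers[fam] = res, led
    res, led = run_dataset1(
        all_table, labels, covariates, spec, None, extra_control_ids
    )
    results["All"], ledgers["All"] = res, led

    comparisons = {
        fam: compare_runs(results["All"].ccrs, results[fam].ccrs, alpha)
        for fam in families
    }
    for led in ledgers.values():
        led.audit()
    return results, comparisons, ledgers


def split_instability(
    features: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame,
    spec: ProtocolSpec,
    n_partitions: int = 50,
    train_fraction: float = 0.5,
) -> np.ndarray:
    """CCRs over repeated random train/test partitions of one fixed cohort.

    Quantifies how strongly the achieved accuracy depends on the particular
    partition — the spread (max - min) is the instability measure.
    """
    ga, gb = spec.groups
    ids = sorted(i for i in features.index if labels[i] in (ga, gb))
    ccrs = []
    for part in range(n_partitions):
        rng = _rng(spec.seed, 900, part)
        n_train = int(round(train_fraction * len(ids)))
        perm = rng.permutation(len(ids))
        train_ids = sorted(ids[i] for i in perm[:n_train])
        test_ids = sorted(ids[i] for i in perm[n_train:])
        if len(set(labels.loc[train_ids])) < 2 or len(set(labels.loc[test_ids])) < 2:
            continue
        control_ids = [i for i in train_ids if labels[i] == "HC"] or train_ids
        metrics, *_ = _one_run(
            features, labels, covariates, train_ids, test_ids, control_ids, spec
        )
        ccrs.append(metrics[0])
    return np.asarray(ccrs)
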