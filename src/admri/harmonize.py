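"""Covariate residualization, missing-value handling, stepwise selection.

Age and sex effects are removed with per-feature ordinary least squares
fitted on healthy controls only — the premise being that control-trained
regression captures normal, not disease-related, covariate variation — and
the fitted correction is then subtracted from ALL subjects, patients
included.  Missing cells (NaN) are never silently treated as zero: they are
excluded from fits and either imputed from training-set statistics or
dropped.  Feature selection is classical forward/backward stepwise
regression on a linear model of the binary label, driven by partial-F
p-values.

Every fit records the subject ids it touched (``train_ids`` on the fitted
object), which the cross-validation ledger audits for leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def encode_covariates(
    cov: pd.DataFrame, terms: tuple[str, ...] = ("age", "sex")
) -> np.ndarray:
    """Design matrix [1, age?, sex_m?] from an (age, sex) covariate table."""
    cols = [np.ones(len(cov))]
    if "age" in terms:
        cols.append(cov["age"].to_numpy(dtype=float))
    if "sex" in terms:
        cols.append((cov["sex"] == "M").to_numpy(dtype=float))
    return np.column_stack(cols)


@dataclass
class CorrectionModel:
    """Per-feature OLS coefficients (intercept, age, sex), control-trained."""

    coef: pd.DataFrame  # features x [intercept, age, sex]
    train_ids: list[str] = field(default_factory=list)
    terms: tuple[str, ...] = ("age", "sex")


def fit_correction(
    features: pd.DataFrame,
    covariates: pd.DataFrame,
    control_ids: list[str],
    terms: tuple[str, ...] = ("age", "sex"),
) -> CorrectionModel:
    """OLS of each feature on [1, age, sex] over control subjects only.

    Missing cells are excluded per feature.  Raises on a rank-deficient
    design (e.g. a single sex among the controls) or when fewer than 3
    controls have a value for some feature.  ``terms`` restricts the
    covariates (protocol drivers drop terms when a small control set
    cannot identify them).
    """
    ctrl = [i for i in control_ids if i in features.index]
    X_all = encode_covariates(covariates.loc[ctrl], terms)
    if np.linalg.matrix_rank(X_all) < X_all.shape[1]:
        raise ValueError("rank-deficient covariate design among controls")
    coefs = {}
    for name in features.columns:
        y = features.loc[ctrl, name].to_numpy(dtype=float)
        ok = np.isfinite(y)
        if ok.sum() < max(3, X_all.shape[1]):
            raise ValueError(f"fewer than 3 controls with values for {name!r}")
        X = X_all[ok]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient design for feature {name!r}")
        beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        full = np.zeros(3)
        full[0] = beta[0]
        j = 1
        if "age" in terms:
            full[1] = beta[j]
            j += 1
        if "sex" in terms:
            full[2] = beta[j]
        coefs[name] = full
    coef = pd.DataFrame(coefs, index=["intercept", "age", "sex"]).T
    return CorrectionModel(coef, list(ctrl), terms)


def apply_correction(
    features: pd.DataFrame,
    model: CorrectionModel,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """Subtract the fitted covariate prediction from every subject.

    corrected = observed - (intercept + b_age * age + b_sex * sex); missing
    stays missing.
    """
    X = encode_covariates(covariates.loc[features.index])
    pred = X @ model.coef.loc[features.columns].to_numpy().T
    return features - pred


@dataclass
class ImputeModel:
    fill: pd.Series
    train_ids: list[str] = field(default_factory=list)


def impute_missing(
    features: pd.DataFrame,
    strategy: str = "train-mean",
    training_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Complete a feature table without touching test-subject statistics.

    Strategies: 'train-mean' fills a missing cell with the mean over
    non-missing *training* subjects; 'drop-subject' removes rows with any
    missing value; 'drop-feature' removes columns with any missing value.
    """
    if strategy == "drop-subject":
        return features.dropna(axis=0)
    if strategy == "drop-feature":
        return features.dropna(axis=1)
    if strategy != "train-mean":
        raise ValueError(f"unknown strategy {strategy!r}")
    train_ids = list(features.index) if training_ids is None else list(training_ids)
    means = features.loc[[i for i in train_ids if i in features.index]].mean()
    if means.isna().any():
        bad = means.index[means.isna()].tolist()
        raise ValueError(f"features missing for all training subjects: {bad}")
    return features.fillna(means)


@dataclass
class SelectionReport:
    selected: list[str]
    steps: list[dict]
    train_ids: list[str] = field(default_factory=list)


def _partial_f_pvalues(X: np.ndarray, y: np.ndarray, included: list[int], candidates: list[int]):
    """p-value of adding each candidate column to the current OLS model."""
    n = len(y)
    base_cols = [0] + [c + 1 for c in included]  # col 0 is the intercept
    Xb = X[:, base_cols]
    beta, *_ = np.linalg.lstsq(Xb, y, rcond=None)
    rss0 = float(np.sum((y - Xb @ beta) ** 2))
    out = {}
    for c in candidates:
        Xc = X[:, base_cols + [c + 1]]
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        rss1 = float(np.sum((y - Xc @ beta) ** 2))
        df2 = n - Xc.shape[1]
        if df2 <= 0 or rss1 <= 0:
            out[c] = 0.0
            continue
        F = max((rss0 - rss1) / (rss1 / df2), 0.0)
        out[c] = float(stats.f.sf(F, 1, df2))
    return out


def _included_pvalues(X: np.ndarray, y: np.ndarray, included: list[int]):
    """Partial-F p-value of each included feature given all the others."""
    out = {}
    for c in included:
        rest = [d for d in included if d != c]
        out[c] = _partial_f_pvalues(X, y, rest, [c])[c]
    return out


def stepwise_select(
    features: pd.DataFrame,
    labels: pd.Series,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_iter: int = 100,
) -> SelectionReport:
    """Forward/backward stepwise regression on a linear model of the label.

    Repeatedly adds the candidate with the smallest partial-F p-value if it
    is below ``p_enter``, then removes any included feature whose p-value
    exceeds ``p_remove``.  Ties break deterministically by feature name.
    ``p_enter <= p_remove`` (required) plus the iteration cap guarantee
    termination.  Labels must be binary.
    """
    if p_enter > p_remove:
        raise ValueError("p_enter must be <= p_remove")
    classes = sorted(pd.unique(labels))
    if len(classes) != 2:
        raise ValueError(f"labels must be binary, got {classes}")
    y = (labels == classes[1]).to_numpy(dtype=float)
    names = list(features.columns)
    Xmat = features.to_numpy(dtype=float)
    if not np.all(np.isfinite(Xmat)):
        raise ValueError("stepwise selection requires a complete (imputed) table")
    X = np.column_stack([np.ones(len(y)), Xmat])

    included: list[int] = []
    steps: list[dict] = []
    for _ in range(max_iter):
        changed = False
        candidates = [c for c in range(len(names)) if c not in included]
        if candidates:
            pvals = _partial_f_pvalues(X, y, included, candidates)
            best = min(candidates, key=lambda c: (pvals[c], names[c]))
            if pvals[best] < p_enter:
                included.append(best)
                steps.append({"action": "add", "feature": names[best], "p": pvals[best]})
                changed = True
        if included:
            pvals = _included_pvalues(X, y, included)
            worst = max(included, key=lambda c: (pvals[c], names[c]))
            if pvals[worst] > p_remove:
                included.remove(worst)
                steps.append(
                    {"action": "remove", "feature": names[worst], "p": pvals[worst]}
                )
                changed = True
        if not changed:
            break
    return SelectionReport(
        [names[c] for c in included], steps, list(features.index)
    )
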