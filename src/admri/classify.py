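"""LDA and RBF-SVM classifiers with run-distribution evaluation metrics.

LDA uses a multivariate normal density model with pooled within-class
covariance and uninformative priors (0.5 / 0.5) regardless of class
imbalance; the pooled covariance gets a small conditioning ridge when
needed.  The SVM is a soft-margin RBF machine (scikit-learn's libsvm-based
SVC behind this surface).  Evaluation reports the paper-standard triple
CCR / SEN / SPE on the percent scale, a 95% CI from the empirical run
distribution, and unpaired t-tests (with a Kolmogorov-Smirnov normality
check) between run distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

POSITIVE_CLASSES = ("AD", "P-MCI")  # disease-ward class per contrast


def positive_class_of(classes) -> str:
    """The disease-ward class of a contrast (SEN is its detection rate)."""
    for c in POSITIVE_CLASSES:
        if c in classes:
            return c
    return sorted(classes)[-1]


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------


@dataclass
class LdaModel:
    """Gaussian LDA: class means, pooled covariance, fixed priors."""

    classes: list
    means: np.ndarray  # (2, p)
    cov_inv: np.ndarray  # (p, p)
    priors: np.ndarray
    positive: object
    ridge_applied: float = 0.0

    @property
    def n_features(self) -> int:
        return self.means.shape[1]


def lda_fit(X: np.ndarray, y, priors=(0.5, 0.5)) -> LdaModel:
    """Fit class means and pooled within-class covariance.

    With n <= dim the covariance is conditioned with a logged ridge
    ``eps * trace(S) / dim * I`` (eps = 1e-6); a still-singular matrix
    raises.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    if len(classes) != 2:
        raise ValueError("LDA here is two-class")
    p = X.shape[1]
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    n = len(y)
    S = np.zeros((p, p))
    for i, c in enumerate(classes):
        d = X[y == c] - means[i]
        S += d.T @ d
    S /= max(n - 2, 1)
    ridge = 0.0
    eigmin = np.linalg.eigvalsh(S).min() if p else 1.0
    if n <= p or eigmin < 1e-10:
        ridge = 1e-6 * np.trace(S) / max(p, 1)
        ridge = max(ridge, 1e-12)
        S = S + ridge * np.eye(p)
    try:
        cov_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance singular after conditioning"
        ) from exc
    return LdaModel(
        classes,
        means,
        cov_inv,
        np.asarray(priors, dtype=float),
        positive_class_of(classes),
        ridge,
    )


def lda_decision(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """delta_k(x) = x' S^-1 mu_k - mu_k' S^-1 mu_k / 2 + ln pi_k, (n, 2)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension {model.n_features}"
        )
    out = np.empty((X.shape[0], 2))
    for k in range(2):
        mu = model.means[k]
        out[:, k] = (
            X @ model.cov_inv @ mu
            - 0.5 * mu @ model.cov_inv @ mu
            + np.log(model.priors[k])
        )
    return out


def lda_predict(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """argmax_k delta_k(x); an exact tie goes to the positive class."""
    d = lda_decision(model, X)
    pos_idx = model.classes.index(model.positive)
    neg_idx = 1 - pos_idx
    pick_pos = d[:, pos_idx] >= d[:, neg_idx]
    return np.where(pick_pos, model.positive, model.classes[neg_idx])


# ---------------------------------------------------------------------------
# SVM
# ---------------------------------------------------------------------------


@dataclass
class SvmModel:
    """RBF-kernel soft-margin SVM (libsvm-backed)."""

    svc: SVC
    classes: list
    positive: object
    gamma: float
    C: float


def svm_fit(
    X: np.ndarray,
    y,
    C: float = 1.0,
    gamma: float | str = "scale",
    tol: float = 1e-4,
) -> SvmModel:
    """Soft-margin dual with RBF kernel k(x,x') = exp(-gamma ||x-x'||^2).

    The default gamma = 1 / (n_features * var(X)) follows the standard
    library guideline.  Non-convergence within the iteration cap raises.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = sorted(np.unique(y).tolist())
    svc = SVC(C=C, kernel="rbf", gamma=gamma, tol=tol, max_iter=200000)
    svc.fit(X, y)
    if svc.fit_status_ != 0:
        raise RuntimeError("SVM failed to converge within the iteration cap")
    g = svc._gamma if isinstance(gamma, str) else gamma
    return SvmModel(svc, classes, positive_class_of(classes), float(g), C)


def svm_decision(model: SvmModel, X: np.ndarray) -> np.ndarray:
    return model.svc.decision_function(np.atleast_2d(np.asarray(X, dtype=float)))


def svm_predict(model: SvmModel, X: np.ndarray) -> np.ndarray:
    return model.svc.predict(np.atleast_2d(np.asarray(X, dtype=float)))


def fit_classifier(method: str, X, y, **kw):
    if method == "lda":
        return ("lda", lda_fit(X, y, **kw))
    if method == "svm":
        return ("svm", svm_fit(X, y, **kw))
    raise ValueError(f"unknown classifier {method!r}")


def predict_classifier(model, X):
    kind, m = model
    return lda_predict(m, X) if kind == "lda" else svm_predict(m, X)


# ---------------------------------------------------------------------------
# evaluation metrics
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    """Aggregate CCR/SEN/SPE (percent) with the 95% CI of run CCRs."""

    runs: list[tuple[float, float, float]] = field(default_factory=list)

    def add(self, ccr: float, sen: float, spe: float) -> None:
        self.runs.append((ccr, sen, spe))

    @property
    def ccrs(self) -> np.ndarray:
        return np.asarray([r[0] for r in self.runs])

    @property
    def ccr(self) -> float:
        return float(self.ccrs.mean())

    @property
    def sen(self) -> float:
        return float(np.mean([r[1] for r in self.runs if np.isfinite(r[1])]))

    @property
    def spe(self) -> float:
        return float(np.mean([r[2] for r in self.runs if np.isfinite(r[2])]))

    @property
    def ci(self) -> tuple[float, float]:
        return ci_from_runs(self.ccrs)


def evaluate(pred, truth, positive_class) -> tuple[float, float, float]:
    """(CCR, SEN, SPE) in percent; SEN w.r.t. the declared positive class.

    SEN or SPE is NaN when the test set lacks the corresponding class.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    if positive_class not in set(truth) | set(pred):
        raise ValueError(f"unknown positive class {positive_class!r}")
    correct = pred == truth
    ccr = 100.0 * correct.mean()
    pos = truth == positive_class
    sen = 100.0 * correct[pos].mean() if pos.any() else float("nan")
    spe = 100.0 * correct[~pos].mean() if (~pos).any() else float("nan")
    return float(ccr), float(sen), float(spe)


def ci_from_runs(run_ccrs, method: str = "percentile") -> tuple[float, float]:
    """95% CI of the run-CCR distribution.

    'percentile': empirical 2.5th/97.5th percentiles (linear interpolation);
    'normal': mean +/- 1.96 sd.
    """
    runs = np.asarray(run_ccrs, dtype=float)
    if runs.size < 2:
        raise ValueError("need at least 2 runs")
    if method == "percentile":
        lo, hi = np.percentile(runs, [2.5, 97.5])
    elif method == "normal":
        m, s = runs.mean(), runs.std(ddof=1)
        lo, hi = m - 1.96 * s, m + 1.96 * s
    else:
        raise ValueError(f"unknown CI method {method!r}")
    return float(lo), float(hi)


def compare_runs(runs_a, runs_b, alpha: float = 1e-4):
    """Unpaired t-test between run distributions, with KS normality check.

    Returns (t, p, significant, ks_normality_pass): each sample is tested
    against a normal fitted to it (KS at 0.05); the group comparison is an
    unequal-variance two-sample t-test, significant at the stated alpha.
    """
    a = np.asarray(runs_a, dtype=float)
    b = np.asarray(runs_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 runs per sample")

    def _ks_pass(x):
        s = x.std(ddof=1)
        if s < 1e-12:
            return True  # degenerate constant sample
        return stats.kstest(x, "norm", args=(x.mean(), s)).pvalue > 0.05

    ks_pass = _ks_pass(a) and _ks_pass(b)
    if a.std() < 1e-12 and b.std() < 1e-12:
        t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), bool(p < alpha), bool(ks_pass)
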