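"""PCA exploration and PLS class prediction from preprocessed spectra.

The screening workflow regresses *class numbers* of a risk index (an
ordinal encoding of the classification schemes) on the spectra with
partial least squares (PLS), validates with full (leave-one-out)
cross-validation, rounds the continuous prediction to the nearest whole
number, and reports per-class and overall accuracy.  Binary variants
(contaminated / not at a given threshold) use a 0/1 target with the same
round-then-clip rule, which puts the decision point at 0.5.

Treating an ordinal class number as a numeric regression target is
statistically unconventional but is exactly the screening procedure this
package implements; it keeps a single latent-variable model per index.

Latent-variable count: chosen by minimum RMSECV over 1..cap (default cap
10) when not forced.  Model fitting itself is deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA as _SkPCA

from .spectral_processing import PreprocessChain

__all__ = [
    "PCAResult",
    "PLSClassModel",
    "ClassPredictionReport",
    "pca",
    "loo_predictions",
    "pls_fit",
    "predict_class",
    "evaluate",
    "fit_binary",
    "teq_threshold_suite",
    "important_regions",
]

logger = logging.getLogger(__name__)

DEFAULT_LATENT_CAP = 10


@dataclass
class PCAResult:
    scores: np.ndarray  # samples × components
    loadings: np.ndarray  # components × wavelengths, rows orthonormal
    explained_variance: np.ndarray  # percent per component, non-increasing
    mean: np.ndarray


def pca(X: np.ndarray, n_components: int | None = None) -> PCAResult:
    """Principal component analysis of a samples × wavelengths matrix.

    Mean-centering is applied internally; loadings are orthonormal and
    ``scores @ loadings + mean`` reconstructs the data when all components
    are kept.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("PCA needs a 2-D matrix with at least 2 samples")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return PCAResult(
        scores=scores,
        loadings=model.components_,
        explained_variance=100.0 * model.explained_variance_ratio_,
        mean=model.mean_,
    )


@dataclass
class ClassPredictionReport:
    overall_accuracy: float  # percent
    per_class_accuracy: dict[int, float]  # percent; absent classes omitted
    confusion: pd.DataFrame  # true class × predicted class counts
    n: int


@dataclass
class PLSClassModel:
    """Fitted PLS model predicting a class number from a spectrum."""

    n_latent: int
    coefficients: np.ndarray  # per wavelength
    intercept: float
    wavelengths: np.ndarray
    class_set: tuple[int, ...]  # ordered classes present in training
    cv_predictions: np.ndarray  # LOO continuous prediction per training sample
    cv_true: np.ndarray
    rmsecv: float
    task: str  # "multiclass" or "binary:<threshold>"
    preprocess_chain: PreprocessChain = field(
        default_factory=lambda: PreprocessChain(())
    )
    rmsecv_by_latent: dict[int, float] = field(default_factory=dict)

    def predict_raw(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.wavelengths.size:
            raise ValueError(
                f"spectra have {X.shape[1]} channels but the model was trained "
                f"on {self.wavelengths.size}"
            )
        if self.preprocess_chain.steps:
            X = self.preprocess_chain.apply_matrix(self.wavelengths, X)
        return X @ self.coefficients + self.intercept


def _fit_pls(X: np.ndarray, y: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Fit PLS and return the equivalent plain affine map (coef, intercept)."""
    model = PLSRegression(n_components=k, scale=False)
    model.fit(X, y.reshape(-1, 1))
    coef = model.coef_.ravel()
    # fold centering into the intercept: the fitted predictor is affine,
    # so its value at the zero spectrum is the intercept
    intercept = float(model.predict(np.zeros((1, X.shape[1]))).ravel()[0])
    return coef, intercept


def loo_predictions(X: np.ndarray, y: np.ndarray, n_latent: int) -> np.ndarray:
    """Leave-one-out continuous predictions: sample i predicted by a model
    fitted on all other samples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        k = min(n_latent, mask.sum() - 1, X.shape[1])
        coef, intercept = _fit_pls(X[mask], y[mask], k)
        preds[i] = X[i] @ coef + intercept
    return preds


def pls_fit(
    X: np.ndarray,
    y: Sequence[float],
    n_latent: int | None = None,
    max_latent: int = DEFAULT_LATENT_CAP,
    preprocess_chain: PreprocessChain | None = None,
    wavelengths: np.ndarray | None = None,
    task: str = "multiclass",
) -> PLSClassModel:
    """Fit a PLS class model with full (leave-one-out) cross-validation.

    ``y`` holds class numbers (or 0/1 labels for binary tasks).  If
    ``preprocess_chain`` is given it is applied to ``X`` before fitting and
    stored in the model so prediction enforces the same chain.  When
    ``n_latent`` is None the count minimising RMSECV over 1..cap is chosen.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per element of y")
    if np.ptp(y) == 0:
        raise ValueError("degenerate target: y has zero variance")
    if wavelengths is None:
        wavelengths = np.arange(X.shape[1], dtype=float)
    chain = preprocess_chain or PreprocessChain(())
    Xp = chain.apply_matrix(wavelengths, X) if chain.steps else X

    n = X.shape[0]
    cap = min(max_latent, n - 2, Xp.shape[1])
    if cap < 1:
        raise ValueError(f"too few samples ({n}) for PLS with LOO validation")
    if n_latent is not None:
        if not (1 <= n_latent <= min(n - 1, Xp.shape[1])):
            raise ValueError(f"n_latent {n_latent} outside [1, {min(n - 1, Xp.shape[1])}]")
        candidates = [n_latent]
    else:
        candidates = list(range(1, cap + 1))

    rmsecv_by_latent: dict[int, float] = {}
    best_k, best_preds, best_rmse = None, None, np.inf
    for k in candidates:
        preds = loo_predictions(Xp, y, k)
        rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
        rmsecv_by_latent[k] = rmse
        if rmse < best_rmse:
            best_k, best_preds, best_rmse = k, preds, rmse
    logger.info("PLS %s: chose %d latent variable(s), RMSECV=%.4g", task, best_k, best_rmse)

    coef, intercept = _fit_pls(Xp, y, best_k)
    class_set = tuple(sorted({int(round(v)) for v in y}))
    return PLSClassModel(
        n_latent=best_k,
        coefficients=coef,
        intercept=intercept,
        wavelengths=np.asarray(wavelengths, dtype=float),
        class_set=class_set,
        cv_predictions=best_preds,
        cv_true=y.copy(),
        rmsecv=best_rmse,
        task=task,
        preprocess_chain=chain,
        rmsecv_by_latent=rmsecv_by_latent,
    )


def _round_half_away(values: np.ndarray) -> np.ndarray:
    return np.sign(values) * np.floor(np.abs(values) + 0.5)


def round_to_class_set(raw: np.ndarray, class_set: Sequence[int]) -> np.ndarray:
    """Round half away from zero, clip to the class range, snap to the
    nearest class present in training (relevant when a class is absent)."""
    classes = np.asarray(sorted(class_set))
    rounded = _round_half_away(np.asarray(raw, dtype=float))
    rounded = np.clip(rounded, classes.min(), classes.max())
    idx = np.abs(rounded[:, None] - classes[None, :]).argmin(axis=1)
    return classes[idx].astype(int)


def predict_class(model: PLSClassModel, X: np.ndarray) -> np.ndarray:
    """Predict class numbers: continuous PLS output rounded to the nearest
    whole number (halves away from zero), clipped to the model's class set."""
    return round_to_class_set(model.predict_raw(X), model.class_set)


def evaluate(model: PLSClassModel, y_true: Sequence[int] | None = None) -> ClassPredictionReport:
    """Accuracy report from the model's leave-one-out predictions.

    Classes absent from the data are omitted from ``per_class_accuracy``
    (reported as "n/a" by the text renderers).
    """
    true = np.asarray(model.cv_true if y_true is None else y_true)
    true = np.asarray([int(round(v)) for v in true])
    pred = round_to_class_set(model.cv_predictions, model.class_set)
    if true.size != pred.size:
        raise ValueError("y_true length does not match the CV predictions")
    labels = sorted(set(true) | set(pred))
    confusion = pd.DataFrame(0, index=labels, columns=labels)
    for t, p in zip(true, pred):
        confusion.loc[t, p] += 1
    n = true.size
    overall = 100.0 * float((true == pred).sum()) / n
    per_class = {}
    for lab in sorted(set(true)):
        sel = true == lab
        per_class[int(lab)] = 100.0 * float((pred[sel] == lab).sum()) / int(sel.sum())
    return ClassPredictionReport(overall, per_class, confusion, n)


def fit_binary(
    X: np.ndarray,
    labels: Sequence[int],
    threshold: float | None = None,
    n_latent: int | None = None,
    max_latent: int = DEFAULT_LATENT_CAP,
    preprocess_chain: PreprocessChain | None = None,
    wavelengths: np.ndarray | None = None,
) -> PLSClassModel:
    """Fit a binary (0/1) PLS screening model.

    With 0/1 encoding the round-then-clip rule places the decision point at
    0.5.  Both classes must be non-empty.
    """
    y = np.asarray(labels, dtype=float)
    present = set(np.unique(y))
    if not present <= {0.0, 1.0}:
        raise ValueError("binary labels must be 0/1")
    if len(present) < 2:
        raise ValueError("binary fit needs both classes non-empty")
    task = f"binary:{threshold:g}" if threshold is not None else "binary"
    return pls_fit(
        X, y, n_latent=n_latent, max_latent=max_latent,
        preprocess_chain=preprocess_chain, wavelengths=wavelengths, task=task,
    )


def teq_threshold_suite(
    X: np.ndarray,
    teq_values: Sequence[float],
    ladder: Sequence[float] = (15.0, 100.0, 200.0, 600.0, 1000.0, 2000.0, 4000.0, 10000.0),
    n_latent: int | None = None,
    max_latent: int = DEFAULT_LATENT_CAP,
    preprocess_chain: PreprocessChain | None = None,
    wavelengths: np.ndarray | None = None,
) -> dict[float, tuple[PLSClassModel, ClassPredictionReport]]:
    """One independent binary model per TEQ guideline threshold.

    Thresholds that leave one side empty are skipped with a logged notice
    (e.g. no samples below the most conservative residential value).
    """
    teq_values = np.asarray(teq_values, dtype=float)
    out: dict[float, tuple[PLSClassModel, ClassPredictionReport]] = {}
    for thr in ladder:
        labels = (teq_values >= thr).astype(int)
        if labels.min() == labels.max():
            logger.info("TEQ threshold %g skipped: one class is empty", thr)
            continue
        model = fit_binary(
            X, labels, threshold=thr, n_latent=n_latent, max_latent=max_latent,
            preprocess_chain=preprocess_chain, wavelengths=wavelengths,
        )
        out[float(thr)] = (model, evaluate(model))
    return out


def important_regions(
    model: PLSClassModel, q: float = 0.9
) -> list[tuple[float, float]]:
    """Contiguous wavelength intervals where |coefficient| exceeds the
    q-quantile of |coefficients| — the "important variables" regions."""
    coefs = np.abs(model.coefficients)
    if q == 0:
        mask = np.ones_like(coefs, dtype=bool)
    else:
        cutoff = np.quantile(coefs, q)
        # a zero cutoff (sparse coefficients) would flag the whole grid
        mask = coefs >= cutoff if cutoff > 0 else coefs > 0
    wl = model.wavelengths
    regions: list[tuple[float, float]] = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = wl[i]
        elif not m and start is not None:
            regions.append((float(start), float(wl[i - 1])))
            start = None
    if start is not None:
        regions.append((float(start), float(wl[-1])))
    return regions
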