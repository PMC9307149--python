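"""The machine-learning decoding arm: CSP spatial filters + LDA.

Common Spatial Patterns solves the generalized eigenproblem of the two
trial-averaged, trace-normalized class covariances; each eigenvector is a
spatial filter whose output variance is maximal for one class and minimal
for the other.  Projected trials Z = W E yield log-variance features of the
m most discriminative filters from each end of the eigenvalue spectrum,
classified by a closed-form linear discriminant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg

from . import evaluate
from .preprocess import FilterBank, apply_filter_bank
from .records import EvalResult
from .simulate import EpochSet

log = logging.getLogger(__name__)

VAR_FLOOR = 1e-30  # clamp for zero-variance components before the log


@dataclass
class CSPModel:
    """Fitted CSP: rows of W are spatial filters, ordered by descending
    generalized eigenvalue (class-0 variance share); ``selected`` indexes the
    m first and m last rows."""

    W: np.ndarray  # (c, c)
    eigenvalues: np.ndarray  # (c,), descending
    selected: np.ndarray  # (2m,) row indices
    band: Optional[Tuple[float, float]] = None
    c: int = 0

    def __post_init__(self) -> None:
        self.c = self.W.shape[0]
        if self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square (c x c)")


@dataclass
class LDAModel:
    """Closed-form linear discriminant: w = pooled_cov^-1 (mu1 - mu0)."""

    w: np.ndarray
    b: float
    class_means: np.ndarray  # (2, d)
    pooled_cov: np.ndarray  # (d, d)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.w + self.b


def trial_covariances(data: np.ndarray, trace_normalize: bool = True) -> np.ndarray:
    """Per-trial spatial covariance E Eᵀ, optionally trace-normalized.

    Trace normalization removes per-trial amplitude scale so the class
    averages are not dominated by a few high-power trials (standard CSP
    conditioning).
    """
    cov = np.einsum("tcs,tds->tcd", data, data)
    if trace_normalize:
        tr = np.trace(cov, axis1=1, axis2=2)[:, None, None]
        cov = cov / tr
    else:
        cov = cov / data.shape[-1]
    return cov


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Deterministic filter signs: largest-|coefficient| entry made positive."""
    idx = np.argmax(np.abs(W), axis=1)
    signs = np.sign(W[np.arange(W.shape[0]), idx])
    signs[signs == 0] = 1.0
    return W * signs[:, None]


def fit_csp(epochs: EpochSet, m: int = 3, trace_normalize: bool = True,
            band: Optional[Tuple[float, float]] = None) -> CSPModel:
    """Fit CSP on a band-filtered epoch set.

    Solves Σ₀ w = λ (Σ₀ + Σ₁) w for the averaged class covariances; rows of
    W are the eigenvector filters sorted by descending λ, so the first rows
    maximize class-0 (left) variance share and the last rows class-1's.
    """
    labels = epochs.labels
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("CSP needs exactly two classes in the labels")
    c = epochs.n_channels
    if 2 * m > c:
        raise ValueError(f"2m = {2 * m} exceeds channel count {c}")
    cov = trial_covariances(epochs.data, trace_normalize)
    s0 = cov[labels == classes[0]].mean(axis=0)
    s1 = cov[labels == classes[1]].mean(axis=0)
    composite = s0 + s1
    # guard: composite must be positive definite for the generalized eigenproblem
    min_eig = linalg.eigvalsh(composite)[0]
    if min_eig <= 1e-12 * np.trace(composite) / c:
        raise np.linalg.LinAlgError(
            "composite covariance is singular; consider ridge-regularizing the "
            "per-trial covariances or removing flat channels")
    evals, evecs = linalg.eigh(s0, composite)
    order = np.argsort(evals)[::-1]  # descending; ties keep ascending index order
    evals = evals[order]
    W = _fix_signs(evecs[:, order].T)
    selected = np.concatenate([np.arange(m), np.arange(c - m, c)])
    return CSPModel(W=W, eigenvalues=evals, selected=selected, band=band)


def apply_csp(model: CSPModel, epochs: EpochSet) -> np.ndarray:
    """Project every trial: Z_i = W E_i, shape (trials, c, samples)."""
    if epochs.n_channels != model.c:
        raise ValueError(
            f"epoch channel count {epochs.n_channels} != model c {model.c}")
    return np.einsum("fc,tcs->tfs", model.W, epochs.data)


def csp_features(Z: np.ndarray, selected: Sequence[int]) -> np.ndarray:
    """Log-variance of the selected projected components, per trial."""
    selected = np.asarray(selected)
    if np.any(selected < 0) or np.any(selected >= Z.shape[1]):
        raise ValueError("selected indices out of range")
    var = Z[:, selected, :].var(axis=-1)
    if np.any(var <= VAR_FLOOR):
        warnings.warn("zero-variance CSP component; clamping before log")
        var = np.maximum(var, VAR_FLOOR)
    return np.log(var)


def fit_lda(features: np.ndarray, labels: Sequence[int],
            ridge: float = 1e-8) -> LDAModel:
    """Closed-form two-class LDA with a relative ridge fallback.

    w = S⁻¹(μ₁ − μ₀), b = −w·(μ₀ + μ₁)/2, with S the pooled within-class
    covariance; a ridge of ``ridge × trace(S)/d`` is added when S is
    ill-conditioned.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("LDA needs exactly two classes")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    mu0, mu1 = X0.mean(axis=0), X1.mean(axis=0)
    n0, n1 = len(X0), len(X1)
    S = ((X0 - mu0).T @ (X0 - mu0) + (X1 - mu1).T @ (X1 - mu1)) / (n0 + n1 - 2)
    d = X.shape[1]
    try:
        w = linalg.solve(S, mu1 - mu0, assume_a="pos")
    except linalg.LinAlgError:
        w = None
    if w is None or not np.all(np.isfinite(w)) or np.linalg.cond(S) > 1e12:
        if ridge <= 0:
            raise np.linalg.LinAlgError("singular pooled covariance and no ridge")
        log.info("pooled covariance near-singular; applying ridge %.1e", ridge)
        S = S + ridge * np.trace(S) / d * np.eye(d)
        w = linalg.solve(S, mu1 - mu0, assume_a="pos")
    b = -float(w @ (mu0 + mu1) / 2)
    return LDAModel(w=w, b=b, class_means=np.stack([mu0, mu1]), pooled_cov=S)


def predict_lda(model: LDAModel, features: np.ndarray) -> np.ndarray:
    """Class labels (0/1) from the sign of the decision value."""
    return (model.decision_function(features) > 0).astype(int)


@dataclass(frozen=True)
class MLConfig:
    """End-to-end CSP+LDA pipeline settings."""

    bank: FilterBank = FilterBank()
    m_pairs: int = 3
    trace_normalize: bool = True
    ridge: float = 1e-8
    train_fraction: float = 0.8
    split_seed: int = 0


def run_ml_pipeline(epochs: EpochSet, config: MLConfig = MLConfig()) -> EvalResult:
    """Filter bank → CSP → log-variance features → LDA, leakage-free.

    CSP and LDA are fitted strictly on the training fold of a stratified
    80/20 split; the same split seed used by the CNN arm yields the
    identical partition, so the two decoders are compared on the same
    test trials.
    """
    train_idx, test_idx = evaluate.train_test_split(
        epochs.n_trials, epochs.labels, config.train_fraction, config.split_seed)
    banded = apply_filter_bank(epochs, config.bank)
    feats_train: List[np.ndarray] = []
    feats_test: List[np.ndarray] = []
    for band_epochs, band in zip(banded, config.bank.bands):
        sub_train = EpochSet(band_epochs.data[train_idx], band_epochs.labels[train_idx],
                             band_epochs.fs, tuple(band_epochs.channel_names))
        csp = fit_csp(sub_train, m=config.m_pairs,
                      trace_normalize=config.trace_normalize, band=band)
        feats_train.append(csp_features(
            apply_csp(csp, sub_train), csp.selected))
        sub_test = EpochSet(band_epochs.data[test_idx], band_epochs.labels[test_idx],
                            band_epochs.fs, tuple(band_epochs.channel_names))
        feats_test.append(csp_features(apply_csp(csp, sub_test), csp.selected))
    X_train = np.hstack(feats_train)
    X_test = np.hstack(feats_test)
    y_train = epochs.labels[train_idx]
    y_test = epochs.labels[test_idx]
    lda = fit_lda(X_train, y_train, ridge=config.ridge)
    pred_train = predict_lda(lda, X_train)
    pred_test = predict_lda(lda, X_test)
    f_left, f_right = evaluate.f_score_per_class(pred_test, y_test)
    return EvalResult(
        model_tag="CSP+LDA",
        train_accuracy=evaluate.accuracy(pred_train, y_train),
        test_accuracy=evaluate.accuracy(pred_test, y_test),
        f_score_left=f_left, f_score_right=f_right,
        split_seed=config.split_seed,
    )
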