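"""Continuous workload decoding: PCA-truncation denoising plus lasso
regression inside trial-granular nested cross-validation.

The outer 10-fold loop estimates generalization; the inner 10-fold loop,
run on outer-training trials only, jointly selects the retained
principal-component count k and the lasso penalty lambda by pooled Pearson
correlation of inner-validation predictions.  Folds partition *trials*, not
samples, so temporally autocorrelated neighbors never straddle a split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

from .preprocessing import LabeledSampleSet

__all__ = [
    "PCATruncation", "LassoModel", "CVScheme", "FoldModel", "DecodingResult",
    "fit_pca_truncation", "apply_pca_truncation", "fit_lasso", "lambda_max",
    "make_lambda_grid", "nested_cv_decode", "decode_peripheral", "pearson_r",
    "DEFAULT_K_GRID",
]

#: candidate retained-PC counts; None stands for "all channels"
DEFAULT_K_GRID: tuple = (1, 2, 3, 5, 8, 12, 17, 25, 35, 50, None)


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Product-moment correlation; raises on constant or mismatched input."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("inputs must share a length >= 2")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(stats.pearsonr(a, b).statistic)


# ------------------------------------------------------------------ PCA ---

@dataclass
class PCATruncation:
    component_basis: np.ndarray    # k x channel, orthonormal rows
    k: int
    training_mean: np.ndarray      # per channel
    explained_variance: np.ndarray  # per retained component, decreasing


def _full_pca(train: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decomposition of the training covariance, components ordered by
    decreasing variance, sign fixed so each component's largest-magnitude
    loading is positive."""
    mean = train.mean(axis=0)
    x = train - mean
    cov = x.T @ x / max(len(x) - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    comps = evecs[:, order].T
    flip = np.sign(comps[np.arange(len(comps)),
                         np.argmax(np.abs(comps), axis=1)])
    comps *= flip[:, None]
    return mean, comps, evals


def fit_pca_truncation(train: np.ndarray, k: int) -> PCATruncation:
    train = np.asarray(train, float)
    n, p = train.shape
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}]")
    if n <= k:
        raise ValueError("need more training samples than components")
    mean, comps, evals = _full_pca(train)
    return PCATruncation(comps[:k], k, mean, evals[:k])


def apply_pca_truncation(model: PCATruncation, data: np.ndarray) -> np.ndarray:
    """Project onto the retained components and back: channel-space output,
    an idempotent denoising of the off-subspace variance."""
    data = np.asarray(data, float)
    if data.shape[-1] != model.component_basis.shape[1]:
        raise ValueError("channel count does not match the fitted model")
    centered = data - model.training_mean
    return centered @ model.component_basis.T @ model.component_basis \
        + model.training_mean


# ---------------------------------------------------------------- lasso ---

@dataclass
class LassoModel:
    weights: np.ndarray            # per feature, standardized space
    intercept: float
    lam: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        xs = (np.asarray(X, float) - self.feature_mean) / self.feature_scale
        return xs @ self.weights + self.intercept


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def lambda_max(X_std: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty shrinking every weight to zero:
    max_j |x_j^T (y - ybar)| / N on standardized features."""
    yc = y - y.mean()
    return float(np.max(np.abs(X_std.T @ yc)) / len(y))


def make_lambda_grid(X_std: np.ndarray, y: np.ndarray, n: int = 50,
                     ratio: float = 1e-3) -> np.ndarray:
    lmax = lambda_max(X_std, y)
    if lmax <= 0:
        raise ValueError("labels are constant; lambda grid undefined")
    return np.geomspace(lmax, lmax * ratio, n)


def fit_lasso(X: np.ndarray, y: np.ndarray, lam: float,
              tol: float = 1e-8) -> LassoModel:
    """Minimize (1/2N)||y - b0 - Xs beta||^2 + lam * ||beta||_1 on
    z-scored features; lam = 0 falls back to least squares."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(X) != len(y) or len(y) < 2:
        raise ValueError("X must be 2-D with one row per element of y")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    xs, mean, scale = _standardize(X)
    if lam == 0:
        a = np.column_stack([np.ones(len(y)), xs])
        coef, *_ = np.linalg.lstsq(a, y, rcond=None)
        return LassoModel(coef[1:], float(coef[0]), 0.0, mean, scale)
    est = Lasso(alpha=lam, fit_intercept=True, tol=tol, max_iter=100_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(xs, y)
    return LassoModel(est.coef_.copy(), float(est.intercept_), float(lam),
                      mean, scale)


# ---------------------------------------------------------- nested CV ---

@dataclass
class CVScheme:
    outer_folds: int = 10
    inner_folds: int = 10
    seed: int = 0


@dataclass
class FoldModel:
    """Everything fitted for one outer fold (for audit / leakage checks)."""

    fold: int
    test_trials: np.ndarray
    k: int
    lam: float
    pca: PCATruncation
    lasso: LassoModel


@dataclass
class DecodingResult:
    induced: np.ndarray
    predicted: np.ndarray
    trial_id: np.ndarray
    fold_of_sample: np.ndarray
    r_mvr: float
    per_fold_r: list[float]
    chosen_k: list[int]
    chosen_lambda: list[float]
    channel_subset_label: str = "whole-head"
    fold_models: list[FoldModel] = field(default_factory=list)

    def trace_frame(self, time: np.ndarray | None = None) -> pd.DataFrame:
        d = {"induced": self.induced, "predicted": self.predicted,
             "trial_id": self.trial_id, "fold": self.fold_of_sample}
        if time is not None:
            d = {"time_s": time, **d}
        return pd.DataFrame(d)


def _trial_folds(trials: np.ndarray, n_folds: int,
                 rng: np.random.Generator) -> list[np.ndarray]:
    perm = rng.permutation(np.asarray(trials))
    return [f for f in np.array_split(perm, n_folds) if len(f)]


def _path_predict(x_tr: np.ndarray, y_tr: np.ndarray, x_va: np.ndarray,
                  lams: np.ndarray) -> np.ndarray:
    """Lasso solutions along a penalty grid; returns val-set predictions,
    shape (n_val, n_lams), grid order preserved."""
    xs, mean, scale = _standardize(x_tr)
    yc = y_tr - y_tr.mean()
    order = np.argsort(lams)[::-1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = lasso_path(xs, yc, alphas=lams[order], max_iter=5000)
    xvs = (x_va - mean) / scale
    preds = xvs @ coefs + y_tr.mean()        # (n_val, n_lams) in order
    out = np.empty_like(preds)
    out[:, order] = preds
    return out


def _resolve_k_grid(k_grid, n_channels: int) -> list[int]:
    ks = sorted({n_channels if k is None else int(k)
                 for k in k_grid if k is None or 1 <= k <= n_channels})
    if not ks:
        raise ValueError("k_grid has no feasible entries")
    return ks


def nested_cv_decode(
    samples: LabeledSampleSet,
    scheme: CVScheme = CVScheme(),
    k_grid: Sequence[int | None] = DEFAULT_K_GRID,
    lam_grid: Sequence[float] | None = None,
    n_lambdas: int = 50,
    channel_subset: Sequence[int] | None = None,
    subset_label: str | None = None,
) -> DecodingResult:
    """Trial-granular nested cross-validated prediction of the induced
    workload level.

    Per outer fold, the inner loop evaluates every (k, lambda) pair by
    pooled inner-validation Pearson r (PCA, scaling and the penalty grid
    are derived from training data only); the winning pair -- ties broken
    toward the smallest k, then the largest lambda -- is refit on the full
    outer-training set and applied once to the held-out trials.
    """
    if channel_subset is not None:
        samples = samples.subset_channels(list(channel_subset))
        subset_label = subset_label or "custom"
    subset_label = subset_label or "whole-head"
    X, y = samples.features, samples.labels.astype(float)
    trial_id = samples.trial_id
    trials = np.unique(trial_id)
    if len(trials) < scheme.outer_folds:
        raise ValueError("fewer trials than outer folds")
    ks = _resolve_k_grid(k_grid, X.shape[1])

    rng = np.random.default_rng(scheme.seed)
    outer = _trial_folds(trials, scheme.outer_folds, rng)
    inner_seeds = rng.integers(0, 2**31 - 1, size=len(outer))

    predicted = np.full(len(y), np.nan)
    fold_of_sample = np.full(len(y), -1)
    per_fold_r, chosen_k, chosen_lam, models = [], [], [], []

    for f, test_trials in enumerate(outer):
        test_mask = np.isin(trial_id, test_trials)
        train_trials = trials[~np.isin(trials, test_trials)]
        tr_mask = ~test_mask
        y_tr = y[tr_mask]
        if np.ptp(y_tr) == 0:
            raise ValueError(f"constant labels in training fold {f}")
        if lam_grid is None:
            xs_tr, _, _ = _standardize(X[tr_mask])
            lams = make_lambda_grid(xs_tr, y_tr, n_lambdas)
        else:
            lams = np.asarray(sorted(lam_grid, reverse=True), float)

        # ---- inner loop: pooled validation predictions per (k, lambda)
        irng = np.random.default_rng(inner_seeds[f])
        inner = _trial_folds(train_trials, scheme.inner_folds, irng)
        preds = {k: [] for k in ks}
        actual = []
        for val_trials in inner:
            va = np.isin(trial_id, val_trials)
            it = tr_mask & ~va
            va &= tr_mask
            if it.sum() < 2 or va.sum() == 0 or np.ptp(y[it]) == 0:
                continue
            mean, comps, _ = _full_pca(X[it])
            xc_tr = X[it] - mean
            xc_va = X[va] - mean
            actual.append(y[va])
            for k in ks:
                basis = comps[:k]
                den_tr = xc_tr @ basis.T @ basis + mean
                den_va = xc_va @ basis.T @ basis + mean
                preds[k].append(_path_predict(den_tr, y[it], den_va, lams))
        if not actual:
            raise ValueError(f"no usable inner folds in outer fold {f}")
        y_val = np.concatenate(actual)

        best = (-np.inf, None, None)
        for k in ks:                       # ascending k
            pk = np.vstack(preds[k])       # (n_val, n_lams)
            for li in range(len(lams)):    # descending lambda
                p = pk[:, li]
                r = (np.corrcoef(p, y_val)[0, 1]
                     if np.ptp(p) > 0 else -np.inf)
                if np.isfinite(r) and r > best[0]:
                    best = (r, k, lams[li])
        if best[1] is None:
            best = (0.0, ks[0], lams[0])
        _, k_star, lam_star = best

        # ---- refit on the full outer-training set, predict held-out trials
        pca = fit_pca_truncation(X[tr_mask], k_star)
        den_tr = apply_pca_truncation(pca, X[tr_mask])
        model = fit_lasso(den_tr, y_tr, float(lam_star), tol=1e-6)
        den_te = apply_pca_truncation(pca, X[test_mask])
        p_te = model.predict(den_te)

        predicted[test_mask] = p_te
        fold_of_sample[test_mask] = f
        per_fold_r.append(pearson_r(p_te, y[test_mask])
                          if np.ptp(p_te) > 0 and np.ptp(y[test_mask]) > 0
                          else float("nan"))
        chosen_k.append(int(k_star))
        chosen_lam.append(float(lam_star))
        models.append(FoldModel(f, np.asarray(test_trials), int(k_star),
                                float(lam_star), pca, model))

    assert not np.isnan(predicted).any()
    r_mvr = pearson_r(predicted, y)
    return DecodingResult(y, predicted, trial_id, fold_of_sample, r_mvr,
                          per_fold_r, chosen_k, chosen_lam, subset_label,
                          models)


def decode_peripheral(
    trials: pd.DataFrame,
    scheme: CVScheme = CVScheme(),
    features: Sequence[str] = ("heart_rate", "rmssd"),
    n_lambdas: int = 50,
) -> DecodingResult:
    """Workload decoding from trial-wise cardiac parameters (a 2-D feature
    space) with the same nested-CV lasso machinery, one sample per trial."""
    missing = [f for f in features if f not in trials.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")
    df = trials.dropna(subset=list(features))
    if df["trial_index"].duplicated().any():
        raise ValueError("one row per trial required (single participant)")
    samples = LabeledSampleSet(
        df[list(features)].to_numpy(float),
        df["nback_level"].to_numpy(float),
        df["trial_index"].to_numpy(),
        np.arange(len(df), dtype=float),
        list(range(1, len(features) + 1)),
    )
    return nested_cv_decode(samples, scheme, k_grid=(1, len(features)),
                            n_lambdas=n_lambdas, subset_label="peripheral")
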