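"""Gaussian process regression with an automatic-relevance-determination
squared-exponential kernel, mapping band reflectance to LAI.

The predictive model is

    f(x) = sum_i a_i K(x_i, x) + alpha_0,
    K(x, x') = nu * exp( -sum_b (x_b - x'_b)^2 / (2 sigma_b^2) ),

with one length-scale sigma_b per band, an overall scale nu and an
observation-noise standard deviation sigma_n added on the Gram
diagonal.  The bias alpha_0 is realized by centring the targets on
their mean.  Hyperparameters are fitted by maximizing the log marginal
likelihood with a quasi-Newton ascent in log-parameter space (analytic
gradients, multiple seeded restarts).  Because a small sigma_b means
the output is allowed to vary quickly along band b, the inverse
length-scales double as a band-relevance ranking.

Inputs are standardized (per-band z-score from training statistics)
before kernel evaluation, so fitted length-scales are comparable across
bands of different dynamic range.

Predictions come with a predictive variance,
nu + sigma_n^2 - k*^T (K + sigma_n^2 I)^{-1} k*, usable as a per-pixel
uncertainty estimate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "GPRModel",
    "Prediction",
    "ValidationReport",
    "ard_kernel",
    "fit",
    "predict",
    "band_relevance",
    "cross_validate",
    "regression_metrics",
]

_JITTER = 1e-10


@dataclass(frozen=True)
class Prediction:
    """Posterior mean (LAI) and variance (LAI² units)."""

    mean: np.ndarray
    variance: np.ndarray


@dataclass(frozen=True)
class ValidationReport:
    """Agreement between predicted and observed values.

    ``r2`` is the coefficient of determination of the least-squares fit
    of predicted on observed (squared Pearson correlation); ``r2_identity``
    scores agreement with the 1:1 line (Nash-Sutcliffe form) and is <= r2.
    """

    r2: float
    rmse: float
    n: int
    slope: float
    intercept: float
    r2_identity: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a validation report needs at least 2 samples")
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")


def regression_metrics(predicted: np.ndarray, observed: np.ndarray) -> ValidationReport:
    """Least-squares fit of predicted on observed plus error statistics."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if p.size < 2:
        raise ValueError("need at least 2 samples")
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    o_var = np.var(o)
    if o_var == 0:
        slope, intercept, r2 = 0.0, float(np.mean(p)), 0.0
    else:
        slope = float(np.cov(o, p, bias=True)[0, 1] / o_var)
        intercept = float(np.mean(p) - slope * np.mean(o))
        p_var = np.var(p)
        r2 = 0.0 if p_var == 0 else float(
            np.cov(o, p, bias=True)[0, 1] ** 2 / (o_var * p_var)
        )
    r2_identity = float(1.0 - np.sum((p - o) ** 2) / np.sum((o - o.mean()) ** 2)) if o_var else 0.0
    return ValidationReport(
        r2=r2,
        rmse=rmse,
        n=p.size,
        slope=slope,
        intercept=intercept,
        r2_identity=r2_identity,
    )


@dataclass
class GPRModel:
    """Trained GPR: kernel hyperparameters, weights and training spectra."""

    X_train: np.ndarray  # standardized (n, B)
    weights: np.ndarray  # a_i = (K + sigma_n^2 I)^-1 (y - alpha_0)
    bias: float  # alpha_0 = mean of training targets
    nu: float
    sigma_b: np.ndarray  # (B,) length-scales in standardized units
    sigma_n: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    band_names: tuple[str, ...] = ()
    log_evidence: float = np.nan
    _chol: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_bands(self) -> int:
        return self.X_train.shape[1]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale

    def cholesky(self) -> np.ndarray:
        if self._chol is None:
            K = ard_kernel(self.X_train, self.X_train, self.nu, self.sigma_b)
            K[np.diag_indices_from(K)] += self.sigma_n**2 + _JITTER * self.nu
            self._chol = linalg.cholesky(K, lower=True)
        return self._chol

    def save(self, directory) -> None:
        """JSON sidecar + CSV of training spectra/weights; bit-exact."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "bias": self.bias,
            "nu": self.nu,
            "sigma_b": self.sigma_b.tolist(),
            "sigma_n": self.sigma_n,
            "x_mean": self.x_mean.tolist(),
            "x_scale": self.x_scale.tolist(),
            "band_names": list(self.band_names),
            "log_evidence": self.log_evidence,
        }
        (d / "gpr_model.json").write_text(json.dumps(meta, indent=2))
        cols = list(self.band_names) or [f"b{i}" for i in range(self.n_bands)]
        df = pd.DataFrame(self.X_train, columns=cols)
        df["weight"] = self.weights
        df.to_csv(d / "gpr_train.csv", index=False, float_format="%.17g")

    @classmethod
    def load(cls, directory) -> "GPRModel":
        d = Path(directory)
        meta = json.loads((d / "gpr_model.json").read_text())
        df = pd.read_csv(d / "gpr_train.csv", float_precision="round_trip")
        weights = df.pop("weight").to_numpy()
        return cls(
            X_train=df.to_numpy(),
            weights=weights,
            bias=meta["bias"],
            nu=meta["nu"],
            sigma_b=np.asarray(meta["sigma_b"]),
            sigma_n=meta["sigma_n"],
            x_mean=np.asarray(meta["x_mean"]),
            x_scale=np.asarray(meta["x_scale"]),
            band_names=tuple(meta["band_names"]),
            log_evidence=meta["log_evidence"],
        )


def ard_kernel(
    Xa: np.ndarray, Xb: np.ndarray, nu: float, sigma_b: np.ndarray
) -> np.ndarray:
    """ARD squared-exponential covariance between two sets of vectors.

    K(x, x') = nu * exp(-sum_b (x_b - x'_b)^2 / (2 sigma_b^2)).  The
    observation-noise term sigma_n^2 delta_ij belongs on the Gram
    diagonal, not here.
    """
    Xa = np.atleast_2d(np.asarray(Xa, dtype=float))
    Xb = np.atleast_2d(np.asarray(Xb, dtype=float))
    if Xa.shape[1] != Xb.shape[1]:
        raise ValueError("band-vector lengths differ")
    sigma_b = np.asarray(sigma_b, dtype=float)
    if sigma_b.size != Xa.shape[1]:
        raise ValueError("one length-scale per band required")
    A = Xa / sigma_b
    B = Xb / sigma_b
    d2 = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return nu * np.exp(-0.5 * np.clip(d2, 0.0, None))


def _nll_and_grad(log_theta: np.ndarray, X: np.ndarray, y: np.ndarray):
    """Negative log marginal likelihood and gradient in log-parameters.

    log_theta = [log nu, log sigma_n, log sigma_1..log sigma_B].
    """
    n, B = X.shape
    nu = np.exp(log_theta[0])
    sigma_n = np.exp(log_theta[1])
    sigma_b = np.exp(log_theta[2:])

    K = ard_kernel(X, X, nu, sigma_b)
    Ky = K + (sigma_n**2 + _JITTER * nu) * np.eye(n)
    try:
        L = linalg.cholesky(Ky, lower=True)
    except linalg.LinAlgError:
        return 1e25, np.zeros_like(log_theta)
    alpha = linalg.cho_solve((L, True), y)
    nll = (
        0.5 * y @ alpha
        + np.sum(np.log(np.diag(L)))
        + 0.5 * n * np.log(2.0 * np.pi)
    )

    Kinv = linalg.cho_solve((L, True), np.eye(n))
    W = np.outer(alpha, alpha) - Kinv  # dLML/dtheta = 0.5 tr(W dK/dtheta)

    grad = np.empty_like(log_theta)
    # d/dlog nu: dK = K (noise-free part)
    grad[0] = -0.5 * np.sum(W * K)
    # d/dlog sigma_n: dK = 2 sigma_n^2 I
    grad[1] = -0.5 * np.trace(W) * 2.0 * sigma_n**2
    # d/dlog sigma_b: dK = K * D_b / sigma_b^2
    WK = W * K
    for b in range(B):
        db = (X[:, b][:, None] - X[:, b][None, :]) ** 2
        grad[2 + b] = -0.5 * np.sum(WK * db) / sigma_b[b] ** 2
    return float(nll), grad


def fit(
    X: np.ndarray,
    y: np.ndarray,
    restarts: int = 5,
    seed: int = 0,
    optimize_hyperparameters: bool = True,
    init: dict | None = None,
    max_opt_points: int = 600,
    maxiter: int = 60,
    band_names: tuple[str, ...] = (),
) -> GPRModel:
    """Train the GPR by maximizing the log marginal likelihood.

    ``restarts`` seeded initializations are run and the best kept; the
    first restart starts from a robust default (unit length-scales in
    standardized units, nu = var(y), sigma_n = 0.1 sd(y)), later ones
    from log-normal perturbations of it.  When the training set exceeds
    ``max_opt_points``, hyperparameters are optimized on a seeded
    subset of that size and the weights are then solved on the full
    set — the standard cost-control for cubic-scaling GP training.
    ``init`` may fix {"nu", "sigma_n", "sigma_b"} and skip optimization
    via ``optimize_hyperparameters=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n_samples, n_bands)")
    n, B = X.shape
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if y.shape != (n,):
        raise ValueError("y must be 1-D with one target per row of X")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("training data must be finite")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    Xs = (X - x_mean) / x_scale
    bias = float(y.mean())
    yc = y - bias
    y_sd = float(yc.std()) or 1.0

    init = dict(init or {})
    nu0 = float(init.get("nu", y_sd**2))
    sn0 = float(init.get("sigma_n", 0.1 * y_sd))
    sb0 = np.atleast_1d(
        np.asarray(init.get("sigma_b", np.ones(B) * np.sqrt(B)), dtype=float)
    )
    if sb0.size == 1:
        sb0 = np.full(B, sb0[0])

    if optimize_hyperparameters:
        rng = np.random.default_rng(seed)
        if n > max_opt_points:
            sub = rng.choice(n, size=max_opt_points, replace=False)
            Xo, yo = Xs[sub], yc[sub]
        else:
            Xo, yo = Xs, yc
        theta0 = np.log(np.concatenate([[max(nu0, 1e-12)], [max(sn0, 1e-6)], sb0]))
        best = None
        for r in range(max(restarts, 1)):
            t0 = theta0 if r == 0 else theta0 + rng.normal(0, 0.5, theta0.size)
            res = optimize.minimize(
                _nll_and_grad,
                t0,
                args=(Xo, yo),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": maxiter},
            )
            if best is None or res.fun < best.fun:
                best = res
        theta = best.x
        nu = float(np.exp(theta[0]))
        sigma_n = float(np.exp(theta[1]))
        sigma_b = np.exp(theta[2:])
        log_evidence = -float(best.fun)
    else:
        nu, sigma_n, sigma_b = nu0, sn0, sb0
        log_evidence = np.nan

    K = ard_kernel(Xs, Xs, nu, sigma_b)
    K[np.diag_indices_from(K)] += sigma_n**2 + _JITTER * nu
    try:
        L = linalg.cholesky(K, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "Gram matrix numerically singular even after jitter"
        ) from exc
    weights = linalg.cho_solve((L, True), yc)

    return GPRModel(
        X_train=Xs,
        weights=weights,
        bias=bias,
        nu=nu,
        sigma_b=sigma_b,
        sigma_n=sigma_n,
        x_mean=x_mean,
        x_scale=x_scale,
        band_names=tuple(band_names),
        log_evidence=log_evidence,
        _chol=L,
    )


def predict(model: GPRModel, X: np.ndarray, chunk: int = 4096) -> Prediction:
    """Posterior mean and variance at query band vectors.

    The variance nu + sigma_n^2 - k*^T (K + sigma_n^2 I)^-1 k* is
    clamped at zero (with a warning) if round-off drives it negative.
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_bands:
        raise ValueError(
            f"query vectors have {X.shape[1]} bands, model expects {model.n_bands}"
        )
    Xs = model.standardize(X)
    L = model.cholesky()

    means = np.empty(Xs.shape[0])
    variances = np.empty(Xs.shape[0])
    prior = model.nu + model.sigma_n**2
    for start in range(0, Xs.shape[0], chunk):
        xq = Xs[start : start + chunk]
        Kstar = ard_kernel(model.X_train, xq, model.nu, model.sigma_b)
        means[start : start + chunk] = Kstar.T @ model.weights + model.bias
        v = linalg.solve_triangular(L, Kstar, lower=True)
        variances[start : start + chunk] = prior - np.sum(v * v, axis=0)

    if np.any(variances < 0):
        if np.any(variances < -1e-6 * prior):
            warnings.warn("negative predictive variance clamped to zero")
        variances = np.clip(variances, 0.0, None)
    if single:
        return Prediction(means[0], variances[0])
    return Prediction(means, variances)


def band_relevance(model: GPRModel) -> list[tuple[str, float]]:
    """Bands sorted by relevance: ascending length-scale, ties by order.

    The smaller sigma_b, the faster the predictor varies along that
    band, i.e. the more relevant the band.
    """
    names = list(model.band_names) or [f"b{i}" for i in range(model.n_bands)]
    order = np.argsort(model.sigma_b, kind="stable")
    return [(names[i], float(model.sigma_b[i])) for i in order]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[ValidationReport, list[ValidationReport]]:
    """Seeded k-fold cross-validation.

    Samples are shuffled once and split into k near-equal folds (any
    remainder spread one per fold); the model is refitted k times and
    every sample is predicted exactly once out-of-fold.  Returns the
    pooled report and the per-fold reports.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError("more folds than samples")

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)

    pooled = np.empty(n)
    fold_reports = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
        model = fit(X[train_idx], y[train_idx], seed=seed + i, **fit_kwargs)
        pred = predict(model, X[test_idx])
        pooled[test_idx] = pred.mean
        if len(test_idx) >= 2:
            fold_reports.append(regression_metrics(pred.mean, y[test_idx]))
    return regression_metrics(pooled, y), fold_reports
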