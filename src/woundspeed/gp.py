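"""Gaussian-process regression of the wound area and perimeter series.

Each measured series (area, perimeter) is modelled as a zero-mean GP over
time with the covariance kernel

    k(t, t') = C + (sigma_k^2 + t * t')^2

— the sum of a constant and a homogeneous quadratic kernel.  The feature-
space view makes its prior explicit: k is the inner product of the features
``[sqrt(C + sigma_k^4), sqrt(2) * sigma_k * t, t^2]``, i.e. a Bayesian
quadratic polynomial in t with correlated coefficient priors.  Area and
perimeter of a front advancing at constant normal speed are exactly
quadratic/linear in time, so the kernel contains the noiseless truth while
still letting the data bend the curve.

The zero prior mean is justified by normalization: targets are centred and
scaled to unit variance and times mapped to [0, 1] before training; all
predictions are mapped back.  Per-point detection variances enter the
likelihood as a heteroscedastic noise diagonal.  Hyperparameters (C,
sigma_k^2) are chosen by maximizing the log marginal likelihood

    log p(y) = -1/2 y^T K^-1 y - 1/2 log|K| - n/2 log(2 pi)

with multi-restart L-BFGS in log space from a seeded quasi-random design.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, optimize
from scipy.stats import qmc

__all__ = ["GPFit", "kernel_eval", "fit_gp", "predict"]

#: relative jitter ladder: start, escalation factor, ceiling
JITTER_START = 1e-8
JITTER_MAX = 1e-4
#: number of L-BFGS restarts (one default start + quasi-random starts)
N_RESTARTS = 10
#: log-space search box for hyperparameter initializations
INIT_BOX = (-6.0, 6.0)


def kernel_eval(t: np.ndarray, tp: np.ndarray, C: float, sigma_k: float) -> np.ndarray:
    """Kernel value ``C + (sigma_k^2 + t * t')^2``; symmetric in (t, t')."""
    if C < 0:
        raise ValueError("C must be >= 0")
    t = np.asarray(t, dtype=float)
    tp = np.asarray(tp, dtype=float)
    return C + (sigma_k**2 + np.multiply.outer(t, tp)) ** 2


@dataclass
class GPFit:
    """A trained GP for one series, in normalized coordinates.

    ``t_train``/``y_train`` are the normalized training data;
    ``noise_var`` the per-point detection variances on the normalized scale.
    De-normalization constants map predictions back to original units.
    """

    t_train: np.ndarray
    y_train: np.ndarray
    noise_var: np.ndarray
    C: float
    sigma_k: float
    t_offset: float
    t_scale: float
    y_mean: float
    y_scale: float
    log_marginal_likelihood: float
    jitter: float
    restart_lmls: np.ndarray = field(default_factory=lambda: np.empty(0))
    noise_level: float = 0.0  # optional learned homoscedastic noise term

    # cached Cholesky factor and weights
    _chol: np.ndarray | None = field(default=None, repr=False)
    _alpha: np.ndarray | None = field(default=None, repr=False)

    @property
    def train_range(self) -> tuple[float, float]:
        """Training time range in original units."""
        lo = self.t_train.min() * self.t_scale + self.t_offset
        hi = self.t_train.max() * self.t_scale + self.t_offset
        return float(lo), float(hi)

    def _factor(self) -> tuple[np.ndarray, np.ndarray]:
        if self._chol is None:
            K = kernel_eval(self.t_train, self.t_train, self.C, self.sigma_k)
            K[np.diag_indices_from(K)] += self.noise_var + self.noise_level + self.jitter
            self._chol = linalg.cholesky(K, lower=True)
            self._alpha = linalg.cho_solve((self._chol, True), self.y_train)
        return self._chol, self._alpha  # type: ignore[return-value]

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize hyperparameters, normalization constants and a training
        summary for provenance."""
        payload = {
            "kernel": "C + (sigma_k^2 + t*t')^2",
            "C": self.C,
            "sigma_k": self.sigma_k,
            "noise_level": self.noise_level,
            "t_offset": self.t_offset,
            "t_scale": self.t_scale,
            "y_mean": self.y_mean,
            "y_scale": self.y_scale,
            "jitter": self.jitter,
            "log_marginal_likelihood": self.log_marginal_likelihood,
            "n_train": int(len(self.t_train)),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _neg_lml(theta: np.ndarray, t: np.ndarray, y: np.ndarray, noise: np.ndarray) -> float:
    C, s2 = np.exp(theta[0]), np.exp(theta[1])
    extra = np.exp(theta[2]) if len(theta) > 2 else 0.0
    K = C + (s2 + np.outer(t, t)) ** 2
    n = len(t)
    jitter = JITTER_START * np.trace(K) / n
    while True:
        Kj = K.copy()
        Kj[np.diag_indices_from(Kj)] += noise + extra + jitter
        try:
            L = linalg.cholesky(Kj, lower=True)
            break
        except linalg.LinAlgError:
            jitter *= 10.0
            if jitter > JITTER_MAX * np.trace(K) / n:
                return 1e25
    alpha = linalg.cho_solve((L, True), y)
    lml = -0.5 * float(y @ alpha) - float(np.log(np.diag(L)).sum()) - 0.5 * n * math.log(2 * math.pi)
    return -lml


def fit_gp(
    times: np.ndarray,
    values: np.ndarray,
    noise_variances: np.ndarray | None = None,
    seed: int = 0,
    n_restarts: int = N_RESTARTS,
    learn_noise: bool = False,
) -> GPFit:
    """Fit the GP to one measured series.

    Targets are centred/scaled to unit variance, times mapped to [0, 1], and
    detection variances divided by the target scale squared so all pieces of
    the model live on one scale.  The marginal likelihood is maximized over
    (C, sigma_k^2) in log space with ``n_restarts`` seeded starts; an
    optional homoscedastic noise term can be learned as a third
    hyperparameter (off by default — detection variances normally carry the
    noise).  Requires at least 3 points.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and values must be matching 1-D arrays")
    if len(t) < 3:
        raise ValueError("GP training needs at least 3 measurements")
    if noise_variances is None:
        noise = np.zeros_like(y)
    else:
        noise = np.asarray(noise_variances, dtype=float)
        if noise.shape != y.shape or (noise < 0).any():
            raise ValueError("noise variances must be nonnegative, one per point")

    t_offset = float(t.min())
    t_scale = float(t.max() - t.min())
    if t_scale <= 0:
        raise ValueError("times must span a nonzero range")
    tn = (t - t_offset) / t_scale
    y_mean = float(y.mean())
    y_scale = float(y.std())
    if y_scale <= 0:
        y_scale = 1.0
    yn = (y - y_mean) / y_scale
    noise_n = noise / y_scale**2

    ndim = 3 if learn_noise else 2
    rng_seed = seed % (2**31)
    sampler = qmc.Sobol(d=ndim, scramble=True, seed=rng_seed)
    lo, hi = INIT_BOX
    starts = [np.zeros(ndim)]
    m = max(0, n_restarts - 1)
    if m:
        n_draw = 1 << (m - 1).bit_length()  # power of two keeps Sobol balanced
        starts.extend(qmc.scale(sampler.random(n_draw)[:m], lo, hi))

    best = None
    restart_lmls = []
    for x0 in starts:
        res = optimize.minimize(
            _neg_lml,
            x0,
            args=(tn, yn, noise_n),
            method="L-BFGS-B",
            bounds=[(-15.0, 15.0)] * ndim,
        )
        restart_lmls.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    if best.fun >= 1e24:
        raise RuntimeError(
            "GP training failed: kernel matrix not positive definite within the jitter ladder"
        )
    theta = best.x
    C, s2 = float(np.exp(theta[0])), float(np.exp(theta[1]))
    noise_level = float(np.exp(theta[2])) if learn_noise else 0.0

    K = C + (s2 + np.outer(tn, tn)) ** 2
    n = len(tn)
    jitter = JITTER_START * np.trace(K) / n
    while True:
        Kj = K.copy()
        Kj[np.diag_indices_from(Kj)] += noise_n + noise_level + jitter
        try:
            linalg.cholesky(Kj, lower=True)
            break
        except linalg.LinAlgError:
            jitter *= 10.0

    return GPFit(
        t_train=tn,
        y_train=yn,
        noise_var=noise_n,
        C=C,
        sigma_k=math.sqrt(s2),
        t_offset=t_offset,
        t_scale=t_scale,
        y_mean=y_mean,
        y_scale=y_scale,
        log_marginal_likelihood=-float(best.fun),
        jitter=float(jitter),
        restart_lmls=np.asarray(restart_lmls),
        noise_level=noise_level,
    )


def predict(
    fit: GPFit,
    query_times: np.ndarray,
    include_noise: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and standard deviation at the query times, in original
    units.  Query times outside the training range are extrapolated (the
    polynomial kernel makes the variance grow rapidly there).  With
    ``include_noise`` the learned homoscedastic noise term is added to the
    predictive variance (useful for imputation calibration)."""
    tq = np.asarray(query_times, dtype=float)
    tn = (tq - fit.t_offset) / fit.t_scale
    L, alpha = fit._factor()
    Ks = kernel_eval(tn, fit.t_train, fit.C, fit.sigma_k)
    mean_n = Ks @ alpha
    v = linalg.solve_triangular(L, Ks.T, lower=True)
    var_n = kernel_eval(tn, tn, fit.C, fit.sigma_k).diagonal() - np.einsum("ij,ij->j", v, v)
    if include_noise:
        var_n = var_n + fit.noise_level
    var_n = np.clip(var_n, 0.0, None)
    mean = mean_n * fit.y_scale + fit.y_mean
    std = np.sqrt(var_n) * fit.y_scale
    return mean, std
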