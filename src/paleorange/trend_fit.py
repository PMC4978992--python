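"""Trend models for the cumulative total range curve.

Three candidate growth models are fitted to the cumulative total range as a
function of time since clade origin and compared by AICc:

* linear            f(t) = a + b·t
* sigmoid           f(t) = K / (1 + exp(−r (t − m)))          (3-par logistic)
* generalized       f(t) = K · (1 + ν·exp(−r (t − m)))^(−1/ν)  (Richards)

The generalized logistic nests the sigmoid at ν = 1. Saturating (sigmoid /
Richards) fits beating the linear model indicate that range accumulation
slows toward the present. Fitting is Gaussian maximum likelihood on curves
normalised to [0, 1] by their maximum (so likelihoods are comparable across
clades); raw-scale fitting is available via ``normalize=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

MODELS = ("linear", "sigmoid", "generalized_logistic")

_N_PARAMS = {"linear": 3, "sigmoid": 4, "generalized_logistic": 5}  # incl. sigma

_SIGMA_FLOOR = 1e-8


class FitError(RuntimeError):
    """Optimizer failed to converge from every start."""


@dataclass(frozen=True)
class TrendModelFit:
    model_id: str
    parameters: dict[str, float]
    sigma: float
    loglik: float
    aicc: float
    n_params: int
    n_obs: int
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return _predict(self.model_id, self.parameters, np.asarray(t, dtype=float))


def _predict(model_id: str, params: dict[str, float], t: np.ndarray) -> np.ndarray:
    if model_id == "linear":
        return params["a"] + params["b"] * t
    if model_id == "sigmoid":
        return params["K"] / (1.0 + np.exp(-params["r"] * (t - params["m"])))
    if model_id == "generalized_logistic":
        nu = params["nu"]
        z = np.exp(np.clip(-params["r"] * (t - params["m"]), -500, 500))
        return params["K"] * (1.0 + nu * z) ** (-1.0 / nu)
    raise ValueError(f"unknown model: {model_id!r}")


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _gaussian_loglik(resid: np.ndarray) -> tuple[float, float]:
    n = len(resid)
    sigma = max(float(np.sqrt(np.mean(resid**2))), _SIGMA_FLOOR)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma**2) + np.mean(resid**2) / sigma**2)
    return ll, sigma


def _starts(model_id: str, t: np.ndarray, y: np.ndarray, n_starts: int, rng: np.random.Generator):
    span = max(float(np.ptp(t)), 1e-9)
    k0 = max(float(np.max(y)), 1e-9)
    base = {
        "sigmoid": np.array([k0, 4.0 / span, float(np.median(t))]),
        "generalized_logistic": np.array([k0, 4.0 / span, float(np.median(t)), 0.0]),
    }[model_id]
    yield base
    for _ in range(n_starts - 1):
        jitter = rng.normal(0, 1, size=base.shape)
        start = base * np.exp(0.3 * jitter)
        start[2] = base[2] + rng.normal(0, 0.3) * span  # midpoint shifts additively
        if model_id == "generalized_logistic":
            start[3] = rng.normal(0, 1)  # log nu
        yield start


def fit_trend(
    t: np.ndarray,
    y: np.ndarray,
    model_id: str,
    n_starts: int = 10,
    seed: int = 0,
    normalize: bool = True,
) -> TrendModelFit:
    """Gaussian ML fit of one trend model to a cumulative range curve.

    ``t`` is time since clade origin (Myr, increasing); ``y`` the cumulative
    total range, normalised to [0, 1] by its maximum unless
    ``normalize=False``. Nonlinear models use multi-start least squares
    (``n_starts`` seeded starts); the best local optimum is returned.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 5:
        raise FitError("need at least 5 points to fit a trend model")
    if normalize:
        y = y / np.max(np.abs(y))
    if model_id == "linear":
        X = np.column_stack([np.ones_like(t), t])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        ll, sigma = _gaussian_loglik(resid)
        params = {"a": float(coef[0]), "b": float(coef[1])}
        return TrendModelFit(model_id, params, sigma, ll, aicc(ll, 3, len(t)), 3, len(t), True)

    if model_id not in MODELS:
        raise ValueError(f"unknown model: {model_id!r}")

    def residuals(theta):
        if model_id == "sigmoid":
            params = {"K": theta[0], "r": theta[1], "m": theta[2]}
        else:
            params = {"K": theta[0], "r": theta[1], "m": theta[2], "nu": np.exp(np.clip(theta[3], -20, 20))}
        return _predict(model_id, params, t) - y

    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    for start in _starts(model_id, t, y, n_starts, rng):
        try:
            res = least_squares(residuals, start, method="lm", max_nfev=5000)
        except Exception:
            continue
        if res.cost < best_cost and np.all(np.isfinite(res.x)):
            best, best_cost = res, res.cost
    if best is None:
        raise FitError(f"{model_id}: no start converged")
    theta = best.x
    if model_id == "sigmoid":
        params = {"K": float(theta[0]), "r": float(theta[1]), "m": float(theta[2])}
    else:
        params = {"K": float(theta[0]), "r": float(theta[1]), "m": float(theta[2]), "nu": float(np.exp(np.clip(theta[3], -20, 20)))}
    resid = residuals(theta)
    ll, sigma = _gaussian_loglik(resid)
    k = _N_PARAMS[model_id]
    return TrendModelFit(model_id, params, sigma, ll, aicc(ll, k, len(t)), k, len(t), bool(best.success))


def fit_all(t, y, seed: int = 0, normalize: bool = True) -> dict[str, TrendModelFit]:
    return {m: fit_trend(t, y, m, seed=seed, normalize=normalize) for m in MODELS}


def select_best(fits) -> str:
    """Model id with minimum AICc; near-ties (ΔAICc < 0.01) go to fewer parameters."""
    fits = list(fits.values()) if isinstance(fits, dict) else list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    best = min(fits, key=lambda f: (f.aicc,))
    contenders = [f for f in fits if f.aicc - best.aicc < 0.01]
    return min(contenders, key=lambda f: f.n_params).model_id
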