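"""Gaussian curve peeling of elution traces into particle subpopulations.

Size-exclusion traces of heterogeneous lipoprotein samples are mixtures of
overlapping, approximately Gaussian elution peaks, one per discretely sized
particle population.  This module decomposes a trace into ``k`` Gaussian
components plus a constant baseline by bounded nonlinear least squares,
selects ``k`` with an information criterion, and quantifies each component by
its share of total fitted area.

Initialization is deterministic residual peeling: the ``k``-component start is
the refined ``k−1`` fit plus a component placed at the residual maximum, with
a small budget of seeded jittered multi-starts for robustness.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .errors import InputError, PeakFitError
from .traces import ElutionTrace

log = logging.getLogger(__name__)

__all__ = [
    "GaussianComponent",
    "PeakModel",
    "fit_components",
    "select_component_count",
    "quantify_peaks",
]

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian elution peak: ``A·exp(−(v−μ)²/2σ²)``.

    amplitude in signal units, mean and sigma in ml.
    """

    amplitude: float
    mean: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise InputError("sigma must be positive")
        if self.amplitude <= 0:
            raise InputError("amplitude must be positive")

    @property
    def area(self) -> float:
        return self.amplitude * self.sigma * SQRT_2PI

    def __call__(self, volume):
        v = np.asarray(volume, dtype=float)
        return self.amplitude * np.exp(-0.5 * ((v - self.mean) / self.sigma) ** 2)


@dataclass(frozen=True)
class PeakModel:
    """Fitted mixture: baseline + sum of components, ordered by mean."""

    components: tuple[GaussianComponent, ...]
    baseline: float
    r_squared: float
    residuals: np.ndarray

    def curve(self, volume):
        v = np.asarray(volume, dtype=float)
        out = np.full_like(v, self.baseline, dtype=float)
        for c in self.components:
            out += c(v)
        return out

    @property
    def k(self) -> int:
        return len(self.components)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "baseline": self.baseline,
            "r_squared": self.r_squared,
            "components": [
                {"amplitude": c.amplitude, "mean": c.mean, "sigma": c.sigma}
                for c in self.components
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _model(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    y = np.full_like(x, theta[0])
    for i in range(1, len(theta), 3):
        a, mu, s = theta[i:i + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / s) ** 2)
    return y


def _jacobian(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    jac = np.empty((len(x), len(theta)))
    jac[:, 0] = 1.0
    for i in range(1, len(theta), 3):
        a, mu, s = theta[i:i + 3]
        z = (x - mu) / s
        g = np.exp(-0.5 * z * z)
        jac[:, i] = g
        jac[:, i + 1] = a * g * z / s
        jac[:, i + 2] = a * g * z * z / s
    return jac


def _bounds(k: int, vmin: float, vmax: float, sigma_bounds: tuple[float, float],
            mean_pad: float, fit_baseline: bool):
    lo = [0.0] + [1e-12, vmin - mean_pad, sigma_bounds[0]] * k
    hi = [np.inf if fit_baseline else 1e-30] + \
         [np.inf, vmax + mean_pad, sigma_bounds[1]] * k
    return np.array(lo), np.array(hi)


def _refine(theta0, x, y, lo, hi):
    theta0 = np.clip(theta0, lo + 1e-15, np.where(np.isfinite(hi), hi, theta0))
    res = least_squares(lambda t: _model(t, x) - y, theta0,
                        jac=lambda t: _jacobian(t, x),
                        bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=400)
    return res


def _sse(theta, x, y) -> float:
    r = _model(theta, x) - y
    return float(r @ r)


def _initial_sigma(x: np.ndarray, sigma_bounds) -> float:
    guess = (x[-1] - x[0]) / 20.0
    return float(np.clip(guess, sigma_bounds[0], sigma_bounds[1]))


def _peel_chain(x, y, k_max, sigma_bounds, mean_pad, fit_baseline):
    """Refined parameter vectors for k = 1..k_max via residual peeling."""
    chain = []
    theta = np.array([max(float(np.min(y)), 0.0) if fit_baseline else 0.0])
    for k in range(1, k_max + 1):
        resid = y - _model(theta, x)
        j = int(np.argmax(resid))
        amp = max(float(resid[j]), 1e-9 * max(float(np.max(y)), 1.0))
        theta = np.concatenate(
            [theta, [amp, float(x[j]), _initial_sigma(x, sigma_bounds)]]
        )
        lo, hi = _bounds(k, x[0], x[-1], sigma_bounds, mean_pad, fit_baseline)
        theta = _refine(theta, x, y, lo, hi).x
        chain.append(theta.copy())
    return chain


def _to_model(theta, x, y, drop_tol: float = 0.0) -> PeakModel:
    comps = []
    for i in range(1, len(theta), 3):
        a, mu, s = theta[i:i + 3]
        comps.append(GaussianComponent(max(float(a), 1e-300), float(mu), float(s)))
    comps.sort(key=lambda c: c.mean)
    resid = y - _model(theta, x)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PeakModel(tuple(comps), baseline=float(theta[0]),
                     r_squared=r2, residuals=resid)


def fit_components(trace: ElutionTrace, k: int, *, seed: int = 0,
                   n_starts: int = 3, fit_baseline: bool = True,
                   sigma_bounds: tuple[float, float] = (0.2, 20.0),
                   mean_pad: float = 2.0,
                   _chain=None) -> PeakModel:
    """Fit ``k`` Gaussian components (+ constant baseline) to a trace.

    Deterministic given ``seed``: residual-peel start plus ``n_starts − 1``
    seeded jittered restarts; the lowest-SSE solution wins.  Raises
    :class:`PeakFitError` (carrying the best attempt) if no start converges.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    if len(trace) <= 3 * k:
        raise InputError(f"trace has {len(trace)} points; need > {3 * k} for k={k}")
    x, y = trace.volume_ml, trace.signal
    chain = _chain if _chain is not None else _peel_chain(
        x, y, k, sigma_bounds, mean_pad, fit_baseline)
    theta0 = chain[k - 1]
    lo, hi = _bounds(k, x[0], x[-1], sigma_bounds, mean_pad, fit_baseline)
    rng = np.random.default_rng(seed)
    best, best_sse = theta0, _sse(theta0, x, y)
    for _ in range(max(n_starts - 1, 0)):
        jitter = theta0.copy()
        jitter[2::3] = jitter[2::3] + rng.normal(0.0, 0.35, size=k)  # means
        jitter[3::3] = jitter[3::3] * np.exp(rng.normal(0.0, 0.3, size=k))
        res = _refine(jitter, x, y, lo, hi)
        if res.success and _sse(res.x, x, y) < best_sse - 1e-12:
            best, best_sse = res.x, _sse(res.x, x, y)
    if not np.all(np.isfinite(best)):
        raise PeakFitError("fit diverged", best_model=None)
    return _to_model(best, x, y)


def _bic(ss_res: float, n: int, n_params: int) -> float:
    ss = max(ss_res, 1e-300)
    return n * math.log(ss / n) + n_params * math.log(n)


def _aic(ss_res: float, n: int, n_params: int) -> float:
    ss = max(ss_res, 1e-300)
    return n * math.log(ss / n) + 2 * n_params


def select_component_count(trace: ElutionTrace, k_min: int = 1, k_max: int = 10,
                           *, criterion: str = "bic", seed: int = 0,
                           delta: float = 10.0,
                           **fit_kwargs) -> tuple[int, PeakModel]:
    """Fit every ``k`` in ``[k_min, k_max]`` and pick the criterion minimizer.

    Default criterion is BIC under a Gaussian error model; a larger ``k``
    must beat the incumbent by more than ``delta`` (default 10, a strong-
    evidence bar that favors the parsimonious model; exact ties also go to
    the smaller ``k``).  Individual fit failures are logged and skipped.
    """
    if k_min > k_max or k_min < 1:
        raise InputError("require 1 <= k_min <= k_max")
    score = {"bic": _bic, "aic": _aic}.get(criterion)
    if score is None:
        raise InputError(f"unknown criterion {criterion!r}")
    x, y = trace.volume_ml, trace.signal
    sigma_bounds = fit_kwargs.get("sigma_bounds", (0.2, 20.0))
    mean_pad = fit_kwargs.get("mean_pad", 2.0)
    fit_baseline = fit_kwargs.get("fit_baseline", True)
    chain = _peel_chain(x, y, k_max, sigma_bounds, mean_pad, fit_baseline)
    # effectively exact fits (residuals at solver precision) must tie rather
    # than keep "improving": floor SS_res at 1e-12 of the total variance
    ss_floor = 1e-12 * float(np.sum((y - y.mean()) ** 2))
    best_k, best_model, best_score = None, None, np.inf
    for k in range(k_min, k_max + 1):
        try:
            model = fit_components(trace, k, seed=seed, _chain=chain, **fit_kwargs)
        except (PeakFitError, InputError) as exc:
            log.warning("k=%d fit failed, skipped: %s", k, exc)
            continue
        n_params = 3 * k + (1 if fit_baseline else 0)
        ss_res = max(float(model.residuals @ model.residuals), ss_floor)
        val = score(ss_res, len(x), n_params)
        if val < best_score - delta:
            best_k, best_model, best_score = k, model, val
    if best_model is None:
        raise PeakFitError(f"all fits failed in k range [{k_min}, {k_max}]")
    return best_k, best_model


def quantify_peaks(model: PeakModel) -> np.ndarray:
    """Per-component area fractions ``A·σ·√2π / Σ`` (baseline excluded)."""
    if model.k < 1:
        raise InputError("model has no components")
    areas = np.array([c.area for c in model.components])
    return areas / areas.sum()
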