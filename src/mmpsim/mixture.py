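"""Univariate Gaussian-mixture fitting and percentile gating of
flow-cytometry intensity samples.

A cell's mitochondrial membrane potential (MMP) is proxied by its TMRM
fluorescence intensity; a bulk sample of naive embryonic stem cells shows a
multimodal intensity distribution which is modelled here as a K-component
Gaussian mixture on the linear intensity scale,

    f(x) = sum_k w_k * N(x | mu_k, sigma_k^2),   sum_k w_k = 1.

Two distinct notions of "low / high MMP" coexist and are kept separate:

* **Gating** is empirical and rank-based: the bottom (top) fraction of
  events by intensity, with floor rounding of the count — this mirrors how
  a sorter draws a 5% gate.
* **Subpopulation probability** is model-based: the mixture's tail mass on
  one side of a threshold, computed as the weight-averaged Gaussian CDF.

The expectation–maximization (EM) fitter is deliberately self-contained:
its contracts (deterministic quantile-spread first start, per-iteration
log-likelihood monotonicity check, relative variance floor, best of
``n_starts`` restarts) are part of this package's tested surface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from ._rng import child_seeds, rng_from
from .exceptions import EmptyGateWarning, FitError, ValidationError

__all__ = [
    "FlowSample",
    "MixtureFit",
    "GateResult",
    "fit_mixture",
    "select_components",
    "gate_percentiles",
    "subpopulation_probability",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class FlowSample:
    """A labelled vector of per-event fluorescence intensities.

    Intensities live on a positive linear activity scale (arbitrary units);
    any log transformation is the caller's responsibility.
    """

    sample_id: str
    intensities: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        if x.ndim != 1 or x.size == 0:
            raise ValidationError("intensities must be a non-empty 1-D vector")
        if not np.all(np.isfinite(x)):
            raise ValidationError("intensities must all be finite")
        if not np.all(x > 0):
            raise ValidationError("intensities must all be > 0")
        object.__setattr__(self, "intensities", x)

    @property
    def n_events(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class MixtureFit:
    """Parameters of a fitted K-component univariate Gaussian mixture.

    Components are stored sorted by ascending mean; ``log_likelihood_trace``
    holds the EM log-likelihood at every iteration of the winning start and
    is non-decreasing by construction.
    """

    k: int
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    log_likelihood: float
    bic: float
    n_iter: int
    converged: bool
    log_likelihood_trace: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.asarray(self.means, dtype=float)
        sd = np.asarray(self.sds, dtype=float)
        if not (w.size == mu.size == sd.size == self.k >= 1):
            raise ValidationError("weights, means, sds must all have length k >= 1")
        if abs(w.sum() - 1.0) > 1e-8:
            raise ValidationError("weights must sum to 1 within 1e-8")
        if np.any(sd <= 0):
            raise ValidationError("sds must be strictly positive")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "sds", sd)

    def pdf(self, x) -> np.ndarray:
        """Mixture density at ``x``."""
        x = np.asarray(x, dtype=float)
        comp = norm.pdf(x[..., None], loc=self.means, scale=self.sds)
        return comp @ self.weights

    def cdf(self, x) -> np.ndarray:
        """Mixture cumulative distribution at ``x``."""
        x = np.asarray(x, dtype=float)
        comp = norm.cdf(x[..., None], loc=self.means, scale=self.sds)
        return comp @ self.weights

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "log_likelihood": self.log_likelihood,
            "bic": self.bic,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


@dataclass(frozen=True)
class GateResult:
    """Rank-based percentile gates on one sample.

    ``low_indices`` are the floor(low_fraction * N) events with the smallest
    intensity (stable ties by event order); ``high_indices`` the analogous
    top set. Thresholds are the intensities at the rank cut-points: the
    largest intensity inside the low gate and the smallest inside the high
    gate (-inf / +inf for an empty gate).
    """

    low_threshold: float
    high_threshold: float
    low_indices: np.ndarray
    high_indices: np.ndarray
    low_fraction: float
    high_fraction: float
    n_events: int

    def to_dict(self) -> dict:
        return {
            "low_threshold": self.low_threshold,
            "high_threshold": self.high_threshold,
            "n_low": int(self.low_indices.size),
            "n_high": int(self.high_indices.size),
            "low_fraction": self.low_fraction,
            "high_fraction": self.high_fraction,
            "n_events": self.n_events,
            "low_indices": self.low_indices.tolist(),
            "high_indices": self.high_indices.tolist(),
        }


def _log_component_pdf(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return -0.5 * z * z - np.log(sds)[None, :] - 0.5 * _LOG_2PI


def _em_once(
    x: np.ndarray,
    weights: np.ndarray,
    means: np.ndarray,
    sds: np.ndarray,
    tol: float,
    max_iter: int,
    sd_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], int, bool]:
    n = x.size
    ll_prev = -np.inf
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_joint = _log_component_pdf(x, means, sds) + np.log(weights)[None, :]
        log_norm = logsumexp(log_joint, axis=1)
        ll = float(log_norm.sum())
        if not np.isfinite(ll):
            raise FitError("EM log-likelihood became non-finite")
        # monotonicity is a structural property of EM; a decrease beyond
        # floating-point noise (relevant only at the sd floor) signals a bug
        if ll < ll_prev - 1e-6 * max(1.0, abs(ll_prev)):
            raise FitError(
                f"EM log-likelihood decreased ({ll_prev:.6g} -> {ll:.6g})"
            )
        trace.append(ll)
        if ll - ll_prev < tol:
            converged = True
            break
        ll_prev = ll
        resp = np.exp(log_joint - log_norm[:, None])
        nk = np.maximum(resp.sum(axis=0), 1e-300)
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), sd_floor)
    return weights, means, sds, trace, n_iter, converged


def fit_mixture(
    sample: FlowSample,
    k: int,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_starts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """Fit a k-component univariate Gaussian mixture by EM.

    The first start is deterministic (component means at evenly spaced
    sample quantiles, pooled sd, uniform weights); the remaining
    ``n_starts - 1`` starts draw their means from the data at random. The
    start with the highest final log-likelihood wins. Standard deviations
    are floored at ``1e-6 * sample sd`` (1e-12 absolute for constant
    samples) to prevent likelihood singularities.

    Raises
    ------
    ValidationError
        If the sample holds fewer than ``2 k`` events or ``tol <= 0``.
    FitError
        If every start yields a non-finite likelihood.
    """
    x = sample.intensities
    n = x.size
    if k < 1:
        raise ValidationError("k must be >= 1")
    if n < 2 * k:
        raise ValidationError(
            f"need at least 2k = {2 * k} events to fit k = {k} components, got {n}"
        )
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")

    sample_sd = float(x.std())
    sd_floor = max(1e-6 * sample_sd, 1e-12)
    pooled_sd = max(sample_sd, sd_floor)

    starts: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    q = (np.arange(k) + 0.5) / k
    starts.append(
        (np.full(k, 1.0 / k), np.quantile(x, q), np.full(k, pooled_sd))
    )
    for s in child_seeds(seed, max(n_starts - 1, 0)):
        rng = rng_from(s)
        starts.append(
            (
                np.full(k, 1.0 / k),
                rng.choice(x, size=k, replace=False).astype(float),
                np.full(k, pooled_sd),
            )
        )

    best = None
    last_err: FitError | None = None
    for w0, mu0, sd0 in starts:
        try:
            w, mu, sd, trace, n_iter, conv = _em_once(
                x, w0.copy(), mu0.copy(), sd0.copy(), tol, max_iter, sd_floor
            )
        except FitError as err:
            last_err = err
            continue
        if best is None or trace[-1] > best[3][-1]:
            best = (w, mu, sd, trace, n_iter, conv)
    if best is None:
        raise FitError(f"all {n_starts} EM starts failed: {last_err}")

    w, mu, sd, trace, n_iter, conv = best
    order = np.argsort(mu, kind="stable")
    ll = trace[-1]
    n_params = 3 * k - 1
    bic = -2.0 * ll + n_params * math.log(n)
    return MixtureFit(
        k=k,
        weights=w[order],
        means=mu[order],
        sds=sd[order],
        log_likelihood=ll,
        bic=bic,
        n_iter=n_iter,
        converged=conv,
        log_likelihood_trace=tuple(trace),
    )


def select_components(
    sample: FlowSample,
    k_max: int,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
    n_starts: int = 5,
    seed: int = 0,
) -> MixtureFit:
    """Fit k = 1..k_max mixtures and return the fit minimizing BIC.

    BIC = -2 log L + (3k - 1) ln N; ties break toward smaller k.
    """
    if k_max < 1:
        raise ValidationError("k_max must be >= 1")
    best: MixtureFit | None = None
    for k in range(1, k_max + 1):
        fit = fit_mixture(
            sample, k, tol=tol, max_iter=max_iter, n_starts=n_starts, seed=seed
        )
        if best is None or fit.bic < best.bic:
            best = fit
    assert best is not None
    return best


def gate_percentiles(
    sample: FlowSample,
    low_fraction: float = 0.05,
    high_fraction: float = 0.05,
) -> GateResult:
    """Rank-based bottom/top percentile gates (floor rounding, stable ties).

    Emits :class:`EmptyGateWarning` when floor(fraction * N) is zero.
    """
    for name, frac in (("low_fraction", low_fraction), ("high_fraction", high_fraction)):
        if not (0.0 < frac < 1.0):
            raise ValidationError(f"{name} must lie strictly between 0 and 1, got {frac}")
    x = sample.intensities
    n = x.size
    order = np.argsort(x, kind="stable")
    n_low = int(math.floor(low_fraction * n))
    n_high = int(math.floor(high_fraction * n))
    low_idx = order[:n_low].copy()
    high_idx = order[n - n_high:].copy() if n_high > 0 else np.empty(0, dtype=order.dtype)
    if n_low == 0:
        warnings.warn(
            f"low gate is empty: floor({low_fraction} * {n}) = 0 events",
            EmptyGateWarning,
            stacklevel=2,
        )
    if n_high == 0:
        warnings.warn(
            f"high gate is empty: floor({high_fraction} * {n}) = 0 events",
            EmptyGateWarning,
            stacklevel=2,
        )
    low_thr = float(x[order[n_low - 1]]) if n_low > 0 else -math.inf
    high_thr = float(x[order[n - n_high]]) if n_high > 0 else math.inf
    return GateResult(
        low_threshold=low_thr,
        high_threshold=high_thr,
        low_indices=low_idx,
        high_indices=high_idx,
        low_fraction=float(low_fraction),
        high_fraction=float(high_fraction),
        n_events=n,
    )


def subpopulation_probability(fit: MixtureFit, threshold: float, side: str = "below") -> float:
    """Mixture tail mass on one side of a threshold.

    Computes the probability that an intensity drawn from the fitted model
    lies below (or above) ``threshold``, as the weight-averaged Gaussian
    CDF. This is the model-based counterpart of an empirical gate fraction.
    """
    if not fit.converged:
        raise ValidationError("fit must have converged before probabilities are read off")
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    if side not in ("below", "above"):
        raise ValidationError(f"side must be 'below' or 'above', got {side!r}")
    below = float(fit.cdf(np.asarray(threshold)))
    return below if side == "below" else 1.0 - below
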