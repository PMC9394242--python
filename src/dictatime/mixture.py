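"""Contaminated-normal model of dictation times.

Observed durations are modelled as a two-component mixture: a Normal
true-reading component with weight ``lam`` and a fixed contamination
density with weight ``1 - lam`` absorbing workflow artefacts (interrupted
saves, paused-and-resumed reports, unknown causes).  The default
contamination is a uniform background over (0, max(durations)] — robust
and identifiable without assuming anything about the artefact shapes.

Two fitting routes are provided and must agree on well-behaved data:

* :func:`fit_em` — reference expectation-maximization, monotone in the
  observed-data log-likelihood.
* :func:`fit_stochastic_search` — iterative stochastic parameter-vector
  search: each iteration draws a vector of candidate values for each of
  (mu, sigma, lam) around the current best, scores candidate triples by
  the mixture log-likelihood, keeps the best, and geometrically shrinks
  the search ranges.

Records are then labelled norm/outlier by the posterior probability of
the normal component (maximum a posteriori at threshold 0.5 by default).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import stats as rstats

__all__ = [
    "MixtureParams",
    "ContaminationModel",
    "FitTrace",
    "ClassifiedSample",
    "fit_em",
    "fit_stochastic_search",
    "classify_records",
    "ks_normality_of_retained",
    "write_fit_json",
    "write_trace_csv",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class MixtureParams:
    """Fitted (mu, sigma) of the normal component and its weight lam."""

    mu: float
    sigma: float
    lam: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 < self.lam <= 1.0:
            raise ValueError("lam must lie in (0, 1]")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.mu, self.sigma, self.lam)


@dataclass(frozen=True)
class ContaminationModel:
    """Fixed contamination density (uniform over (lower, upper])."""

    upper: float
    lower: float = 0.0
    label: str = "unknown"

    def __post_init__(self) -> None:
        if not self.upper > self.lower:
            raise ValueError("contamination support must have upper > lower")

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        inside = (x > self.lower) & (x <= self.upper)
        return np.where(inside, 1.0 / (self.upper - self.lower), 0.0)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.clip((x - self.lower) / (self.upper - self.lower), 0.0, 1.0)

    @classmethod
    def uniform_background(cls, durations) -> "ContaminationModel":
        d = np.asarray(getattr(durations, "durations", durations), dtype=float)
        if d.size == 0:
            raise ValueError("cannot build contamination support from empty sample")
        return cls(upper=float(d.max()))


@dataclass
class FitTrace:
    """Per-iteration best parameters, objective, and search-range widths."""

    mu: np.ndarray
    sigma: np.ndarray
    lam: np.ndarray
    objective: np.ndarray
    width_mu: np.ndarray
    width_sigma: np.ndarray
    width_lam: np.ndarray
    converged: bool
    iterations_run: int
    method: str = "em"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": np.arange(len(self.mu)),
                "mu": self.mu,
                "sigma": self.sigma,
                "lam": self.lam,
                "objective": self.objective,
                "width_mu": self.width_mu,
                "width_sigma": self.width_sigma,
                "width_lam": self.width_lam,
            }
        )


@dataclass(frozen=True)
class ClassifiedSample:
    """Posterior-based norm/outlier labels for one duration sample."""

    durations: np.ndarray
    posterior_norm: np.ndarray
    labels: np.ndarray
    threshold: float
    exam_ids: tuple[str, ...] | None = None

    @property
    def retained(self) -> np.ndarray:
        return self.durations[self.labels == "norm"]

    @property
    def n_norm(self) -> int:
        return int(np.count_nonzero(self.labels == "norm"))

    @property
    def n_total(self) -> int:
        return int(self.durations.size)

    def to_frame(self) -> pd.DataFrame:
        ids = self.exam_ids if self.exam_ids is not None else [""] * self.n_total
        return pd.DataFrame(
            {
                "exam_id": list(ids),
                "duration_min": self.durations,
                "posterior_norm": self.posterior_norm,
                "label": self.labels,
            }
        )


def _extract(durations) -> tuple[np.ndarray, tuple[str, ...] | None]:
    ids = getattr(durations, "exam_ids", None)
    x = np.asarray(getattr(durations, "durations", durations), dtype=float)
    return x, ids


def _validate_sample(x: np.ndarray, min_n: int = 30) -> None:
    if x.size < min_n:
        raise ValueError("sample too small for mixture fit (need >= 30 durations)")
    if not np.all(x > 0):
        raise ValueError("durations must all be positive")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate sample (zero variance)")


def _auto_init(x: np.ndarray) -> MixtureParams:
    """Robust starting point: median, 1.4826*MAD, lam = 0.8."""
    mu0 = float(np.median(x))
    mad = float(np.median(np.abs(x - mu0)))
    sigma0 = 1.4826 * mad
    if sigma0 <= 0:
        sigma0 = float(x.std(ddof=1))
    return MixtureParams(mu=mu0, sigma=sigma0, lam=0.8)


def _loglik_grid(
    x: np.ndarray, g: np.ndarray, mus: np.ndarray, sigmas: np.ndarray, lams: np.ndarray
) -> np.ndarray:
    """Mixture log-likelihood for each candidate triple (vectorized)."""
    z = (x[None, :] - mus[:, None]) / sigmas[:, None]
    phi = np.exp(-0.5 * z * z) / (sigmas[:, None] * _SQRT_2PI)
    den = lams[:, None] * phi + (1.0 - lams)[:, None] * g[None, :]
    with np.errstate(divide="ignore"):
        return np.log(den).sum(axis=1)


def _ks_distance_grid(
    x_sorted: np.ndarray,
    contamination: ContaminationModel,
    mus: np.ndarray,
    sigmas: np.ndarray,
    lams: np.ndarray,
) -> np.ndarray:
    """KS distance between the empirical CDF and each candidate mixture CDF."""
    n = x_sorted.size
    gc = contamination.cdf(x_sorted)[None, :]
    z = (x_sorted[None, :] - mus[:, None]) / sigmas[:, None]
    cdf = lams[:, None] * ndtr(z) + (1.0 - lams)[:, None] * gc
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    return np.maximum((hi[None, :] - cdf).max(axis=1), (cdf - lo[None, :]).max(axis=1))


def _warn_negative_mass(params: MixtureParams) -> None:
    mass_below_zero = float(ndtr(-params.mu / params.sigma))
    if mass_below_zero > 0.01:
        warnings.warn(
            f"fitted normal places {100 * mass_below_zero:.1f}% mass below 0; "
            "durations are strictly positive",
            RuntimeWarning,
            stacklevel=3,
        )


def fit_em(
    durations,
    contamination: ContaminationModel | None = None,
    init: MixtureParams | str = "auto",
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> tuple[MixtureParams, FitTrace]:
    """Maximum-likelihood fit of the two-component mixture by EM.

    The contamination density is held fixed; only (mu, sigma, lam) are
    estimated.  The observed-data log-likelihood is non-decreasing across
    iterations; ``converged`` is set when the maximum relative parameter
    change drops below ``tol``.
    """
    x, _ = _extract(durations)
    _validate_sample(x)
    contamination = contamination or ContaminationModel.uniform_background(x)
    g = contamination.pdf(x)
    p0 = _auto_init(x) if isinstance(init, str) else init
    mu, sigma, lam = p0.mu, p0.sigma, p0.lam
    n = x.size

    mus, sigmas, lams, objs = [], [], [], []
    converged = False
    iterations = 0
    for _ in range(max_iter):
        z = (x - mu) / sigma
        phi = np.exp(-0.5 * z * z) / (sigma * _SQRT_2PI)
        num = lam * phi
        den = num + (1.0 - lam) * g
        with np.errstate(divide="ignore"):
            ll = float(np.log(den).sum())
        mus.append(mu)
        sigmas.append(sigma)
        lams.append(lam)
        objs.append(ll)

        r = num / den
        rsum = float(r.sum())
        lam_new = min(max(rsum / n, 1e-10), 1.0)
        mu_new = float((r * x).sum() / rsum)
        sigma_new = math.sqrt(max(float((r * (x - mu_new) ** 2).sum() / rsum), 1e-24))
        rel = max(
            abs(mu_new - mu) / max(abs(mu), 1e-12),
            abs(sigma_new - sigma) / max(abs(sigma), 1e-12),
            abs(lam_new - lam) / max(abs(lam), 1e-12),
        )
        mu, sigma, lam = mu_new, sigma_new, lam_new
        iterations += 1
        if rel < tol:
            converged = True
            break

    # final state with its own objective
    z = (x - mu) / sigma
    phi = np.exp(-0.5 * z * z) / (sigma * _SQRT_2PI)
    with np.errstate(divide="ignore"):
        ll = float(np.log(lam * phi + (1.0 - lam) * g).sum())
    mus.append(mu)
    sigmas.append(sigma)
    lams.append(lam)
    objs.append(ll)

    params = MixtureParams(mu=mu, sigma=sigma, lam=lam)
    _warn_negative_mass(params)
    zeros = np.zeros(len(mus))
    trace = FitTrace(
        mu=np.array(mus),
        sigma=np.array(sigmas),
        lam=np.array(lams),
        objective=np.array(objs),
        width_mu=zeros,
        width_sigma=zeros.copy(),
        width_lam=zeros.copy(),
        converged=converged,
        iterations_run=iterations,
        method="em",
    )
    return params, trace


def fit_stochastic_search(
    durations,
    contamination: ContaminationModel | None = None,
    n_iterations: int = 1000,
    vector_size: int = 100,
    seed: int = 0,
    init: MixtureParams | str = "auto",
    shrink: float = 0.995,
    width_lam0: float = 0.5,
    conv_window: int = 50,
    conv_rtol: float = 1e-3,
    objective: str = "loglik",
) -> tuple[MixtureParams, FitTrace]:
    """Iterative stochastic parameter-vector search for (mu, sigma, lam).

    Per iteration, ``vector_size`` candidate values are drawn uniformly
    around the current best for each parameter (initial half-widths:
    mu0, sigma0, ``width_lam0``), candidate triples are scored, the best
    is kept, and the ranges shrink geometrically by ``shrink``.  The run
    is accepted (``converged``) when each best parameter varies by less
    than ``conv_rtol`` relative over the final ``conv_window`` iterations.
    Fully reproducible for a fixed ``seed``.

    ``objective`` is ``"loglik"`` (default) or ``"ks"`` (minimize the KS
    distance between the empirical and mixture CDFs; sensitivity check).
    """
    x, _ = _extract(durations)
    _validate_sample(x)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if vector_size < 2:
        raise ValueError("vector_size must be >= 2")
    if objective not in ("loglik", "ks"):
        raise ValueError("objective must be 'loglik' or 'ks'")
    contamination = contamination or ContaminationModel.uniform_background(x)
    p0 = _auto_init(x) if isinstance(init, str) else init

    g = contamination.pdf(x)
    x_sorted = np.sort(x)
    if objective == "loglik":

        def score(mus, sigmas, lams):
            return _loglik_grid(x, g, mus, sigmas, lams)

    else:

        def score(mus, sigmas, lams):
            return -_ks_distance_grid(x_sorted, contamination, mus, sigmas, lams)

    best = np.array([p0.mu, p0.sigma, p0.lam])
    best_score = float(score(best[:1], best[1:2], best[2:3])[0])
    widths = np.array([p0.mu, p0.sigma, width_lam0])
    mu_floor = 1e-6 * p0.mu
    sigma_floor = 1e-6 * p0.sigma

    rng = np.random.default_rng(seed)
    hist = np.empty((n_iterations, 3))
    objs = np.empty(n_iterations)
    whist = np.empty((n_iterations, 3))
    for it in range(n_iterations):
        mus = np.maximum(
            rng.uniform(best[0] - widths[0], best[0] + widths[0], vector_size), mu_floor
        )
        sigmas = np.maximum(
            rng.uniform(best[1] - widths[1], best[1] + widths[1], vector_size),
            sigma_floor,
        )
        lams = np.clip(
            rng.uniform(best[2] - widths[2], best[2] + widths[2], vector_size),
            0.01,
            1.0,
        )
        scores = score(mus, sigmas, lams)
        k = int(np.argmax(scores))
        if scores[k] > best_score:
            best = np.array([mus[k], sigmas[k], lams[k]])
            best_score = float(scores[k])
        hist[it] = best
        objs[it] = best_score
        whist[it] = widths
        widths = widths * shrink

    converged = False
    if n_iterations > conv_window:
        tail = hist[-conv_window:]
        span = tail.max(axis=0) - tail.min(axis=0)
        rel = span / np.maximum(np.abs(hist[-1]), 1e-12)
        converged = bool(np.all(rel < conv_rtol))
    if not converged:
        warnings.warn(
            "stochastic search did not settle within the configured window",
            RuntimeWarning,
            stacklevel=2,
        )

    params = MixtureParams(mu=float(best[0]), sigma=float(best[1]), lam=float(best[2]))
    _warn_negative_mass(params)
    trace = FitTrace(
        mu=hist[:, 0].copy(),
        sigma=hist[:, 1].copy(),
        lam=hist[:, 2].copy(),
        objective=objs,
        width_mu=whist[:, 0].copy(),
        width_sigma=whist[:, 1].copy(),
        width_lam=whist[:, 2].copy(),
        converged=converged,
        iterations_run=n_iterations,
        method="search",
    )
    return params, trace


def classify_records(
    durations,
    params: MixtureParams,
    contamination: ContaminationModel | None = None,
    threshold: float = 0.5,
) -> ClassifiedSample:
    """Label records norm/outlier by the posterior of the normal component.

    P(norm | x) = lam phi(x) / (lam phi(x) + (1 - lam) g(x)); a record is
    ``norm`` iff its posterior is >= ``threshold``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    x, ids = _extract(durations)
    if x.size == 0:
        raise ValueError("cannot classify an empty sample")
    contamination = contamination or ContaminationModel.uniform_background(x)
    g = contamination.pdf(x)
    z = (x - params.mu) / params.sigma
    phi = np.exp(-0.5 * z * z) / (params.sigma * _SQRT_2PI)
    num = params.lam * phi
    den = num + (1.0 - params.lam) * g
    with np.errstate(invalid="ignore"):
        post = np.where(den > 0.0, num / den, params.lam)
    labels = np.where(post >= threshold, "norm", "outlier")
    return ClassifiedSample(
        durations=x,
        posterior_norm=post,
        labels=labels,
        threshold=threshold,
        exam_ids=ids,
    )


def ks_normality_of_retained(
    classified: ClassifiedSample, params: MixtureParams, min_n: int = 10
) -> rstats.TestResult:
    """KS test of the retained ("norm") subset against Normal(mu, sigma)."""
    retained = classified.retained
    if retained.size < min_n:
        raise ValueError(f"retained subset too small for KS test (need >= {min_n})")
    return rstats.ks_test(retained, params.mu, params.sigma, min_n=min_n)


def write_fit_json(
    params: MixtureParams,
    trace: FitTrace,
    path,
    seed: int | None = None,
    settings: dict | None = None,
) -> None:
    """Serialize a fit result as structured text (JSON)."""
    payload = {
        "mu": params.mu,
        "sigma": params.sigma,
        "lam": params.lam,
        "converged": trace.converged,
        "iterations_run": trace.iterations_run,
        "method": trace.method,
        "objective": float(trace.objective[-1]),
        "seed": seed,
        "settings": settings or {},
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_trace_csv(trace: FitTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False)
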