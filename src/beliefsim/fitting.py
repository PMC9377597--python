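"""MAP estimation of belief-model parameters and BIC computation.

Each participant x referent run is fitted independently.  The objective is
the sum of Beta report log-densities over all 21 reports plus the log prior
densities, maximized by bounded local optimization from multiple start
points drawn from the priors (plus one deterministic midpoint start).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import (
    BeliefTrajectory,
    ModelSpec,
    get_model,
    report_logdensity,
)

__all__ = [
    "PriorFamily",
    "PriorSpec",
    "DEFAULT_PRIORS",
    "FitConfig",
    "FitResult",
    "log_posterior",
    "fit_map",
    "bic",
    "fits_to_frame",
    "write_fits",
    "read_fits",
    "default_config_json",
]


class PriorFamily(str, enum.Enum):
    HALF_NORMAL = "half_normal"
    NORMAL = "normal"


@dataclass(frozen=True)
class PriorSpec:
    """A parameter prior: untruncated Normal/HalfNormal density with the
    parameter range enforced as a hard box constraint during optimization
    (truncation renormalization would not move the mode inside the box)."""

    family: PriorFamily
    location: float
    scale: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if self.lower >= self.upper:
            raise ValueError("lower must be < upper")

    def logpdf(self, x: float) -> float:
        # closed forms (matching scipy.stats.halfnorm / norm) — this sits in
        # the optimizer's inner loop
        z = (x - self.location) / self.scale
        if self.family is PriorFamily.HALF_NORMAL:
            if x < self.location:
                return -math.inf
            return 0.5 * math.log(2.0 / math.pi) - math.log(self.scale) - 0.5 * z * z
        return -0.5 * math.log(2.0 * math.pi) - math.log(self.scale) - 0.5 * z * z

    def sample(self, rng: np.random.Generator) -> float:
        """One draw from the prior truncated to [lower, upper]."""
        if self.family is PriorFamily.HALF_NORMAL:
            # rejection from the half-normal; the box always has mass
            for _ in range(1000):
                x = self.location + abs(rng.normal(0.0, self.scale))
                if self.lower <= x <= self.upper:
                    return x
            return float(np.clip(x, self.lower, self.upper))
        a = (self.lower - self.location) / self.scale
        b = (self.upper - self.location) / self.scale
        return float(
            stats.truncnorm.rvs(a, b, loc=self.location, scale=self.scale, random_state=rng)
        )


def _hn(scale: float, lower: float, upper: float) -> PriorSpec:
    return PriorSpec(PriorFamily.HALF_NORMAL, 0.0, scale, lower, upper)


#: priors per model parameter: HalfNormal(0, 50) on alpha0/beta0,
#: Normal(1, 0.5) on omega, Normal(0.5, 0.5) on mu0, HalfNormal(0, 500) on nu,
#: HalfNormal(0, 0.5) on eta, HalfNormal(0, 2) on bias.
DEFAULT_PRIORS: dict[str, PriorSpec] = {
    "alpha0": _hn(50.0, 2.0, 100.0),
    "beta0": _hn(50.0, 2.0, 100.0),
    "omega": PriorSpec(PriorFamily.NORMAL, 1.0, 0.5, 0.0, 5.0),
    "mu0": PriorSpec(PriorFamily.NORMAL, 0.5, 0.5, 0.0, 1.0),
    "nu": _hn(500.0, 2.0, 1000.0),
    "eta": _hn(0.5, 0.0, 1.0),
    "bias": _hn(2.0, 0.0, 5.0),
}

#: observation count entering the BIC penalty.  All 21 reports enter the
#: likelihood, but the printed convention counts the 20 post-feedback
#: reports; set to 21 to count every observation.
DEFAULT_BIC_N = 20


@dataclass(frozen=True)
class FitConfig:
    n_restarts: int = 10
    tol: float = 1e-6
    seed: int = 0
    bic_n: int = DEFAULT_BIC_N
    priors: dict[str, PriorSpec] = field(default_factory=lambda: dict(DEFAULT_PRIORS))

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")


@dataclass(frozen=True)
class FitResult:
    model_id: int
    participant_id: str
    referent: str
    map_params: dict[str, float]
    log_likelihood: float
    log_posterior: float
    bic: float
    n_obs: int
    converged: bool
    n_restarts_agreeing: int = 1
    at_bound: bool = False

    @property
    def param_vector(self) -> np.ndarray:
        spec = get_model(self.model_id)
        return np.array([self.map_params[p] for p in spec.param_names])


def bic(log_likelihood: float, k: int, n: int) -> float:
    """Bayesian information criterion: -2 log L + k log n."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * log_likelihood + k * math.log(n)


def _log_likelihood(
    spec: ModelSpec, theta: np.ndarray, trajectory: BeliefTrajectory
) -> float:
    alphas, betas = spec.propagate(theta, trajectory.feedback)
    return float(np.sum(report_logdensity(alphas, betas, trajectory.reports)))


def _log_prior(spec: ModelSpec, theta: np.ndarray, priors: dict[str, PriorSpec]) -> float:
    return sum(priors[name].logpdf(x) for name, x in zip(spec.param_names, theta))


def log_posterior(
    model_id: int,
    params: Sequence[float],
    trajectory: BeliefTrajectory,
    priors: dict[str, PriorSpec] | None = None,
) -> float:
    """Unnormalized log posterior: report log-likelihood + log priors."""
    spec = get_model(model_id)
    theta = spec.check_params(params)
    priors = priors if priors is not None else DEFAULT_PRIORS
    return _log_likelihood(spec, theta, trajectory) + _log_prior(spec, theta, priors)


_BOUND_TOL = 1e-6


def fit_map(
    model_id: int,
    trajectory: BeliefTrajectory,
    config: FitConfig | None = None,
) -> FitResult:
    """Posterior-mode fit by multi-start L-BFGS-B.

    Start points are the bounds midpoint plus ``n_restarts`` draws from the
    (truncated) priors.  The best mode wins; ties between restarts are
    broken by log posterior, then lexicographically smallest parameter
    vector, so the result is deterministic given ``config.seed``.
    """
    config = config or FitConfig()
    spec = get_model(model_id)
    priors = config.priors
    rng = np.random.default_rng(config.seed)
    bounds = list(spec.bounds)

    def neg_objective(theta: np.ndarray) -> float:
        theta = np.clip(theta, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        try:
            ll = _log_likelihood(spec, theta, trajectory)
        except ValueError:
            # degenerate corner of the box (e.g. omega = 0 under negative
            # feedback): treat as -inf posterior
            return 1e12
        val = ll + _log_prior(spec, theta, priors)
        return -val if np.isfinite(val) else 1e12

    starts = [spec.midpoint()]
    for _ in range(config.n_restarts):
        starts.append(np.array([priors[p].sample(rng) for p in spec.param_names]))

    candidates = []
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            neg_objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": config.tol, "maxiter": 500},
        )
        theta = np.clip(res.x, [lo for lo, _ in bounds], [hi for _, hi in bounds])
        candidates.append((-res.fun, theta, bool(res.success)))
        any_converged = any_converged or res.success

    # best log posterior; ties -> lexicographically smallest theta
    best_lp = max(c[0] for c in candidates)
    tied = [c for c in candidates if abs(c[0] - best_lp) < 1e-6]
    tied.sort(key=lambda c: tuple(c[1]))
    _, theta_hat, _ = tied[0]
    n_agree = len(tied)

    ll = _log_likelihood(spec, theta_hat, trajectory)
    lp = ll + _log_prior(spec, theta_hat, priors)
    at_bound = any(
        x - lo < _BOUND_TOL or hi - x < _BOUND_TOL
        for x, (lo, hi) in zip(theta_hat, bounds)
    )
    return FitResult(
        model_id=model_id,
        participant_id=trajectory.participant_id,
        referent=trajectory.referent.value,
        map_params=dict(zip(spec.param_names, (float(x) for x in theta_hat))),
        log_likelihood=ll,
        log_posterior=lp,
        bic=bic(ll, spec.k, config.bic_n),
        n_obs=len(trajectory.reports),
        converged=any_converged,
        n_restarts_agreeing=n_agree,
        at_bound=at_bound,
    )


# ---------------------------------------------------------------------------
# fits.csv I/O
# ---------------------------------------------------------------------------


def fits_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    rows = []
    for f in fits:
        row = {
            "participant_id": f.participant_id,
            "referent": f.referent,
            "model_id": f.model_id,
            **f.map_params,
            "log_likelihood": f.log_likelihood,
            "log_posterior": f.log_posterior,
            "bic": f.bic,
            "converged": f.converged,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def write_fits(fits: Sequence[FitResult], path) -> None:
    fits_to_frame(fits).to_csv(path, index=False)


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path)


def default_config_json() -> str:
    """The versioned default prior/bounds specification, as JSON."""
    payload = {
        "bic_n": DEFAULT_BIC_N,
        "priors": {
            name: {
                "family": p.family.value,
                "location": p.location,
                "scale": p.scale,
                "lower": p.lower,
                "upper": p.upper,
            }
            for name, p in DEFAULT_PRIORS.items()
        },
    }
    return json.dumps(payload, indent=2)
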