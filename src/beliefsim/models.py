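"""Belief-updating models over Beta-distributed beliefs.

Four registered models share an observation architecture: on every trial the
reported probability is a single draw from the current Beta belief
distribution.  They differ in how the distribution's parameters move in
response to binary feedback:

====  ==========================  =================================
id    update rule                 free parameters
====  ==========================  =================================
1     Bayesian, biased            alpha0, beta0, omega
2     Bayesian, unbiased (w=1)    alpha0, beta0
3     Rescorla-Wagner, biased     mu0, nu, eta, b
4     Rescorla-Wagner, unbiased   mu0, nu, eta
====  ==========================  =================================

The registry is open: additional models may be registered by client code via
:func:`register_model`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import betaln, xlog1py, xlogy

__all__ = [
    "Referent",
    "Framing",
    "FeedbackOrder",
    "BeliefTrajectory",
    "BeliefState",
    "RWParams",
    "BayesParams",
    "ModelSpec",
    "MODEL_REGISTRY",
    "register_model",
    "get_model",
    "mean_precision_to_shape",
    "rw_update",
    "bayes_update",
    "report_logdensity",
    "propagate_states",
    "simulate_trajectory",
    "read_trajectories",
    "write_trajectories",
    "DEFAULT_CLIP_EPS",
]

#: reports and RW means are clipped into [eps, 1-eps] before Beta evaluation
DEFAULT_CLIP_EPS = 1e-4

N_TRIALS = 20


class Referent(str, enum.Enum):
    SELF = "self"
    OTHER = "other"


class Framing(str, enum.Enum):
    TOP_HALF = "top_half"
    BOTTOM_HALF = "bottom_half"


class FeedbackOrder(str, enum.Enum):
    POSITIVE_FIRST = "positive_first"
    NEGATIVE_FIRST = "negative_first"


@dataclass(frozen=True)
class BeliefTrajectory:
    """One participant x referent run: 20 binary feedbacks, 21 reports.

    Reports are stored in the canonical "probability of being in the top
    half" convention; runs collected under bottom-half framing are flipped
    (q -> 1-q) at ingest.
    """

    participant_id: str
    referent: Referent
    framing: Framing
    feedback: np.ndarray  # shape (20,), values in {0, 1}
    reports: np.ndarray  # shape (21,), values in [0, 1]; reports[0] pre-feedback
    feedback_order: FeedbackOrder = FeedbackOrder.POSITIVE_FIRST

    def __post_init__(self) -> None:
        fb = np.asarray(self.feedback, dtype=int)
        rp = np.asarray(self.reports, dtype=float)
        if fb.shape != (N_TRIALS,):
            raise ValueError(f"feedback must have length {N_TRIALS}, got {fb.shape}")
        if rp.shape != (N_TRIALS + 1,):
            raise ValueError(
                f"reports must have length {N_TRIALS + 1}, got {rp.shape}"
            )
        if not np.isin(fb, (0, 1)).all():
            raise ValueError("feedback values must be 0 or 1")
        if (rp < 0).any() or (rp > 1).any():
            raise ValueError("reports must lie in [0, 1]")
        object.__setattr__(self, "feedback", fb)
        object.__setattr__(self, "reports", rp)
        object.__setattr__(self, "referent", Referent(self.referent))
        object.__setattr__(self, "framing", Framing(self.framing))
        object.__setattr__(self, "feedback_order", FeedbackOrder(self.feedback_order))

    @property
    def n_trials(self) -> int:
        return len(self.feedback)

    def updates(self) -> np.ndarray:
        """Signed report changes, aligned with the feedback that preceded them."""
        return np.diff(self.reports)


@dataclass(frozen=True)
class BeliefState:
    """Beta belief B(alpha, beta) at a given trial index."""

    alpha: float
    beta: float
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def _check_bounds(name: str, value: float, lo: float, hi: float) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name}={value} outside [{lo}, {hi}]")


@dataclass(frozen=True)
class RWParams:
    """Parameters of the Rescorla-Wagner models (3 biased, 4 with bias=1)."""

    mu0: float
    nu: float
    eta: float
    bias: float = 1.0

    def __post_init__(self) -> None:
        _check_bounds("mu0", self.mu0, 0.0, 1.0)
        _check_bounds("nu", self.nu, 2.0, 1000.0)
        _check_bounds("eta", self.eta, 0.0, 1.0)
        _check_bounds("bias", self.bias, 0.0, 5.0)


@dataclass(frozen=True)
class BayesParams:
    """Parameters of the Bayesian models (1 biased, 2 with omega=1)."""

    alpha0: float
    beta0: float
    omega: float = 1.0

    def __post_init__(self) -> None:
        _check_bounds("alpha0", self.alpha0, 2.0, 100.0)
        _check_bounds("beta0", self.beta0, 2.0, 100.0)
        _check_bounds("omega", self.omega, 0.0, 5.0)


# ---------------------------------------------------------------------------
# Core update / observation primitives
# ---------------------------------------------------------------------------


def mean_precision_to_shape(mu: float, nu: float) -> tuple[float, float]:
    """Map a (mean, precision) parameterization to Beta shapes.

    alpha = nu * mu, beta = nu * (1 - mu); hence alpha + beta = nu.
    """
    if not (0.0 < mu < 1.0):
        raise ValueError(f"mu={mu} must lie strictly in (0, 1)")
    if nu <= 0:
        raise ValueError(f"nu={nu} must be positive")
    return nu * mu, nu * (1.0 - mu)


def rw_update(mu_prev: float, feedback: int, eta: float, bias: float) -> float:
    """One Rescorla-Wagner step: min(mu + eta*(bias*X - mu), 1).

    With bias > 1 the target for positive feedback exceeds 1, so the mean is
    clamped from above; negative feedback always decays the mean toward 0.
    """
    if not (0.0 <= mu_prev <= 1.0):
        raise ValueError(f"mu_prev={mu_prev} outside [0, 1]")
    if not (0.0 <= eta <= 1.0):
        raise ValueError(f"eta={eta} outside [0, 1]")
    if not (0.0 <= bias <= 5.0):
        raise ValueError(f"bias={bias} outside [0, 5]")
    if feedback not in (0, 1):
        raise ValueError("feedback must be 0 or 1")
    mu = mu_prev + eta * (bias * feedback - mu_prev)
    return min(mu, 1.0)


def bayes_update(
    alpha_prev: float, beta_prev: float, feedback: int, omega: float
) -> tuple[float, float]:
    """One (possibly biased) Bayesian counting step.

    alpha += omega * X; beta += (1/omega) * (1 - X).  With omega = 1 this is
    exact Beta-Bernoulli conjugate updating.
    """
    if alpha_prev <= 0 or beta_prev <= 0:
        raise ValueError("shape parameters must be positive")
    if feedback not in (0, 1):
        raise ValueError("feedback must be 0 or 1")
    if omega <= 0 and feedback == 0:
        raise ValueError("omega must be positive when feedback is negative")
    alpha = alpha_prev + omega * feedback
    beta = beta_prev + (1.0 - feedback) / omega if feedback == 0 else beta_prev
    return alpha, beta


def report_logdensity(
    alpha: float | np.ndarray,
    beta: float | np.ndarray,
    report: float | np.ndarray,
    clip_eps: float = DEFAULT_CLIP_EPS,
) -> float | np.ndarray:
    """Beta log-density of a report, with boundary clipping.

    Reports of exactly 0 or 1 have zero or infinite density under most Beta
    distributions; clipping into [clip_eps, 1-clip_eps] keeps the likelihood
    finite.  Vectorized over all arguments.
    """
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if (alpha <= 0).any() or (beta <= 0).any():
        raise ValueError("Beta shape parameters must be positive")
    if not (0.0 < clip_eps < 0.1):
        raise ValueError("clip_eps must lie in (0, 0.1)")
    q = np.clip(np.asarray(report, dtype=float), clip_eps, 1.0 - clip_eps)
    out = xlogy(alpha - 1.0, q) + xlog1py(beta - 1.0, -q) - betaln(alpha, beta)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """A registered belief-updating model.

    ``propagate`` maps a free-parameter vector and a feedback sequence of
    length T to per-trial Beta shapes (arrays of length T+1, index 0 being
    the pre-feedback prior state).
    """

    model_id: int
    name: str
    param_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    propagate: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]
    fixed: dict[str, float] = field(default_factory=dict)

    @property
    def k(self) -> int:
        """Number of free parameters."""
        return len(self.param_names)

    def check_params(self, params: Sequence[float]) -> np.ndarray:
        theta = np.asarray(params, dtype=float)
        if theta.shape != (self.k,):
            raise ValueError(
                f"model {self.model_id} expects {self.k} parameters, got {theta.shape}"
            )
        for name, value, (lo, hi) in zip(self.param_names, theta, self.bounds):
            _check_bounds(name, value, lo, hi)
        return theta

    def midpoint(self) -> np.ndarray:
        return np.array([(lo + hi) / 2.0 for lo, hi in self.bounds])


def _propagate_bayes(
    alpha0: float, beta0: float, omega: float, feedback: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    T = len(feedback)
    alphas = np.empty(T + 1)
    betas = np.empty(T + 1)
    alphas[0], betas[0] = alpha0, beta0
    a, b = alpha0, beta0
    for t, x in enumerate(feedback, start=1):
        a, b = bayes_update(a, b, int(x), omega)
        alphas[t], betas[t] = a, b
    return alphas, betas


def _propagate_rw(
    mu0: float,
    nu: float,
    eta: float,
    bias: float,
    feedback: np.ndarray,
    clip_eps: float = DEFAULT_CLIP_EPS,
) -> tuple[np.ndarray, np.ndarray]:
    T = len(feedback)
    mus = np.empty(T + 1)
    mus[0] = mu0
    mu = mu0
    for t, x in enumerate(feedback, start=1):
        mu = rw_update(mu, int(x), eta, bias)
        mus[t] = mu
    # the dynamics follow the exact clamp; only the observation model needs
    # mu strictly inside (0, 1) for valid Beta shapes
    mu_obs = np.clip(mus, clip_eps, 1.0 - clip_eps)
    return nu * mu_obs, nu * (1.0 - mu_obs)


def _make_bayes_propagate(omega_fixed: float | None):
    def propagate(theta, feedback):
        if omega_fixed is None:
            alpha0, beta0, omega = theta
        else:
            (alpha0, beta0), omega = theta, omega_fixed
        return _propagate_bayes(alpha0, beta0, omega, feedback)

    return propagate


def _make_rw_propagate(bias_fixed: float | None):
    def propagate(theta, feedback):
        if bias_fixed is None:
            mu0, nu, eta, bias = theta
        else:
            (mu0, nu, eta), bias = theta, bias_fixed
        return _propagate_rw(mu0, nu, eta, bias, feedback)

    return propagate


MODEL_REGISTRY: dict[int, ModelSpec] = {}


def register_model(spec: ModelSpec, overwrite: bool = False) -> ModelSpec:
    if spec.model_id in MODEL_REGISTRY and not overwrite:
        raise ValueError(f"model id {spec.model_id} already registered")
    MODEL_REGISTRY[spec.model_id] = spec
    return spec


def get_model(model_id: int) -> ModelSpec:
    try:
        return MODEL_REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown model id {model_id}; registered: {sorted(MODEL_REGISTRY)}"
        ) from None


register_model(
    ModelSpec(
        model_id=1,
        name="bayes_biased",
        param_names=("alpha0", "beta0", "omega"),
        bounds=((2.0, 100.0), (2.0, 100.0), (0.0, 5.0)),
        propagate=_make_bayes_propagate(None),
    )
)
register_model(
    ModelSpec(
        model_id=2,
        name="bayes_unbiased",
        param_names=("alpha0", "beta0"),
        bounds=((2.0, 100.0), (2.0, 100.0)),
        propagate=_make_bayes_propagate(1.0),
        fixed={"omega": 1.0},
    )
)
register_model(
    ModelSpec(
        model_id=3,
        name="rw_biased",
        param_names=("mu0", "nu", "eta", "bias"),
        bounds=((0.0, 1.0), (2.0, 1000.0), (0.0, 1.0), (0.0, 5.0)),
        propagate=_make_rw_propagate(None),
    )
)
register_model(
    ModelSpec(
        model_id=4,
        name="rw_unbiased",
        param_names=("mu0", "nu", "eta"),
        bounds=((0.0, 1.0), (2.0, 1000.0), (0.0, 1.0)),
        propagate=_make_rw_propagate(1.0),
        fixed={"bias": 1.0},
    )
)


def propagate_states(
    model_id: int, params: Sequence[float], feedback: Sequence[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial Beta shapes (alphas, betas), index 0 = prior state."""
    spec = get_model(model_id)
    theta = spec.check_params(params)
    return spec.propagate(theta, np.asarray(feedback, dtype=int))


def simulate_trajectory(
    model_id: int,
    params: Sequence[float],
    feedback_seq: Sequence[int],
    seed: int | np.random.Generator,
    participant_id: str = "sim",
    referent: Referent = Referent.SELF,
    framing: Framing = Framing.TOP_HALF,
    feedback_order: FeedbackOrder = FeedbackOrder.POSITIVE_FIRST,
) -> BeliefTrajectory:
    """Forward-simulate a run: propagate beliefs and draw one report per trial."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    feedback = np.asarray(feedback_seq, dtype=int)
    alphas, betas = propagate_states(model_id, params, feedback)
    reports = rng.beta(alphas, betas)
    return BeliefTrajectory(
        participant_id=participant_id,
        referent=referent,
        framing=framing,
        feedback=feedback,
        reports=reports,
        feedback_order=feedback_order,
    )


# ---------------------------------------------------------------------------
# trajectories.csv I/O (long format)
# ---------------------------------------------------------------------------

_TRAJ_COLUMNS = [
    "participant_id",
    "referent",
    "framing",
    "feedback_order",
    "trial",
    "feedback",
    "report",
]


def write_trajectories(trajectories: Sequence[BeliefTrajectory], path) -> None:
    """Write runs in long format, undoing framing normalization on the way out.

    Reports for bottom-half-framed runs are stored as 1-q (the raw elicited
    value); :func:`read_trajectories` restores the canonical convention.
    """
    rows = []
    for traj in trajectories:
        reports = traj.reports
        if traj.framing is Framing.BOTTOM_HALF:
            reports = 1.0 - reports
        for t in range(traj.n_trials + 1):
            rows.append(
                {
                    "participant_id": traj.participant_id,
                    "referent": traj.referent.value,
                    "framing": traj.framing.value,
                    "feedback_order": traj.feedback_order.value,
                    "trial": t,
                    "feedback": "" if t == 0 else int(traj.feedback[t - 1]),
                    "report": reports[t],
                }
            )
    pd.DataFrame(rows, columns=_TRAJ_COLUMNS).to_csv(path, index=False)


def read_trajectories(path) -> list[BeliefTrajectory]:
    """Read trajectories.csv, validate invariants, normalize framing."""
    df = pd.read_csv(path)
    missing = set(_TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectories file missing columns: {sorted(missing)}")
    out = []
    for (pid, referent), grp in df.groupby(["participant_id", "referent"], sort=False):
        grp = grp.sort_values("trial")
        if list(grp["trial"]) != list(range(N_TRIALS + 1)):
            raise ValueError(f"run ({pid}, {referent}) has malformed trial index")
        framing = Framing(grp["framing"].iloc[0])
        reports = grp["report"].to_numpy(dtype=float)
        if framing is Framing.BOTTOM_HALF:
            reports = 1.0 - reports
        feedback = grp["feedback"].iloc[1:].to_numpy(dtype=float)
        out.append(
            BeliefTrajectory(
                participant_id=str(pid),
                referent=Referent(referent),
                framing=framing,
                feedback=feedback.astype(int),
                reports=reports,
                feedback_order=FeedbackOrder(grp["feedback_order"].iloc[0]),
            )
        )
    return out
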