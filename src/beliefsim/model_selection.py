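"""Random-effects model comparison and recovery diagnostics.

Model evidence is approximated per participant by -BIC/2.  A variational
random-effects scheme estimates a Dirichlet posterior over population model
frequencies; exceedance probabilities (the probability that each model is
the most prevalent) are estimated by Monte-Carlo argmax frequency over
Dirichlet draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import digamma, logsumexp
from scipy.stats import ks_2samp

from .fitting import FitConfig, FitResult, fit_map
from .models import get_model, simulate_trajectory

__all__ = [
    "EvidenceMatrix",
    "ComparisonResult",
    "ConfusionMatrix",
    "ComparisonConfig",
    "exceedance_probabilities",
    "evidence_from_bic",
    "prior_param_sampler",
    "cohort_param_sampler",
    "model_recovery",
    "PosteriorPredictiveResult",
    "posterior_predictive_updates",
]


@dataclass(frozen=True)
class EvidenceMatrix:
    """Participants x models log model evidence (here -BIC/2)."""

    log_evidence: np.ndarray
    participant_ids: tuple[str, ...]
    model_ids: tuple[int, ...]

    def __post_init__(self) -> None:
        le = np.asarray(self.log_evidence, dtype=float)
        if le.ndim != 2:
            raise ValueError("log_evidence must be 2-D (participants x models)")
        if le.shape != (len(self.participant_ids), len(self.model_ids)):
            raise ValueError("log_evidence shape does not match labels")
        if le.shape[1] < 1:
            raise ValueError("need at least one model")
        if not np.isfinite(le).all():
            raise ValueError("log evidence must be finite")
        object.__setattr__(self, "log_evidence", le)


def evidence_from_bic(fits: Sequence[FitResult]) -> EvidenceMatrix:
    """Assemble an EvidenceMatrix from per-participant fits (log ev = -BIC/2)."""
    df = pd.DataFrame(
        {
            "participant_id": [f.participant_id for f in fits],
            "model_id": [f.model_id for f in fits],
            "log_ev": [-f.bic / 2.0 for f in fits],
        }
    )
    wide = df.pivot_table(index="participant_id", columns="model_id", values="log_ev")
    if wide.isna().any().any():
        raise ValueError("every participant must be fitted by every model")
    return EvidenceMatrix(
        log_evidence=wide.to_numpy(),
        participant_ids=tuple(str(i) for i in wide.index),
        model_ids=tuple(int(m) for m in wide.columns),
    )


@dataclass(frozen=True)
class ComparisonConfig:
    alpha0: float = 1.0
    tol: float = 1e-6
    n_mc: int = 100_000
    seed: int = 0
    max_iter: int = 10_000


@dataclass(frozen=True)
class ComparisonResult:
    model_ids: tuple[int, ...]
    dirichlet_alpha: np.ndarray
    expected_freq: np.ndarray
    exceedance_prob: np.ndarray
    n_mc_samples: int
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_ids": list(self.model_ids),
                "dirichlet_alpha": list(map(float, self.dirichlet_alpha)),
                "expected_freq": list(map(float, self.expected_freq)),
                "exceedance_prob": list(map(float, self.exceedance_prob)),
                "n_mc_samples": self.n_mc_samples,
                "seed": self.seed,
            },
            indent=2,
        )


def exceedance_probabilities(
    evidence: EvidenceMatrix, config: ComparisonConfig | None = None
) -> ComparisonResult:
    """Variational random-effects model comparison.

    Iterates responsibilities u_nk ∝ exp(log_ev_nk + ψ(α_k) − ψ(Σα)) and
    pseudo-counts α_k = α0 + Σ_n u_nk to convergence, then estimates
    exceedance probabilities by argmax frequency over Dirichlet draws.
    """
    config = config or ComparisonConfig()
    le = evidence.log_evidence
    n, K = le.shape
    alpha = np.full(K, config.alpha0, dtype=float)
    for _ in range(config.max_iter):
        log_u = le + digamma(alpha) - digamma(alpha.sum())
        log_u -= logsumexp(log_u, axis=1, keepdims=True)
        u = np.exp(log_u)
        alpha_new = config.alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < config.tol:
            alpha = alpha_new
            break
        alpha = alpha_new

    expected = alpha / alpha.sum()
    if K == 1:
        xp = np.array([1.0])
    else:
        rng = np.random.default_rng(config.seed)
        draws = rng.dirichlet(alpha, size=config.n_mc)
        winners = np.argmax(draws, axis=1)
        xp = np.bincount(winners, minlength=K) / config.n_mc
    return ComparisonResult(
        model_ids=evidence.model_ids,
        dirichlet_alpha=alpha,
        expected_freq=expected,
        exceedance_prob=xp,
        n_mc_samples=config.n_mc,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Model recovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    """Generating-model x recovering-model winner percentages (rows sum to 100)."""

    model_ids: tuple[int, ...]
    percentages: np.ndarray
    n_sim: int

    def to_frame(self) -> pd.DataFrame:
        labels = [f"model_{m}" for m in self.model_ids]
        return pd.DataFrame(self.percentages, index=labels, columns=labels)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path)


ParamSampler = Callable[[int, np.random.Generator], np.ndarray]


def prior_param_sampler(model_id: int, rng: np.random.Generator) -> np.ndarray:
    """Draw generating parameters from the MAP priors truncated to bounds."""
    from .fitting import DEFAULT_PRIORS

    spec = get_model(model_id)
    return np.array([DEFAULT_PRIORS[p].sample(rng) for p in spec.param_names])


def cohort_param_sampler(fits: Sequence[FitResult]) -> ParamSampler:
    """A sampler moment-matched to fitted estimates (per model, per parameter).

    Draws each parameter from a normal with the empirical mean/sd of the MAP
    estimates, truncated to the model's bounds by rejection.
    """
    by_model: dict[int, pd.DataFrame] = {}
    for mid in {f.model_id for f in fits}:
        rows = [f.map_params for f in fits if f.model_id == mid]
        by_model[mid] = pd.DataFrame(rows)

    def sampler(model_id: int, rng: np.random.Generator) -> np.ndarray:
        spec = get_model(model_id)
        df = by_model.get(model_id)
        if df is None or df.empty:
            raise ValueError(f"no fits available for model {model_id}")
        out = np.empty(spec.k)
        for j, (name, (lo, hi)) in enumerate(zip(spec.param_names, spec.bounds)):
            m, s = df[name].mean(), max(df[name].std(ddof=1), 1e-6)
            for _ in range(1000):
                x = rng.normal(m, s)
                if lo <= x <= hi:
                    break
            else:
                x = float(np.clip(m, lo, hi))
            out[j] = x
        return out

    return sampler


def model_recovery(
    model_ids: Sequence[int],
    param_sampler: ParamSampler,
    n_sim: int,
    feedback_seq: Sequence[int],
    seed: int = 0,
    fit_config: FitConfig | None = None,
) -> ConfusionMatrix:
    """Simulate runs from each model, refit all candidates, tally BIC winners."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    model_ids = tuple(int(m) for m in model_ids)
    rng = np.random.default_rng(seed)
    fit_config = fit_config or FitConfig(n_restarts=4)
    K = len(model_ids)
    counts = np.zeros((K, K), dtype=int)
    for i, gen in enumerate(model_ids):
        spec = get_model(gen)
        for s in range(n_sim):
            theta = np.asarray(param_sampler(gen, rng), dtype=float)
            spec.check_params(theta)  # out-of-bounds sampler output is an error
            traj = simulate_trajectory(
                gen, theta, feedback_seq, rng, participant_id=f"sim_{gen}_{s}"
            )
            bics = [fit_map(m, traj, fit_config).bic for m in model_ids]
            counts[i, int(np.argmin(bics))] += 1
    return ConfusionMatrix(
        model_ids=model_ids,
        percentages=100.0 * counts / n_sim,
        n_sim=n_sim,
    )


# ---------------------------------------------------------------------------
# Posterior-predictive update check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PosteriorPredictiveResult:
    mean_update_after_positive: np.ndarray  # one entry per replicate
    mean_update_after_negative: np.ndarray
    observed_mean_after_positive: float
    observed_mean_after_negative: float
    ks_statistic: float
    ks_pvalue: float
    n_rep: int


def posterior_predictive_updates(
    fit: FitResult,
    trajectory,
    n_rep: int = 20,
    seed: int = 0,
) -> PosteriorPredictiveResult:
    """Simulate replicates at the MAP and compare update distributions.

    For each replicate the signed report changes are averaged separately for
    trials following positive and negative feedback; a two-sample KS test
    compares all simulated updates against the observed ones.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if not fit.converged:
        raise ValueError("posterior-predictive check requires a converged fit")
    rng = np.random.default_rng(seed)
    theta = fit.param_vector
    pos = trajectory.feedback == 1
    obs_updates = trajectory.updates()

    mean_pos = np.empty(n_rep)
    mean_neg = np.empty(n_rep)
    sim_updates = []
    for r in range(n_rep):
        sim = simulate_trajectory(
            fit.model_id, theta, trajectory.feedback, rng,
            participant_id=trajectory.participant_id,
        )
        upd = sim.updates()
        mean_pos[r] = upd[pos].mean()
        mean_neg[r] = upd[~pos].mean()
        sim_updates.append(upd)
    ks = ks_2samp(np.concatenate(sim_updates), obs_updates)
    return PosteriorPredictiveResult(
        mean_update_after_positive=mean_pos,
        mean_update_after_negative=mean_neg,
        observed_mean_after_positive=float(obs_updates[pos].mean()),
        observed_mean_after_negative=float(obs_updates[~pos].mean()),
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        n_rep=n_rep,
    )
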