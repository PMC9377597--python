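"""Synthetic cohort generation.

Builds cohorts carrying the effect structure the downstream analysis is
designed to detect: three orthogonal latent affect factors, biased-RW
belief parameters whose unconstrained transforms are coupled to the factors
through a Gaussian copula (depression -> prior mean, anxiety -> updating
bias, plus a prior-mean/bias "confirmation" correlation), a weakly
depression-linked popularity percentage that is nearly uncorrelated with
prior beliefs, Likert item responses generated from a fixed loadings
matrix, and optional "careless" participants whose reports ignore feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit

from .models import (
    BeliefTrajectory,
    FeedbackOrder,
    Framing,
    Referent,
    simulate_trajectory,
)

__all__ = [
    "CohortConfig",
    "Cohort",
    "canonical_feedback_sequences",
    "sample_cohort",
    "sample_item_responses",
    "default_loadings",
    "FACTOR_NAMES",
]

FACTOR_NAMES = ("general", "anxiety_specific", "depression_specific")

# fixed pair of counterbalanced feedback orders: positive-first starts 1,1,
# carries six positives in the first ten trials and ten positives overall;
# negative-first is its elementwise complement
_POSITIVE_FIRST = np.array(
    [1, 1, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1, 0, 1, 0, 0, 1, 0, 1, 0], dtype=int
)


def canonical_feedback_sequences() -> tuple[np.ndarray, np.ndarray]:
    """The two counterbalanced 20-trial feedback sequences (pos-first, neg-first)."""
    pos = _POSITIVE_FIRST.copy()
    return pos, 1 - pos


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the generative cohort model.

    Planted correlations operate on the unconstrained parameter scales
    (logit for mu0 and eta, log for nu and bias) before transforming into
    each parameter's bounds, so empirical correlations on the natural scale
    are mildly attenuated.
    """

    n_participants: int = 66
    seed: int = 0
    # planted factor -> parameter correlations (latent, unconstrained scale)
    depression_mu0_corr: float = -0.33
    anxiety_bias_corr: float = -0.32
    confirm_corr: float = 0.5  # mu0 <-> bias coupling
    popularity_corr: float = -0.17  # depression -> popularity
    # location/spread of model-3 parameters on unconstrained scales
    mu0_logit_mean: float = 0.0
    mu0_logit_sd: float = 0.8
    bias_log_mean: float = 0.0
    bias_log_sd: float = 0.4
    nu_log_mean: float = float(np.log(320.0))
    nu_log_sd: float = 0.5
    eta_logit_mean: float = float(logit(0.098))
    eta_logit_sd: float = 0.5
    # other-referent runs: positive shift relative to self
    other_mu0_logit_shift: float = 0.2
    other_bias_log_shift: float = 0.15
    other_carryover: float = 0.5  # latent correlation between self and other params
    fraction_bottom_framing: float = 0.5
    careless_fraction: float = 0.0
    item_noise_sd: float = 0.8

    def __post_init__(self) -> None:
        for name in ("depression_mu0_corr", "anxiety_bias_corr", "confirm_corr", "popularity_corr"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")
        for name in ("fraction_bottom_framing", "careless_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path) -> None:
        payload = {k: getattr(self, k) for k in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


@dataclass(frozen=True)
class Cohort:
    config: CohortConfig
    participants: pd.DataFrame  # factor scores, true params, popularity, flags
    trajectories: list[BeliefTrajectory] = field(repr=False)
    item_responses: pd.DataFrame = field(repr=False)
    loadings: pd.DataFrame = field(repr=False)

    def write(self, out_dir) -> None:
        from .models import write_trajectories

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_trajectories(self.trajectories, out / "trajectories.csv")
        self.participants.to_csv(out / "cohort.csv", index=False)
        self.item_responses.to_csv(out / "items.csv", index=False)
        self.loadings.to_csv(out / "loadings.csv", index=True)
        self.config.to_yaml(out / "config.yaml")


def _latent_correlation_matrix(config: CohortConfig) -> np.ndarray:
    """Correlation over (general, anxiety, depression, z_mu0, z_bias)."""
    C = np.eye(5)

    def put(i, j, v):
        C[i, j] = C[j, i] = v

    put(1, 4, config.anxiety_bias_corr)  # anxiety <-> z_bias
    put(2, 3, config.depression_mu0_corr)  # depression <-> z_mu0
    put(3, 4, config.confirm_corr)  # z_mu0 <-> z_bias
    eig = np.linalg.eigvalsh(C)
    if eig.min() <= 1e-10:
        raise ValueError(
            "planted correlations do not form a positive-definite matrix"
        )
    return C


def _careless_reports(rng: np.random.Generator, n_trials: int = 20) -> np.ndarray:
    """A feedback-blind random walk on the probability slider."""
    q = np.empty(n_trials + 1)
    q[0] = rng.uniform(0.2, 0.8)
    for t in range(1, n_trials + 1):
        q[t] = np.clip(q[t - 1] + rng.normal(0.0, 0.15), 0.02, 0.98)
    return q


def sample_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw a full cohort: factors, parameters, trajectories, items, popularity."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants

    L = np.linalg.cholesky(_latent_correlation_matrix(config))
    z = rng.standard_normal((n, 5)) @ L.T
    general, anxiety, depression, z_mu0, z_bias = z.T

    def bounded(x, lo, hi, eps=1e-3):
        return np.clip(x, lo + eps, hi - eps)

    mu0 = bounded(expit(config.mu0_logit_mean + config.mu0_logit_sd * z_mu0), 0, 1)
    bias = bounded(np.exp(config.bias_log_mean + config.bias_log_sd * z_bias), 0, 5)
    nu = bounded(np.exp(config.nu_log_mean + config.nu_log_sd * rng.standard_normal(n)), 2, 1000)
    eta = bounded(
        expit(config.eta_logit_mean + config.eta_logit_sd * rng.standard_normal(n)), 0, 1
    )

    # other-referent parameters: partially carried over, shifted positive
    rho = config.other_carryover
    fresh = rng.standard_normal((n, 2))
    z_mu0_o = rho * z_mu0 + np.sqrt(1 - rho**2) * fresh[:, 0]
    z_bias_o = rho * z_bias + np.sqrt(1 - rho**2) * fresh[:, 1]
    mu0_other = bounded(
        expit(config.mu0_logit_mean + config.other_mu0_logit_shift
              + config.mu0_logit_sd * z_mu0_o), 0, 1
    )
    bias_other = bounded(
        np.exp(config.bias_log_mean + config.other_bias_log_shift
               + config.bias_log_sd * z_bias_o), 0, 5
    )

    # popularity: weak planted depression link; correlation with mu0 arises
    # only through depression (product of two small/medium r's, near zero)
    rp = config.popularity_corr
    pop_z = rp * depression + np.sqrt(1 - rp**2) * rng.standard_normal(n)
    popularity = np.clip(50.0 + 13.0 * pop_z, 1.0, 99.0)

    pos_first, neg_first = canonical_feedback_sequences()
    n_careless = int(round(config.careless_fraction * n))
    careless_ids = set(rng.choice(n, size=n_careless, replace=False)) if n_careless else set()

    trajectories: list[BeliefTrajectory] = []
    rows = []
    for i in range(n):
        pid = f"p{i:03d}"
        order = FeedbackOrder.POSITIVE_FIRST if i % 2 == 0 else FeedbackOrder.NEGATIVE_FIRST
        feedback = pos_first if order is FeedbackOrder.POSITIVE_FIRST else neg_first
        framing = (
            Framing.BOTTOM_HALF
            if rng.random() < config.fraction_bottom_framing
            else Framing.TOP_HALF
        )
        careless = i in careless_ids
        for referent, params in (
            (Referent.SELF, (mu0[i], nu[i], eta[i], bias[i])),
            (Referent.OTHER, (mu0_other[i], nu[i], eta[i], bias_other[i])),
        ):
            if careless:
                traj = BeliefTrajectory(
                    participant_id=pid,
                    referent=referent,
                    framing=framing,
                    feedback=feedback,
                    reports=_careless_reports(rng),
                    feedback_order=order,
                )
            else:
                traj = simulate_trajectory(
                    3, params, feedback, rng,
                    participant_id=pid, referent=referent,
                    framing=framing, feedback_order=order,
                )
            trajectories.append(traj)
        rows.append(
            {
                "participant_id": pid,
                "general": general[i],
                "anxiety_specific": anxiety[i],
                "depression_specific": depression[i],
                "true_mu0": mu0[i],
                "true_nu": nu[i],
                "true_eta": eta[i],
                "true_bias": bias[i],
                "true_mu0_other": mu0_other[i],
                "true_bias_other": bias_other[i],
                "popularity": popularity[i],
                "feedback_order": order.value,
                "framing": framing.value,
                "careless": careless,
                "failed_catch": False,
            }
        )
    participants = pd.DataFrame(rows)

    loadings = default_loadings()
    factor_scores = participants[list(FACTOR_NAMES)].to_numpy()
    items = sample_item_responses(
        factor_scores, loadings.to_numpy(), config.item_noise_sd,
        rng.integers(2**31),
    )
    item_df = pd.DataFrame(items, columns=loadings.index)
    item_df.insert(0, "participant_id", participants["participant_id"])

    return Cohort(
        config=config,
        participants=participants,
        trajectories=trajectories,
        item_responses=item_df,
        loadings=loadings,
    )


# ---------------------------------------------------------------------------
# Questionnaire item model
# ---------------------------------------------------------------------------

_N_ITEMS = 95
_LOADINGS_SEED = 20220428  # fixture is deterministic by construction


def default_loadings(n_items: int = _N_ITEMS) -> pd.DataFrame:
    """A fixed items x 3 loadings matrix with a bifactor-like pattern.

    Every item loads moderately on the general factor; the first block
    (anhedonia-flavoured items) loads highly on the depression-specific
    factor, the second (worry-flavoured) on the anxiety-specific factor,
    and the remainder only weakly on either specific factor.
    """
    rng = np.random.default_rng(_LOADINGS_SEED)
    n_dep = n_items // 4
    n_anx = n_items // 4
    gen = rng.uniform(0.3, 0.55, size=n_items)
    dep = np.zeros(n_items)
    anx = np.zeros(n_items)
    dep[:n_dep] = rng.uniform(0.4, 0.65, size=n_dep)
    anx[n_dep:n_dep + n_anx] = rng.uniform(0.4, 0.65, size=n_anx)
    rest = slice(n_dep + n_anx, n_items)
    dep[rest] = rng.uniform(0.0, 0.15, size=n_items - n_dep - n_anx)
    anx[rest] = rng.uniform(0.0, 0.15, size=n_items - n_dep - n_anx)
    items = (
        [f"anhedonia_{i:02d}" for i in range(n_dep)]
        + [f"worry_{i:02d}" for i in range(n_anx)]
        + [f"distress_{i:02d}" for i in range(n_items - n_dep - n_anx)]
    )
    df = pd.DataFrame(
        {"general": gen, "anxiety_specific": anx, "depression_specific": dep},
        index=pd.Index(items, name="item"),
    )
    communality = (df.to_numpy() ** 2).sum(axis=1)
    assert communality.max() < 1.0
    return df


def sample_item_responses(
    factor_scores: np.ndarray,
    loadings: np.ndarray,
    noise_sd: float,
    seed: int | np.random.Generator,
    likert_levels: int = 4,
    discretize: bool = True,
) -> np.ndarray:
    """Linear factor model responses, optionally discretized to a Likert range."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    scores = np.atleast_2d(np.asarray(factor_scores, dtype=float))
    lam = np.asarray(loadings, dtype=float)
    if scores.shape[1] != lam.shape[1]:
        raise ValueError(
            f"factor dimension mismatch: scores {scores.shape[1]} vs loadings {lam.shape[1]}"
        )
    continuous = scores @ lam.T + noise_sd * rng.standard_normal((scores.shape[0], lam.shape[0]))
    if not discretize:
        return continuous
    centre = (1 + likert_levels) / 2.0
    return np.clip(np.rint(centre + continuous), 1, likert_levels).astype(int)
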