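"""Downstream individual-differences statistics.

Exclusion filters, model-agnostic belief indices, permutation-based
correlation inference with Benjamini-Hochberg FDR, joint regressions with
permutation tests on between-model coefficient differences, and a linear
bootstrap mediation (product-of-coefficients ACME).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .models import BeliefTrajectory

__all__ = [
    "CorrelationResult",
    "MediationResult",
    "directional_error_filter",
    "model_agnostic_indices",
    "permutation_corr",
    "bh_adjust",
    "joint_regression_coef_diff",
    "bootstrap_mediation",
    "build_analysis_report",
]

FACTOR_COLUMNS = ("general", "anxiety_specific", "depression_specific")
MODEL3_PARAMS = ("mu0", "nu", "eta", "bias")

DIRECTIONAL_ERROR_EXCLUSION_THRESHOLD = 9


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_uncorrected: float
    n_perm: int
    seed: int | None
    p_fdr: float | None = None
    exact: bool = False


@dataclass(frozen=True)
class MediationResult:
    acme: float
    acme_p: float
    acme_ci: tuple[float, float]
    direct_effect: float
    total_effect: float
    n_boot: int
    seed: int


def directional_error_filter(trajectory: BeliefTrajectory) -> tuple[int, bool]:
    """Count anti-feedback report moves; 9 or more flags the run for exclusion.

    A directional error is a strict decrease after positive feedback or a
    strict increase after negative feedback.  Leaving the report unchanged
    is never an error.
    """
    updates = trajectory.updates()
    fb = trajectory.feedback
    errors = int(((fb == 1) & (updates < 0)).sum() + ((fb == 0) & (updates > 0)).sum())
    return errors, errors >= DIRECTIONAL_ERROR_EXCLUSION_THRESHOLD


def model_agnostic_indices(trajectory: BeliefTrajectory) -> tuple[float, float, float]:
    """(starting belief, ending belief, belief change = end - start)."""
    start = float(trajectory.reports[0])
    end = float(trajectory.reports[-1])
    return start, end, end - start


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def permutation_corr(
    x,
    y,
    n_perm: int = 10_000,
    seed: int = 0,
    enumerate_small: bool = False,
) -> CorrelationResult:
    """Two-tailed permutation test for a Pearson correlation.

    The sampled p uses the add-one correction (1 + #extreme)/(n_perm + 1),
    so p >= 1/(n_perm+1) always.  With ``enumerate_small`` and n <= 7 all
    n! permutations are enumerated and the p-value is exact.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")

    r_obs = _pearson(x, y)

    if enumerate_small and n <= 7:
        count = 0
        total = math.factorial(n)
        for perm in itertools.permutations(range(n)):
            if abs(_pearson(x, y[list(perm)])) >= abs(r_obs) - 1e-12:
                count += 1
        return CorrelationResult(
            r=r_obs, p_uncorrected=count / total, n_perm=total, seed=None, exact=True
        )

    rng = np.random.default_rng(seed)
    # vectorized: z-score once, correlate permuted y against fixed x
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    r_null = (yz[perms] @ xz) / n
    count = int((np.abs(r_null) >= abs(r_obs) - 1e-12).sum())
    p = (1 + count) / (n_perm + 1)
    return CorrelationResult(r=r_obs, p_uncorrected=p, n_perm=n_perm, seed=seed)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def joint_regression_coef_diff(
    factor_scores: pd.DataFrame,
    mu0_estimates,
    b_estimates,
    n_perm: int = 10_000,
    seed: int = 0,
    include_interaction: bool = False,
) -> dict:
    """Per-factor OLS of factor score on (mu0, b), plus permutation tests on
    between-factor coefficient differences.

    For each factor column an OLS ``factor ~ mu0 + b`` is fitted.  The
    coefficient-difference statistics compare, e.g., the mu0 coefficient in
    the depression-factor model against the anxiety-factor model; their null
    distribution is built by jointly permuting whole factor-score rows
    against the (fixed) parameter rows, preserving the mu0-b dependence.
    With ``include_interaction`` each factor also gets a likelihood-ratio
    test of adding the mu0 x b term.
    """
    mu0 = np.asarray(mu0_estimates, dtype=float)
    b = np.asarray(b_estimates, dtype=float)
    F = factor_scores.to_numpy(dtype=float)
    if not (len(mu0) == len(b) == F.shape[0]):
        raise ValueError("factor scores and parameter estimates must align by row")
    if F.shape[0] < 10:
        raise ValueError("need at least 10 participants")

    X = sm.add_constant(np.column_stack([mu0, b]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design (mu0, b collinear?)")

    factors = list(factor_scores.columns)

    def coefs(Fmat: np.ndarray) -> np.ndarray:
        """OLS coefficients of every factor on X at once; rows = (const, mu0, b)."""
        return np.linalg.lstsq(X, Fmat, rcond=None)[0]

    regressions = {}
    for j, name in enumerate(factors):
        res = sm.OLS(F[:, j], X).fit()
        entry = {
            "coef": {"const": res.params[0], "mu0": res.params[1], "b": res.params[2]},
            "pvalues": {"mu0": float(res.pvalues[1]), "b": float(res.pvalues[2])},
            "r_squared": float(res.rsquared),
        }
        if include_interaction:
            Xi = sm.add_constant(np.column_stack([mu0, b, mu0 * b]))
            res_i = sm.OLS(F[:, j], Xi).fit()
            lr = 2.0 * (res_i.llf - res.llf)
            entry["interaction_lrt_p"] = float(stats.chi2.sf(lr, df=1))
            entry["interaction_coef"] = float(res_i.params[3])
        regressions[name] = entry

    # observed coefficient differences between factor models
    beta_obs = coefs(F)  # (3 predictors incl. const) x (n_factors)
    contrasts = []
    for predictor, row in (("mu0", 1), ("b", 2)):
        for fa, fb_ in itertools.combinations(range(len(factors)), 2):
            contrasts.append((predictor, row, fa, fb_))

    rng = np.random.default_rng(seed)
    obs_diffs = np.array([beta_obs[row, fa] - beta_obs[row, fb_] for _, row, fa, fb_ in contrasts])
    exceed = np.zeros(len(contrasts), dtype=int)
    for _ in range(n_perm):
        Fp = F[rng.permutation(F.shape[0])]
        beta_p = coefs(Fp)
        null_diffs = np.array(
            [beta_p[row, fa] - beta_p[row, fb_] for _, row, fa, fb_ in contrasts]
        )
        exceed += np.abs(null_diffs) >= np.abs(obs_diffs) - 1e-12

    diff_tests = {}
    for (predictor, _, fa, fb_), d, c in zip(contrasts, obs_diffs, exceed):
        key = f"{predictor}:{factors[fa]}-{factors[fb_]}"
        diff_tests[key] = {
            "difference": float(d),
            "p": (1 + int(c)) / (n_perm + 1),
        }

    return {
        "regressions": regressions,
        "coefficient_differences": diff_tests,
        "n_perm": n_perm,
        "seed": seed,
    }


def bootstrap_mediation(
    x, mediator, y, n_boot: int = 5_000, seed: int = 0
) -> MediationResult:
    """Linear product-of-coefficients mediation with a percentile bootstrap.

    ACME = a*b where a is the slope of mediator ~ x and b the mediator slope
    of y ~ x + mediator; for linear models total = ACME + direct exactly.
    """
    x = np.asarray(x, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (len(x) == len(m) == len(y)):
        raise ValueError("inputs must align")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 observations")

    def acme_direct_total(xi, mi, yi):
        Xa = sm.add_constant(xi)
        a = np.linalg.lstsq(Xa, mi, rcond=None)[0][1]
        Xb = sm.add_constant(np.column_stack([xi, mi]))
        coef = np.linalg.lstsq(Xb, yi, rcond=None)[0]
        direct, b = coef[1], coef[2]
        total = np.linalg.lstsq(Xa, yi, rcond=None)[0][1]
        return a * b, direct, total

    acme, direct, total = acme_direct_total(x, m, y)

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[i], _, _ = acme_direct_total(x[idx], m[idx], y[idx])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    p = 2.0 * min((boots <= 0).mean(), (boots >= 0).mean())
    p = min(max(p, 1.0 / n_boot), 1.0)
    return MediationResult(
        acme=float(acme),
        acme_p=float(p),
        acme_ci=(float(lo), float(hi)),
        direct_effect=float(direct),
        total_effect=float(total),
        n_boot=n_boot,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Full analysis report
# ---------------------------------------------------------------------------


def build_analysis_report(
    fits: pd.DataFrame,
    cohort: pd.DataFrame,
    trajectories: list[BeliefTrajectory] | None = None,
    n_perm: int = 10_000,
    n_boot: int = 5_000,
    seed: int = 0,
    model_id: int = 3,
) -> dict:
    """Run the downstream statistics end to end and return a JSON-ready dict.

    Expects ``fits`` in the fits.csv layout (participant_id, referent,
    model_id, parameter columns) and ``cohort`` with factor-score columns,
    popularity and exclusion flag columns.  If trajectories are supplied the
    directional-error filter is applied; careless/failed_catch flags in the
    cohort table are honored either way.
    """
    excluded: dict[str, str] = {}
    error_counts: dict[str, int] = {}
    if trajectories is not None:
        for traj in trajectories:
            if traj.referent.value != "self":
                continue
            n_err, flag = directional_error_filter(traj)
            error_counts[traj.participant_id] = n_err
            if flag:
                excluded[traj.participant_id] = "directional_errors"
    if "failed_catch" in cohort.columns:
        for pid in cohort.loc[cohort["failed_catch"].astype(bool), "participant_id"]:
            excluded.setdefault(str(pid), "failed_catch")

    keep = ~cohort["participant_id"].astype(str).isin(excluded)
    cohort_kept = cohort.loc[keep].copy()

    fit_self = fits[(fits["model_id"] == model_id) & (fits["referent"] == "self")]
    merged = cohort_kept.merge(fit_self, on="participant_id", how="inner")
    if merged.empty:
        raise ValueError("no overlapping participants between fits and cohort")

    rng_seed = seed
    report: dict = {
        "n_analyzed": int(len(merged)),
        "exclusions": {
            "n_excluded": len(excluded),
            "by_reason": {
                r: sum(1 for v in excluded.values() if v == r)
                for r in set(excluded.values())
            },
            "directional_error_counts": error_counts,
        },
        "settings": {"n_perm": n_perm, "n_boot": n_boot, "seed": seed, "model_id": model_id},
    }

    # 12-test family: 3 factors x 4 parameters, BH-corrected together
    corr_block = []
    for factor in FACTOR_COLUMNS:
        for param in MODEL3_PARAMS:
            res = permutation_corr(
                merged[factor], merged[param], n_perm=n_perm, seed=rng_seed
            )
            corr_block.append(
                {"factor": factor, "parameter": param,
                 "r": res.r, "p_uncorrected": res.p_uncorrected}
            )
            rng_seed += 1
    adj = bh_adjust([c["p_uncorrected"] for c in corr_block])
    for c, a in zip(corr_block, adj):
        c["p_fdr"] = float(a)
    report["factor_parameter_correlations"] = corr_block

    conf = permutation_corr(merged["mu0"], merged["bias"], n_perm=n_perm, seed=rng_seed)
    rng_seed += 1
    report["confirmation_bias"] = {"r": conf.r, "p": conf.p_uncorrected}

    report["joint_regressions"] = joint_regression_coef_diff(
        merged[list(FACTOR_COLUMNS)],
        merged["mu0"],
        merged["bias"],
        n_perm=n_perm,
        seed=rng_seed,
        include_interaction=True,
    )
    rng_seed += 1

    if "popularity" in merged.columns:
        med = bootstrap_mediation(
            merged["depression_specific"], merged["popularity"], merged["mu0"],
            n_boot=n_boot, seed=rng_seed,
        )
        rng_seed += 1
        pop_corr = permutation_corr(
            merged["depression_specific"], merged["popularity"],
            n_perm=n_perm, seed=rng_seed,
        )
        rng_seed += 1
        insight_corr = permutation_corr(
            merged["popularity"], merged["mu0"], n_perm=n_perm, seed=rng_seed
        )
        rng_seed += 1
        report["depressive_realism"] = {
            "acme": med.acme,
            "acme_p": med.acme_p,
            "acme_ci": list(med.acme_ci),
            "direct_effect": med.direct_effect,
            "total_effect": med.total_effect,
            "depression_popularity_r": pop_corr.r,
            "depression_popularity_p": pop_corr.p_uncorrected,
            "popularity_mu0_r": insight_corr.r,
            "popularity_mu0_p": insight_corr.p_uncorrected,
        }

    if trajectories is not None:
        kept_ids = set(merged["participant_id"].astype(str))
        rows = []
        for traj in trajectories:
            if traj.referent.value != "self" or traj.participant_id not in kept_ids:
                continue
            start, end, change = model_agnostic_indices(traj)
            rows.append(
                {"participant_id": traj.participant_id,
                 "feedback_order": traj.feedback_order.value,
                 "starting_belief": start, "ending_belief": end,
                 "belief_change": change}
            )
        if rows:
            idx = pd.DataFrame(rows)
            pos = idx.loc[idx["feedback_order"] == "positive_first", "belief_change"]
            neg = idx.loc[idx["feedback_order"] == "negative_first", "belief_change"]
            block = {
                "mean_change_positive_first": float(pos.mean()) if len(pos) else None,
                "mean_change_negative_first": float(neg.mean()) if len(neg) else None,
            }
            if len(pos) > 1 and len(neg) > 1:
                t, p = stats.ttest_ind(pos, neg)
                block["order_t"] = float(t)
                block["order_p"] = float(p)
            report["model_agnostic"] = block

    return report
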