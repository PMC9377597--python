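"""Anderson-Rubin factor scoring from a fixed loadings matrix.

The loadings are an input (estimated elsewhere); this module only computes
orthogonality-preserving scores.  Items are z-scored with the current
sample's moments.  With R the item correlation matrix, Lambda the loadings
and Psi = diag(1 - communality), the weights are

    W = Psi^-1 Lambda (Lambda' Psi^-1 R Psi^-1 Lambda)^(-1/2)

(symmetric inverse square root), which makes the sample covariance of the
scores exactly the identity under the sample R.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["anderson_rubin_scores", "subset_loadings"]


def _inv_sqrtm(M: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root via eigendecomposition."""
    vals, vecs = np.linalg.eigh(M)
    if vals.min() <= 1e-12:
        raise np.linalg.LinAlgError(
            f"matrix not positive definite (min eigenvalue {vals.min():.3g}); "
            "check for collinear or constant items"
        )
    return (vecs / np.sqrt(vals)) @ vecs.T


def subset_loadings(loadings: pd.DataFrame, items) -> pd.DataFrame:
    """Row-subset the loadings to the items actually administered."""
    missing = [i for i in items if i not in loadings.index]
    if missing:
        raise KeyError(f"items absent from loadings matrix: {missing[:5]}...")
    return loadings.loc[list(items)]


def anderson_rubin_scores(
    responses: pd.DataFrame | np.ndarray,
    loadings: pd.DataFrame | np.ndarray,
) -> pd.DataFrame:
    """Compute Anderson-Rubin factor scores.

    Parameters
    ----------
    responses
        Participants x items matrix.  If a DataFrame, its columns must match
        the loadings index (items present in the responses but described by
        the loadings are aligned by name; loadings rows for items that were
        not administered are dropped).
    loadings
        Items x factors matrix.

    Returns
    -------
    DataFrame of participants x factors scores whose sample covariance is
    (up to the ddof convention) the identity.
    """
    if isinstance(loadings, pd.DataFrame):
        lam_df = loadings
    else:
        lam = np.asarray(loadings, dtype=float)
        lam_df = pd.DataFrame(lam, columns=[f"f{j}" for j in range(lam.shape[1])])

    if isinstance(responses, pd.DataFrame):
        cols = [c for c in responses.columns if c in lam_df.index]
        if len(cols) == 0:
            # positional fallback: unnamed items
            X = responses.to_numpy(dtype=float)
            lam = lam_df.to_numpy(dtype=float)
        else:
            X = responses[cols].to_numpy(dtype=float)
            lam = lam_df.loc[cols].to_numpy(dtype=float)
        index = responses.index
    else:
        X = np.asarray(responses, dtype=float)
        lam = lam_df.to_numpy(dtype=float)
        index = pd.RangeIndex(X.shape[0])

    n, p = X.shape
    if lam.shape[0] != p:
        raise ValueError(f"responses have {p} items but loadings {lam.shape[0]}")
    if n <= lam.shape[1]:
        raise ValueError("need more participants than factors")

    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)[:5]
        raise np.linalg.LinAlgError(f"constant items at positions {bad.tolist()}")
    Z = (X - X.mean(axis=0)) / sd
    R = (Z.T @ Z) / n

    communality = (lam**2).sum(axis=1)
    if (communality >= 1.0).any():
        raise ValueError("item communalities must be < 1")
    psi_inv = 1.0 / (1.0 - communality)
    A = lam * psi_inv[:, None]  # Psi^-1 Lambda
    W = A @ _inv_sqrtm(A.T @ R @ A)
    scores = Z @ W
    return pd.DataFrame(scores, index=index, columns=list(lam_df.columns))
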