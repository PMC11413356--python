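"""Shared LD-matrix estimation from reference-panel dosages.

Both the summary-statistics simulator and the composite-likelihood
estimator draw their per-block SNP correlation matrices from here, so
simulation and inference agree on what "the LD of this panel" means.
"""

from __future__ import annotations

import numpy as np

from .errors import SingularityError

#: default lower bound on the shrinkage weight
LAMBDA_MIN = 0.05


def shrinkage_weight(m: int, n_ref: int, lambda_min: float = LAMBDA_MIN) -> float:
    """lambda = max(lambda_min, m / n_ref).

    Shrinking an empirical correlation matrix toward the identity by at
    least m/n_ref keeps it comfortably positive definite even when the
    block size approaches the panel sample count.
    """
    return max(float(lambda_min), m / n_ref)


def block_correlation(
    dosages: np.ndarray,
    indices: np.ndarray,
    shrink: float | None = None,
    lambda_min: float = LAMBDA_MIN,
) -> tuple[np.ndarray, float]:
    """Shrunk empirical correlation of the given dosage columns.

    Returns ``(R, lam)`` with R = (1 - lam) * corr + lam * I.  Every
    eigenvalue of R is >= lam because the empirical correlation is PSD.
    Monomorphic columns (zero variance) get unit diagonal and zero
    off-diagonals.
    """
    X = np.asarray(dosages, dtype=float)[:, indices]
    n_ref, m = X.shape
    if shrink is None:
        lam = shrinkage_weight(m, n_ref, lambda_min)
    else:
        lam = max(float(shrink), m / n_ref) if shrink > 0 else 0.0
    sd = X.std(axis=0)
    if lam == 0.0 and m > n_ref:
        raise SingularityError(
            f"block of {m} SNPs exceeds panel size {n_ref} with shrinkage disabled"
        )
    ok = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    R = (Xs.T @ Xs) / n_ref
    np.fill_diagonal(R, 1.0)
    R = (1.0 - lam) * R + lam * np.eye(m)
    return R, lam
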