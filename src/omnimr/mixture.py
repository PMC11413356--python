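"""Grid-search mixture-model replication estimator.

Complementary to the composite-likelihood estimator: a small set of
approximately independent, genome-wide-significant instruments is
selected by p-value clumping, and for each candidate causal effect
theta on a grid the residuals

    t_j = beta_y,j - theta * beta_x,j,   s_j^2 = se_y,j^2 + theta^2 se_x,j^2

are modeled as a two-component scale mixture pi0 * N(0, s_j^2) +
(1 - pi0) * N(0, s_j^2 + tau^2).  At the true theta every valid
instrument's residual is pure noise, so the null mass pi0 peaks there;
the causal estimate is the theta maximizing pi0 (ties broken toward the
smallest |theta|).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyInstrumentError, ParameterError
from .harmonize import HarmonizedPair
from ._stats import log_p_from_z

logger = logging.getLogger(__name__)

_TAU2_FLOOR = 1e-6


@dataclass
class InstrumentSet:
    """Clumped genome-wide-significant instruments on the z/beta scale."""

    indices: np.ndarray
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    settings: dict = field(default_factory=dict)

    @property
    def n_instruments(self) -> int:
        return len(self.indices)


@dataclass
class MixtureGridFit:
    theta_grid: np.ndarray
    pi0_curve: np.ndarray
    tau2_curve: np.ndarray
    loglik_curve: np.ndarray
    theta_hat: float
    n_instruments: int


def select_instruments(
    pair: HarmonizedPair,
    blocks,
    p_threshold: float = 5e-8,
    r2_max: float = 0.1,
) -> InstrumentSet:
    """Greedy p-value clumping of exposure-significant SNPs.

    Candidates are visited by ascending exposure p; a SNP is kept if its
    panel r^2 with every previously kept SNP in the same LD block stays
    below ``r2_max`` (SNPs in different blocks are treated as
    independent).  Effects are returned on the standardized scale
    (beta = z / sqrt(n), se = 1 / sqrt(n)).
    """
    log_p = log_p_from_z(pair.z_x)
    sig = np.flatnonzero(log_p < np.log(p_threshold))
    if len(sig) == 0:
        raise EmptyInstrumentError(
            f"no SNP passes the exposure threshold {p_threshold:g}"
        )
    block_of = np.full(pair.n_snps, -1)
    local_of = np.zeros(pair.n_snps, dtype=int)
    for bi, blk in enumerate(blocks):
        block_of[blk.indices] = bi
        local_of[blk.indices] = np.arange(blk.size)

    order = sig[np.argsort(log_p[sig], kind="stable")]
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            if block_of[i] == block_of[j] and block_of[i] >= 0:
                r = blocks[block_of[i]].R[local_of[i], local_of[j]]
                if r * r >= r2_max:
                    ok = False
                    break
        if ok:
            kept.append(i)
    kept_arr = np.array(sorted(kept))
    sx = 1.0 / np.sqrt(pair.n_x)
    sy = 1.0 / np.sqrt(pair.n_y)
    return InstrumentSet(
        indices=kept_arr,
        beta_x=pair.z_x[kept_arr] * sx,
        se_x=np.full(len(kept_arr), sx),
        beta_y=pair.z_y[kept_arr] * sy,
        se_y=np.full(len(kept_arr), sy),
        settings={"p_threshold": p_threshold, "r2_max": r2_max},
    )


def _mixture_loglik(t, s2, tau2, pi0):
    v1 = s2 + tau2
    f0 = np.exp(-0.5 * t * t / s2) / np.sqrt(2.0 * np.pi * s2)
    f1 = np.exp(-0.5 * t * t / v1) / np.sqrt(2.0 * np.pi * v1)
    return float(np.sum(np.log(pi0 * f0 + (1.0 - pi0) * f1 + 1e-300))), f0, f1


def fit_mixture_at_theta(
    instr: InstrumentSet, theta: float
) -> tuple[float, float, float]:
    """EM fit of (pi0, tau2) to the residuals at one candidate theta.

    The non-null component is integrated over a latent direct effect
    u_j ~ N(0, tau2), giving a closed-form E-step and a monotone
    fixed-point update for tau2.  Residuals are noise-normalized before
    the EM so the fit is equivariant under a common rescaling of all
    (beta, se) pairs; the tau2 floor of 1e-6 lives on that normalized
    scale.  Returns (pi0, tau2, loglik) on the original scale.
    """
    if instr.n_instruments < 2:
        raise ParameterError("need at least 2 instruments")
    t_raw = instr.beta_y - theta * instr.beta_x
    s2_raw = instr.se_y**2 + theta**2 * instr.se_x**2

    scale2 = float(np.mean(s2_raw))
    if scale2 <= 0:
        raise ParameterError("instrument standard errors must be positive")
    t = t_raw / np.sqrt(scale2)
    s2 = s2_raw / scale2

    if np.ptp(t) < 1e-12:
        # degenerate residuals: no spread for the mixture to explain
        warnings.warn(
            "degenerate residuals (all instruments equal); "
            "returning the boundary fit pi0=1",
            stacklevel=2,
        )
        ll, _, _ = _mixture_loglik(t, s2, _TAU2_FLOOR, 1.0)
        return 1.0, _TAU2_FLOOR * scale2, ll - 0.5 * len(t) * np.log(scale2)

    pi0 = 0.5
    tau2 = max(float(np.var(t) - np.mean(s2)), _TAU2_FLOOR)
    ll_old = -np.inf
    for _ in range(500):
        ll, f0, f1 = _mixture_loglik(t, s2, tau2, pi0)
        # E-step
        denom = pi0 * f0 + (1.0 - pi0) * f1 + 1e-300
        r0 = pi0 * f0 / denom
        r1 = 1.0 - r0
        # M-step
        pi0 = float(np.mean(r0))
        w1 = r1.sum()
        if w1 > 1e-12:
            # E[u^2 | t, non-null] under u ~ N(0, tau2), t | u ~ N(u, s2)
            shrink = tau2 / (tau2 + s2)
            eu2 = shrink * s2 + (shrink * t) ** 2
            tau2 = max(float((r1 @ eu2) / w1), _TAU2_FLOOR)
        else:
            tau2 = _TAU2_FLOOR
        if abs(ll - ll_old) < 1e-8:
            break
        ll_old = ll
    else:
        logger.debug("mixture EM hit the iteration cap at theta=%g", theta)
    ll, _, _ = _mixture_loglik(t, s2, tau2, pi0)
    # undo the normalization: variance scale and the density Jacobian
    return (
        float(np.clip(pi0, 0.0, 1.0)),
        tau2 * scale2,
        ll - 0.5 * len(t) * np.log(scale2),
    )


def default_grid(lo: float = -1.0, hi: float = 1.0, step: float = 0.005) -> np.ndarray:
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def grid_search_theta(
    instr: InstrumentSet, grid: np.ndarray | None = None
) -> MixtureGridFit:
    """Profile the null mass pi0 over candidate causal effects.

    ``theta_hat`` is the grid point maximizing pi0; exact ties resolve
    toward the smallest |theta|.
    """
    if instr.n_instruments == 0:
        raise EmptyInstrumentError("no instruments to profile")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    pi0 = np.empty(len(grid))
    tau2 = np.empty(len(grid))
    ll = np.empty(len(grid))
    for i, th in enumerate(grid):
        pi0[i], tau2[i], ll[i] = fit_mixture_at_theta(instr, float(th))
    best = pi0.max()
    contenders = np.flatnonzero(pi0 >= best - 1e-12)
    theta_hat = float(grid[contenders[np.argmin(np.abs(grid[contenders]))]])
    return MixtureGridFit(
        theta_grid=grid,
        pi0_curve=pi0,
        tau2_curve=tau2,
        loglik_curve=ll,
        theta_hat=theta_hat,
        n_instruments=instr.n_instruments,
    )
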