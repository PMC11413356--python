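"""Composite-likelihood causal-effect estimation from all genome-wide SNPs.

Model
-----
For a harmonized pair of GWAS z-score vectors and an LD block with
correlation matrix R (m SNPs out of p genome-wide), the polygenic model
with exposure heritability sigma2_beta, causal effect alpha and
horizontal-pleiotropy variance sigma2_gamma implies a zero-mean joint
Gaussian for the stacked (z_x, z_y):

    Sigma_xx = (n_x sigma2_beta / p) R^2 + R
    Sigma_yy = (n_y (alpha^2 sigma2_beta + sigma2_gamma) / p) R^2 + R
    Sigma_xy = sqrt(n_x n_y) (alpha sigma2_beta / p) R^2

(the cross term has no noise part because the two cohorts do not
overlap).  The log composite likelihood is the weighted sum of these
block log-densities; blocks are treated as independent, which is exact
when LD does not cross block boundaries.

Because all three covariance pieces are polynomials in R, they share
R's eigenvectors: rotating each block's z-scores into R's eigenbasis
decouples the 2m-dimensional density into m independent bivariate
normals with 2x2 covariances built from the eigenvalues.  That
factorization (computed once per block) makes a full likelihood
evaluation O(p), cheap enough for the delete-one-block jackknife that
provides standard errors — composite likelihoods misstate
curvature-based variances, so resampling is used instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import ParameterError, SingularityError
from .harmonize import HarmonizedPair
from .ld import LAMBDA_MIN, block_correlation
from .sumstats import ReferencePanel
from ._stats import log_p_from_z

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-8  # variance components below this are treated as boundary


@dataclass
class OmrParams:
    """Model parameters: causal effect and the two variance fractions."""

    alpha: float
    sigma2_beta: float
    sigma2_gamma: float

    def __post_init__(self) -> None:
        if not all(
            np.isfinite([self.alpha, self.sigma2_beta, self.sigma2_gamma])
        ):
            raise ParameterError("non-finite model parameters")
        if self.sigma2_beta < 0 or self.sigma2_gamma < 0:
            raise ParameterError("variance components must be non-negative")


@dataclass
class LDBlock:
    """Contiguous SNP window with its shrunk panel correlation matrix."""

    indices: np.ndarray
    R: np.ndarray
    lam: float  # shrinkage weight applied to R

    def __post_init__(self) -> None:
        self._eig: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def size(self) -> int:
        return len(self.indices)

    @property
    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Eigendecomposition of R, cached after first use."""
        if self._eig is None:
            vals, vecs = np.linalg.eigh(self.R)
            if vals.min() <= 0:
                raise SingularityError(
                    f"block at index {self.indices[0]} is not positive definite"
                )
            self._eig = (vals, vecs)
        return self._eig


@dataclass
class FitOptions:
    block_size: int = 50
    shrink: float = LAMBDA_MIN
    weights: str = "equal"  # "equal" or "invsize" (w_b = 1/m_b)
    max_iter: int = 500
    xatol: float = 1e-6
    fatol: float = 1e-8
    jackknife: bool = True


@dataclass
class OmrFit:
    """Fitted causal effect with block-jackknife inference.

    ``pve_pleiotropy`` is the fraction of outcome variance attributable
    to direct SNP effects, i.e. the fitted sigma2_gamma.  ``log10_p``
    accompanies ``p_value`` so that magnitudes below the double
    underflow limit remain representable.
    """

    alpha_hat: float
    se_alpha: float
    p_value: float
    log10_p: float
    sigma2_beta_hat: float
    sigma2_gamma_hat: float
    loglik: float
    n_snps: int
    n_blocks: int
    converged: bool
    boundary: bool = False
    alpha_jackknife: np.ndarray | None = field(default=None, repr=False)

    @property
    def pve_pleiotropy(self) -> float:
        return self.sigma2_gamma_hat


def build_blocks(
    pair: HarmonizedPair,
    panel: ReferencePanel,
    opts: FitOptions | None = None,
) -> list[LDBlock]:
    """Partition retained SNPs into LD blocks with shrunk correlations.

    Sidecar block ids take precedence when the pair carries them;
    otherwise contiguous windows of ``block_size`` SNPs (last window
    keeps the remainder) are cut within each chromosome.  Each block's R
    is the panel correlation shrunk by lambda = max(shrink, m/n_ref).
    """
    opts = opts or FitOptions()
    if pair.n_snps == 0:
        raise ParameterError("empty harmonized pair")

    groups: list[np.ndarray] = []
    local = np.arange(pair.n_snps)
    if (pair.block_id >= 0).all() and len(np.unique(pair.block_id)) > 1:
        for bid in np.unique(pair.block_id):
            groups.append(local[pair.block_id == bid])
    else:
        chroms = panel.snp["chr"].to_numpy()[pair.panel_indices]
        for chrom in pd_unique(chroms):
            on_chr = local[chroms == chrom]
            n = len(on_chr)
            n_win = max(1, n // opts.block_size)
            edges = [i * opts.block_size for i in range(n_win)] + [n]
            for s, e in zip(edges[:-1], edges[1:]):
                groups.append(on_chr[s:e])

    blocks = []
    for g in groups:
        if len(g) == 0:
            continue
        R, lam = block_correlation(
            panel.dosages, pair.panel_indices[g], shrink=opts.shrink
        )
        blocks.append(LDBlock(indices=g, R=R, lam=lam))
    return blocks


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def block_covariance(
    block: LDBlock, params: OmrParams, n_x: float, n_y: float, p_total: int
) -> np.ndarray:
    """Dense 2m x 2m joint covariance of (z_x, z_y) for one block."""
    R = block.R
    R2 = R @ R
    a = n_x * params.sigma2_beta / p_total
    b = n_y * (params.alpha**2 * params.sigma2_beta + params.sigma2_gamma) / p_total
    c = np.sqrt(n_x * n_y) * params.alpha * params.sigma2_beta / p_total
    return np.block([[a * R2 + R, c * R2], [c * R2, b * R2 + R]])


class _CompositeData:
    """Eigen-rotated z-scores and eigenvalues, flattened across blocks.

    Precomputes everything that does not depend on the parameters so a
    likelihood evaluation is a handful of length-p vector operations.
    """

    def __init__(self, pair: HarmonizedPair, blocks: list[LDBlock], weights: str):
        lam_l, wx_l, wy_l, block_of_l = [], [], [], []
        for bi, blk in enumerate(blocks):
            vals, vecs = blk.eig
            lam_l.append(vals)
            wx_l.append(vecs.T @ pair.z_x[blk.indices])
            wy_l.append(vecs.T @ pair.z_y[blk.indices])
            block_of_l.append(np.full(blk.size, bi))
        self.lam = np.concatenate(lam_l)
        self.lam2 = self.lam**2
        wx = np.concatenate(wx_l)
        wy = np.concatenate(wy_l)
        self.wx2 = wx**2
        self.wy2 = wy**2
        self.wxwy = wx * wy
        self.block_of = np.concatenate(block_of_l)
        self.n_blocks = len(blocks)
        if weights == "equal":
            bw = np.ones(self.n_blocks)
        elif weights == "invsize":
            bw = 1.0 / np.array([b.size for b in blocks], dtype=float)
        else:
            raise ParameterError(f"unknown weight scheme {weights!r}")
        self.block_weights = bw
        self.n_x = pair.n_x
        self.n_y = pair.n_y
        self.p_total = pair.n_snps

    def component_loglik(self, alpha: float, sb2: float, sg2: float) -> np.ndarray:
        a = self.n_x * sb2 / self.p_total
        b = self.n_y * (alpha * alpha * sb2 + sg2) / self.p_total
        c = np.sqrt(self.n_x * self.n_y) * alpha * sb2 / self.p_total
        s11 = a * self.lam2 + self.lam
        s22 = b * self.lam2 + self.lam
        s12 = c * self.lam2
        det = s11 * s22 - s12 * s12
        quad = (s22 * self.wx2 - 2.0 * s12 * self.wxwy + s11 * self.wy2) / det
        return -_LOG2PI - 0.5 * np.log(det) - 0.5 * quad

    def weight_vector(self, exclude_block: int | None = None) -> np.ndarray:
        bw = self.block_weights.copy()
        if exclude_block is not None:
            bw[exclude_block] = 0.0
        return bw[self.block_of]

    def loglik(self, params: OmrParams, exclude_block: int | None = None) -> float:
        w = self.weight_vector(exclude_block)
        return float(
            w @ self.component_loglik(params.alpha, params.sigma2_beta, params.sigma2_gamma)
        )


def composite_loglik(
    pair: HarmonizedPair,
    blocks: list[LDBlock],
    params: OmrParams,
    weights: str = "equal",
) -> float:
    """Weighted sum of block log-densities under the joint Gaussian law.

    Computed through each block's eigenfactorization (never an explicit
    matrix inverse); with a single all-SNP block and equal weights this
    equals the dense joint multivariate-normal log-density exactly.
    """
    return _CompositeData(pair, blocks, weights).loglik(params)


def moment_init(pair: HarmonizedPair) -> OmrParams:
    """LD-free method-of-moments starting values.

    Under R ~ I: E[z_x^2] - 1 = n_x sigma2_beta / p, E[z_x z_y] =
    sqrt(n_x n_y) alpha sigma2_beta / p, and E[z_y^2] - 1 =
    n_y (alpha^2 sigma2_beta + sigma2_gamma) / p.  Falls back to a weak
    default when the exposure signal is too small to invert.
    """
    p = pair.n_snps
    mx2 = float(np.mean(pair.z_x**2))
    my2 = float(np.mean(pair.z_y**2))
    mxy = float(np.mean(pair.z_x * pair.z_y))
    denom = mx2 - 1.0
    if denom <= 0.05:
        warnings.warn(
            "exposure z-scores carry too little polygenic signal for "
            "moment initialization; falling back to defaults",
            stacklevel=2,
        )
        return OmrParams(alpha=0.0, sigma2_beta=0.01, sigma2_gamma=0.01)
    sb2 = p * denom / pair.n_x
    alpha = float(np.sqrt(pair.n_x / pair.n_y) * mxy / denom)
    sg2 = max(p * (my2 - 1.0) / pair.n_y - alpha**2 * sb2, 0.0)
    return OmrParams(alpha=alpha, sigma2_beta=sb2, sigma2_gamma=sg2)


def _maximize(data: _CompositeData, start: OmrParams, opts: FitOptions,
              exclude_block: int | None = None):
    w = data.weight_vector(exclude_block)

    def neg_loglik(t: np.ndarray) -> float:
        alpha = t[0]
        sb2 = np.exp(np.clip(t[1], -46.0, 5.0))
        sg2 = np.exp(np.clip(t[2], -46.0, 5.0))
        return -float(w @ data.component_loglik(alpha, sb2, sg2))

    t0 = np.array(
        [
            start.alpha,
            np.log(max(start.sigma2_beta, 1e-6)),
            np.log(max(start.sigma2_gamma, 1e-6)),
        ]
    )
    res = minimize(
        neg_loglik,
        t0,
        method="Nelder-Mead",
        options={
            "xatol": opts.xatol,
            "fatol": opts.fatol,
            "maxiter": opts.max_iter * 3,
            "maxfev": opts.max_iter * 6,
        },
    )
    alpha = float(res.x[0])
    sb2 = float(np.exp(np.clip(res.x[1], -46.0, 5.0)))
    sg2 = float(np.exp(np.clip(res.x[2], -46.0, 5.0)))
    return OmrParams(alpha, sb2, sg2), -float(res.fun), bool(res.success)


def fit_omr(
    pair: HarmonizedPair,
    blocks: list[LDBlock],
    opts: FitOptions | None = None,
) -> OmrFit:
    """Maximize the composite likelihood; jackknife over blocks for SE.

    Variance components are optimized on the log scale to enforce
    positivity; values ending up at the floor are flagged as boundary
    rather than silently clipped.  The delete-one-block jackknife
    restarts each leave-one-out fit from the full-data optimum.
    """
    opts = opts or FitOptions()
    data = _CompositeData(pair, blocks, opts.weights)
    start = moment_init(pair)
    est, ll, converged = _maximize(data, start, opts)
    if not converged:
        warnings.warn("composite-likelihood optimization did not converge", stacklevel=2)

    boundary = est.sigma2_beta <= _VAR_FLOOR or est.sigma2_gamma <= _VAR_FLOOR
    if boundary:
        logger.warning("variance component at boundary: %s", est)

    se = np.nan
    jack = None
    if opts.jackknife and data.n_blocks >= 2:
        B = data.n_blocks
        jack = np.empty(B)
        for b in range(B):
            est_b, _, _ = _maximize(data, est, opts, exclude_block=b)
            jack[b] = est_b.alpha
        se = float(np.sqrt((B - 1) / B * np.sum((jack - jack.mean()) ** 2)))

    if se > 0:
        log_p = float(log_p_from_z(est.alpha / se))
    else:
        log_p = 0.0
    p_value = float(max(np.exp(log_p), np.nextafter(0, 1)))
    return OmrFit(
        alpha_hat=est.alpha,
        se_alpha=se,
        p_value=p_value,
        log10_p=log_p / np.log(10.0),
        sigma2_beta_hat=est.sigma2_beta,
        sigma2_gamma_hat=est.sigma2_gamma,
        loglik=ll,
        n_snps=pair.n_snps,
        n_blocks=data.n_blocks,
        converged=converged,
        boundary=boundary,
        alpha_jackknife=jack,
    )
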