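"""Synthetic reference panels and GWAS summary statistics.

The generator implements the structural model behind the estimator:
standardized genotypes G, polygenic exposure effects beta_j ~ N(0,
sigma2_beta/p), direct (horizontally pleiotropic) outcome effects
gamma_j ~ N(0, sigma2_gamma/p), a scalar causal effect alpha, and two
disjoint cohorts of sizes n_x, n_y:

    x = G_x beta + eps_x,                 Var(eps_x) = 1 - sigma2_beta
    y = G_y (alpha * beta + gamma) + eps_y,
        Var(eps_y) = 1 - alpha^2 sigma2_beta - sigma2_gamma

Intercepts are handled by centering phenotypes before the per-SNP
marginal regressions, so they never appear in summary output.  LD is
block-structured: within each block a latent AR(1) Gaussian with
parameter rho is thresholded to haplotypes at each SNP's allele
frequency; blocks are mutually independent.

Two samplers share this law: :func:`simulate_individual_gwas` draws
cohort genotypes and runs the marginal regressions (the slow oracle
path), while :func:`simulate_summary_gwas` draws the per-block z-score
vectors directly from their implied Gaussian distribution

    z_x,b = sqrt(n_x) R_b beta_b + e_x,   e_x ~ N(0, R_b)
    z_y,b = sqrt(n_y) R_b (alpha beta_b + gamma_b) + e_y,  e_y ~ N(0, R_b)

with e_x independent of e_y (no sample overlap), where R_b is the
shrunk empirical correlation of the panel — the same matrix the
estimator later rebuilds, so the generative law and the fitted model
coincide exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .errors import ParameterError
from .ld import block_correlation
from .sumstats import ReferencePanel, SumStatsTable, SUMSTATS_COLUMNS
from ._stats import p_from_z

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic exposure/outcome pair.

    Variance parameters are fractions of unit phenotype variance:
    ``sigma2_beta`` is the exposure heritability, ``sigma2_gamma`` the
    outcome-variance share of direct SNP effects.  ``alpha`` is the
    causal effect of the exposure on the outcome.
    """

    p_snps: int = 20_000
    n_blocks: int = 400
    rho: float = 0.5
    n_ref: int = 500
    n_x: int = 50_000
    n_y: int = 30_000
    alpha: float = 0.2
    sigma2_beta: float = 0.3
    sigma2_gamma: float = 0.05
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ParameterError(f"rho must be in [0, 1), got {self.rho}")
        if self.sigma2_beta < 0 or self.sigma2_gamma < 0:
            raise ParameterError("variance components must be non-negative")
        if self.alpha**2 * self.sigma2_beta + self.sigma2_gamma >= 1.0:
            raise ParameterError("outcome residual variance must be positive")
        if self.sigma2_beta >= 1.0:
            raise ParameterError("exposure residual variance must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError(f"invalid maf_range {self.maf_range}")
        if self.p_snps < 1 or self.n_blocks < 1 or self.n_blocks > self.p_snps:
            raise ParameterError("need 1 <= n_blocks <= p_snps")

    def block_sizes(self) -> list[int]:
        base = self.p_snps // self.n_blocks
        sizes = [base] * self.n_blocks
        sizes[-1] += self.p_snps - base * self.n_blocks
        return sizes


@dataclass
class EffectVectors:
    """Per-SNP standardized effects: beta on the exposure, gamma
    directly on the outcome; drawn independently of each other."""

    beta: np.ndarray
    gamma: np.ndarray


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    # one independent stream per operation so each op is individually
    # reproducible from config.seed
    return np.random.default_rng([int(config.seed), stream])


def _draw_genotypes(
    rng: np.random.Generator,
    freqs: np.ndarray,
    block_sizes: Sequence[int],
    rho: float,
    n: int,
) -> np.ndarray:
    """Diploid dosages: two AR(1)-latent haplotypes thresholded per SNP."""
    dosage = np.empty((n, len(freqs)))
    thresh = ndtri(freqs)  # allele carried when latent < Phi^-1(f)
    start = 0
    innov = np.sqrt(1.0 - rho**2)
    for m in block_sizes:
        cols = slice(start, start + m)
        dos = np.zeros((n, m))
        for _hap in range(2):
            lat = np.empty((n, m))
            lat[:, 0] = rng.standard_normal(n)
            eps = rng.standard_normal((n, m - 1)) if m > 1 else None
            for j in range(1, m):
                lat[:, j] = rho * lat[:, j - 1] + innov * eps[:, j - 1]
            dos += lat < thresh[cols]
        dosage[:, cols] = dos
        start += m
    return dosage


def simulate_reference_panel(config: SimulationConfig) -> ReferencePanel:
    """Draw an LD reference panel of n_ref diploid samples.

    SNP ids, positions and ref/alt alleles are synthetic; block
    boundaries are recorded so downstream stages can reuse them.
    """
    rng = _rng(config, 0)
    p = config.p_snps
    freqs = rng.uniform(*config.maf_range, size=p)
    a2 = rng.choice(_BASES, size=p)
    # alt allele differs from ref
    a1 = np.array([rng.choice(_BASES[_BASES != r]) for r in a2])
    snp = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:06d}" for i in range(p)],
            "chr": "1",
            "pos": np.arange(1, p + 1) * 1000,
            "a1": a1,
            "a2": a2,
            "freq": freqs,
        }
    )
    sizes = config.block_sizes()
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    blocks = pd.DataFrame(
        {
            "block_id": np.arange(len(sizes)),
            "chr": "1",
            "start": starts,
            "end": starts + np.asarray(sizes),
        }
    )
    dosages = _draw_genotypes(rng, freqs, sizes, config.rho, config.n_ref)
    panel = ReferencePanel(dosages=dosages, snp=snp, blocks=blocks)
    # panel-realized frequencies are what downstream standardization uses
    panel.snp["freq"] = dosages.mean(axis=0) / 2.0
    return panel


def draw_effects(config: SimulationConfig) -> EffectVectors:
    """beta_j ~ N(0, sigma2_beta/p), gamma_j ~ N(0, sigma2_gamma/p), independent."""
    rng = _rng(config, 1)
    p = config.p_snps
    beta = rng.normal(0.0, np.sqrt(config.sigma2_beta / p), size=p)
    gamma = rng.normal(0.0, np.sqrt(config.sigma2_gamma / p), size=p)
    return EffectVectors(beta=beta, gamma=gamma)


def _marginal_gwas(G: np.ndarray, pheno: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP simple regression of centered phenotype on standardized dosage."""
    n = G.shape[0]
    y = pheno - pheno.mean()
    sd = G.std(axis=0)
    sd[sd == 0] = 1.0
    Gs = (G - G.mean(axis=0)) / sd
    sxy = Gs.T @ y
    beta = sxy / (n - 1)
    rss = y @ y - beta**2 * (n - 1)
    se = np.sqrt(np.maximum(rss, 0.0) / (n - 2) / (n - 1))
    return beta, se


def _table_from_beta_se(
    panel: ReferencePanel, beta: np.ndarray, se: np.ndarray, n: int, label: str,
    freq: np.ndarray | None = None,
) -> SumStatsTable:
    df = panel.snp[["snp_id", "chr", "pos", "a1", "a2"]].copy()
    df["freq"] = panel.snp["freq"].to_numpy() if freq is None else freq
    df["beta"] = beta
    df["se"] = se
    df["p"] = p_from_z(beta / se)
    df["n"] = n
    return SumStatsTable(df[SUMSTATS_COLUMNS].copy(), label)


def simulate_individual_gwas(
    config: SimulationConfig, panel: ReferencePanel, effects: EffectVectors
) -> tuple[SumStatsTable, SumStatsTable]:
    """Oracle path: draw two disjoint cohorts and run the marginal GWAS.

    Genotypes come from the panel's generative process; phenotypes follow
    the structural equations with standardization by the panel allele
    frequencies.  Intended for modest sizes (n, p <= ~5000 each).
    """
    sizes = config.block_sizes()
    rng = _rng(config, 2)
    freqs = panel.snp["freq"].to_numpy()
    scale = np.sqrt(2.0 * freqs * (1.0 - freqs))

    resid_x = 1.0 - config.sigma2_beta
    resid_y = 1.0 - config.alpha**2 * config.sigma2_beta - config.sigma2_gamma
    if resid_x <= 0 or resid_y <= 0:
        raise ParameterError("residual variance must be positive")

    out = []
    for n, effect, resid, label in (
        (config.n_x, effects.beta, resid_x, "exposure"),
        (config.n_y, config.alpha * effects.beta + effects.gamma, resid_y, "outcome"),
    ):
        G = _draw_genotypes(rng, freqs, sizes, config.rho, n)
        Gstd = (G - 2.0 * freqs) / scale
        pheno = Gstd @ effect + rng.normal(0.0, np.sqrt(resid), size=n)
        beta, se = _marginal_gwas(G, pheno)
        out.append(
            _table_from_beta_se(panel, beta, se, n, label, freq=G.mean(axis=0) / 2.0)
        )
    return out[0], out[1]


def simulate_summary_gwas(
    config: SimulationConfig,
    panel: ReferencePanel,
    effects: EffectVectors,
    rng: np.random.Generator | None = None,
) -> tuple[SumStatsTable, SumStatsTable]:
    """Draw exposure/outcome z-scores directly from the summary-level law.

    Pass an explicit ``rng`` to draw independent replicates over a fixed
    panel and effect vectors; by default the stream is derived from
    ``config.seed`` and the call is fully deterministic.
    """
    if rng is None:
        rng = _rng(config, 3)
    n_x, n_y, p = config.n_x, config.n_y, config.p_snps
    sa = config.alpha
    zx = np.empty(p)
    zy = np.empty(p)
    for start, end in panel.block_slices():
        idx = np.arange(start, end)
        R, _lam = block_correlation(panel.dosages, idx)
        L = np.linalg.cholesky(R)
        b = effects.beta[idx]
        g = effects.gamma[idx]
        zx[idx] = np.sqrt(n_x) * (R @ b) + L @ rng.standard_normal(len(idx))
        zy[idx] = np.sqrt(n_y) * (R @ (sa * b + g)) + L @ rng.standard_normal(len(idx))
    se_x = np.full(p, 1.0 / np.sqrt(n_x))
    se_y = np.full(p, 1.0 / np.sqrt(n_y))
    tab_x = _table_from_beta_se(panel, zx * se_x, se_x, n_x, "exposure")
    tab_y = _table_from_beta_se(panel, zy * se_y, se_y, n_y, "outcome")
    return tab_x, tab_y


def simulate_instruments(
    n_instruments: int = 50,
    alpha: float = 0.3,
    beta_sd: float = 0.1,
    se_x: float = 0.001,
    se_y: float = 0.0015,
    tau: float = 0.0,
    seed: int = 0,
):
    """Instrument-level summary statistics for the replication estimator.

    Draws independent true instrument effects b_j ~ N(0, beta_sd^2),
    observes beta_x = b_j + N(0, se_x^2) and beta_y = alpha*b_j +
    N(0, se_y^2) + N(0, tau^2); ``tau > 0`` adds direct (pleiotropic)
    instrument effects on the outcome.  The defaults emulate the
    strong-instrument regime the profile search needs to localize theta
    at grid resolution: |beta_x| / se_x ~ 100, as seen for the top
    cis-acting variants of molecular traits.
    """
    from .mixture import InstrumentSet

    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, beta_sd, size=n_instruments)
    bx = b + rng.normal(0.0, se_x, size=n_instruments)
    by = alpha * b + rng.normal(0.0, se_y, size=n_instruments)
    if tau > 0:
        by = by + rng.normal(0.0, tau, size=n_instruments)
    return InstrumentSet(
        indices=np.arange(n_instruments),
        beta_x=bx,
        se_x=np.full(n_instruments, se_x),
        beta_y=by,
        se_y=np.full(n_instruments, se_y),
        settings={"source": "simulate_instruments", "alpha": alpha, "seed": seed},
    )


def simulate_cascade_datasets(
    config: SimulationConfig,
    mediator_alphas: Sequence[float],
    outcome_specs: Sequence[tuple[int | None, float]] = (),
    n_mediator: int | None = None,
    n_outcome: int | None = None,
    sigma2_gamma_mediator: float | None = None,
) -> dict:
    """One exposure, K mediators, M outcomes sharing a single panel.

    Mediator k responds to the exposure with causal effect
    ``mediator_alphas[k]`` plus its own pleiotropy draw.  Each outcome is
    ``(parent_index, theta)``: it responds with effect theta to mediator
    ``parent_index``'s total SNP effect (alpha_k*beta + gamma_k), or to
    nothing when the parent is None.  Returns a dict with the panel, the
    exposure table, and lists of mediator/outcome tables.
    """
    n_med = n_mediator or config.n_y
    n_out = n_outcome or config.n_y
    sg2_med = (
        config.sigma2_gamma if sigma2_gamma_mediator is None else sigma2_gamma_mediator
    )
    panel = simulate_reference_panel(config)
    effects = draw_effects(config)
    rng = _rng(config, 4)
    p = config.p_snps

    slices = panel.block_slices()
    Rs, Ls = [], []
    for start, end in slices:
        R, _ = block_correlation(panel.dosages, np.arange(start, end))
        Rs.append(R)
        Ls.append(np.linalg.cholesky(R))

    def draw_z(effect: np.ndarray, n: int) -> np.ndarray:
        z = np.empty(p)
        for (start, end), R, L in zip(slices, Rs, Ls):
            idx = np.arange(start, end)
            z[idx] = np.sqrt(n) * (R @ effect[idx]) + L @ rng.standard_normal(len(idx))
        return z

    def to_table(z: np.ndarray, n: int, label: str) -> SumStatsTable:
        se = np.full(p, 1.0 / np.sqrt(n))
        return _table_from_beta_se(panel, z * se, se, n, label)

    exposure = to_table(draw_z(effects.beta, config.n_x), config.n_x, "exposure")

    mediators, mediator_effects = [], []
    for k, a_k in enumerate(mediator_alphas):
        gamma_k = rng.normal(0.0, np.sqrt(sg2_med / p), size=p)
        u_k = a_k * effects.beta + gamma_k
        mediator_effects.append(u_k)
        mediators.append(to_table(draw_z(u_k, n_med), n_med, f"mediator{k + 1}"))

    outcomes = []
    for m, (parent, theta) in enumerate(outcome_specs):
        gamma_o = rng.normal(0.0, np.sqrt(sg2_med / p), size=p)
        eff = gamma_o if parent is None else theta * mediator_effects[parent] + gamma_o
        outcomes.append(to_table(draw_z(eff, n_out), n_out, f"outcome{m + 1}"))

    return {
        "panel": panel,
        "exposure": exposure,
        "mediators": mediators,
        "outcomes": outcomes,
        "effects": effects,
    }
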