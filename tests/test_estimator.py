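"""Composite-likelihood estimator: covariance algebra, oracles, inference."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

import omnimr as om
from omnimr.estimator import (
    FitOptions,
    LDBlock,
    OmrParams,
    block_covariance,
    build_blocks,
    composite_loglik,
    fit_omr,
    moment_init,
)
from omnimr.harmonize import HarmonizedPair


def _ldfree_pair(rng, p, n_x, n_y, alpha, sb2, sg2):
    """Exact summary-law draw at R = I, as a HarmonizedPair."""
    beta = rng.normal(0, np.sqrt(sb2 / p), p)
    gamma = rng.normal(0, np.sqrt(sg2 / p), p)
    z_x = np.sqrt(n_x) * beta + rng.standard_normal(p)
    z_y = np.sqrt(n_y) * (alpha * beta + gamma) + rng.standard_normal(p)
    return HarmonizedPair(
        snp_id=np.array([f"s{i}" for i in range(p)]),
        panel_indices=np.arange(p),
        z_x=z_x,
        z_y=z_y,
        n_x=n_x,
        n_y=n_y,
        block_id=np.full(p, -1),
    )


def _identity_blocks(p, m):
    return [
        LDBlock(indices=np.arange(s, min(s + m, p)), R=np.eye(min(m, p - s)), lam=0.0)
        for s in range(0, p, m)
    ]


def _random_block(rng, m, lam=0.1, start=0):
    A = rng.normal(size=(m, 3 * m))
    R = (1 - lam) * np.corrcoef(A) + lam * np.eye(m)
    return LDBlock(indices=np.arange(start, start + m), R=R, lam=lam)


# ---------------------------------------------------------------- blocks

def test_build_blocks_windowing():
    cfg = om.SimulationConfig(p_snps=100, n_blocks=1, n_ref=200, seed=0)
    panel = om.simulate_reference_panel(cfg)
    eff = om.draw_effects(cfg)
    ssx, ssy = om.simulate_summary_gwas(cfg, panel, eff)
    panel.blocks = None
    pair = om.merge_pair(ssx, ssy, panel, om.QCSettings(min_snps=1, maf_min=0.0,
                                                        drop_ambiguous_palindromes=False))
    blocks = build_blocks(pair, panel, FitOptions(block_size=50))
    assert [b.size for b in blocks] == [50, 50]


def test_shrunk_blocks_min_eigenvalue(small_pair):
    _, blocks = small_pair
    for blk in blocks:
        vals = np.linalg.eigvalsh(blk.R)
        assert vals.min() >= blk.lam - 1e-10
        assert blk.lam >= 0.05
        assert np.allclose(np.diag(blk.R), 1.0)


# ----------------------------------------------------- block covariance

def test_block_covariance_null_genetics():
    rng = np.random.default_rng(0)
    blk = _random_block(rng, 5)
    cov = block_covariance(blk, OmrParams(0.3, 0.0, 0.0), 1e4, 1e4, 1000)
    assert np.allclose(cov[:5, :5], blk.R)
    assert np.allclose(cov[5:, 5:], blk.R)
    assert np.allclose(cov[:5, 5:], 0.0)


def test_block_covariance_scalar_closed_form():
    blk = LDBlock(indices=np.array([0]), R=np.eye(1), lam=0.0)
    n_x, n_y, p = 5e4, 3e4, 1e4
    par = OmrParams(0.2, 0.3, 0.05)
    cov = block_covariance(blk, par, n_x, n_y, int(p))
    assert cov[0, 0] == pytest.approx(1 + n_x * 0.3 / p)
    assert cov[1, 1] == pytest.approx(1 + n_y * (0.2**2 * 0.3 + 0.05) / p)
    assert cov[0, 1] == pytest.approx(np.sqrt(n_x * n_y) * 0.2 * 0.3 / p)


def test_block_covariance_alpha_sign_symmetry():
    rng = np.random.default_rng(1)
    blk = _random_block(rng, 6)
    pos = block_covariance(blk, OmrParams(0.4, 0.3, 0.05), 5e4, 3e4, 10_000)
    neg = block_covariance(blk, OmrParams(-0.4, 0.3, 0.05), 5e4, 3e4, 10_000)
    assert np.allclose(pos[:6, :6], neg[:6, :6])
    assert np.allclose(pos[6:, 6:], neg[6:, 6:])
    assert np.allclose(pos[:6, 6:], -neg[:6, 6:])


# -------------------------------------------------- composite likelihood

def test_single_snp_null_loglik_closed_form():
    pair = HarmonizedPair(
        snp_id=np.array(["s0"]), panel_indices=np.array([0]),
        z_x=np.array([0.7]), z_y=np.array([-1.1]),
        n_x=1e4, n_y=1e4, block_id=np.array([-1]),
    )
    blocks = [LDBlock(indices=np.array([0]), R=np.eye(1), lam=0.0)]
    ll = composite_loglik(pair, blocks, OmrParams(0.0, 0.0, 0.0))
    assert ll == pytest.approx(-np.log(2 * np.pi) - (0.7**2 + 1.1**2) / 2, rel=1e-12)


def test_dense_oracle_single_block():
    """One all-SNP block: composite equals the dense joint MVN density."""
    rng = np.random.default_rng(2)
    for m in (3, 17, 60):
        blk = _random_block(rng, m)
        pair = HarmonizedPair(
            snp_id=np.array([f"s{i}" for i in range(m)]),
            panel_indices=np.arange(m),
            z_x=rng.standard_normal(m), z_y=rng.standard_normal(m),
            n_x=5e4, n_y=3e4, block_id=np.zeros(m, dtype=int),
        )
        par = OmrParams(0.25, 0.3, 0.05)
        cov = block_covariance(blk, par, pair.n_x, pair.n_y, m)
        dense = multivariate_normal(np.zeros(2 * m), cov).logpdf(
            np.concatenate([pair.z_x, pair.z_y])
        )
        assert composite_loglik(pair, [blk], par) == pytest.approx(dense, abs=1e-8)


def test_independent_blocks_equal_concatenated_dense():
    rng = np.random.default_rng(3)
    m1, m2 = 8, 11
    b1 = _random_block(rng, m1, start=0)
    b2 = _random_block(rng, m2, start=m1)
    p = m1 + m2
    pair = HarmonizedPair(
        snp_id=np.array([f"s{i}" for i in range(p)]), panel_indices=np.arange(p),
        z_x=rng.standard_normal(p), z_y=rng.standard_normal(p),
        n_x=2e4, n_y=2e4, block_id=np.repeat([0, 1], [m1, m2]),
    )
    par = OmrParams(-0.3, 0.2, 0.1)
    ll = composite_loglik(pair, [b1, b2], par)
    dense = 0.0
    for blk in (b1, b2):
        cov = block_covariance(blk, par, pair.n_x, pair.n_y, p)
        stacked = np.concatenate([pair.z_x[blk.indices], pair.z_y[blk.indices]])
        dense += multivariate_normal(np.zeros(2 * blk.size), cov).logpdf(stacked)
    assert ll == pytest.approx(dense, abs=1e-8)


def test_alpha_zero_separates_into_marginals():
    rng = np.random.default_rng(4)
    m = 12
    blk = _random_block(rng, m)
    zx, zy = rng.standard_normal(m), rng.standard_normal(m)
    pair = HarmonizedPair(
        snp_id=np.array([f"s{i}" for i in range(m)]), panel_indices=np.arange(m),
        z_x=zx, z_y=zy, n_x=3e4, n_y=1e4, block_id=np.zeros(m, dtype=int),
    )
    par = OmrParams(0.0, 0.25, 0.07)
    ll = composite_loglik(pair, [blk], par)
    R2 = blk.R @ blk.R
    cov_x = pair.n_x * 0.25 / m * R2 + blk.R
    cov_y = pair.n_y * 0.07 / m * R2 + blk.R
    marg = multivariate_normal(np.zeros(m), cov_x).logpdf(zx)
    marg += multivariate_normal(np.zeros(m), cov_y).logpdf(zy)
    assert ll == pytest.approx(marg, abs=1e-8)


def test_invsize_weights_divide_block_contributions():
    rng = np.random.default_rng(5)
    m = 10
    blk = _random_block(rng, m)
    pair = HarmonizedPair(
        snp_id=np.array([f"s{i}" for i in range(m)]), panel_indices=np.arange(m),
        z_x=rng.standard_normal(m), z_y=rng.standard_normal(m),
        n_x=1e4, n_y=1e4, block_id=np.zeros(m, dtype=int),
    )
    par = OmrParams(0.1, 0.2, 0.02)
    equal = composite_loglik(pair, [blk], par, weights="equal")
    inv = composite_loglik(pair, [blk], par, weights="invsize")
    assert inv == pytest.approx(equal / m, rel=1e-12)


# ------------------------------------------------------------ moment init

def test_moment_init_weak_signal_fallback():
    rng = np.random.default_rng(6)
    pair = _ldfree_pair(rng, 5000, 100, 100, 0.0, 0.0, 0.0)
    with pytest.warns(UserWarning, match="polygenic signal"):
        par = moment_init(pair)
    assert par.alpha == 0.0 and par.sigma2_beta == 0.01


def test_moment_init_sign_equivariance():
    rng = np.random.default_rng(7)
    pair = _ldfree_pair(rng, 4000, 5e4, 3e4, 0.25, 0.3, 0.05)
    par = moment_init(pair)
    flipped = HarmonizedPair(
        snp_id=pair.snp_id, panel_indices=pair.panel_indices,
        z_x=pair.z_x, z_y=-pair.z_y, n_x=pair.n_x, n_y=pair.n_y,
        block_id=pair.block_id,
    )
    par_neg = moment_init(flipped)
    assert par_neg.alpha == pytest.approx(-par.alpha, rel=1e-12)
    assert par_neg.sigma2_beta == par.sigma2_beta


def test_moment_init_recovers_alpha_on_ldfree_data():
    rng = np.random.default_rng(8)
    errs = [
        moment_init(_ldfree_pair(rng, 20_000, 5e4, 3e4, 0.2, 0.3, 0.05)).alpha - 0.2
        for _ in range(5)
    ]
    assert np.all(np.abs(errs) < 0.05)


# ------------------------------------------------------------------ fits

def test_fit_sign_equivariance(small_pair):
    pair, blocks = small_pair
    fit = fit_omr(pair, blocks)
    flipped = HarmonizedPair(
        snp_id=pair.snp_id, panel_indices=pair.panel_indices,
        z_x=pair.z_x, z_y=-pair.z_y, n_x=pair.n_x, n_y=pair.n_y,
        block_id=pair.block_id,
    )
    fit_neg = fit_omr(flipped, blocks)
    assert fit_neg.alpha_hat == pytest.approx(-fit.alpha_hat, abs=1e-9)
    assert fit_neg.se_alpha == pytest.approx(fit.se_alpha, abs=1e-9)
    assert fit_neg.sigma2_beta_hat == pytest.approx(fit.sigma2_beta_hat, rel=1e-6)
    assert fit_neg.sigma2_gamma_hat == pytest.approx(fit.sigma2_gamma_hat, rel=1e-6)


def test_mle_agrees_with_mom_on_ldfree_data():
    rng = np.random.default_rng(9)
    p = 10_000
    pair = _ldfree_pair(rng, p, 5e4, 3e4, 0.2, 0.3, 0.05)
    blocks = _identity_blocks(p, 50)
    fit = fit_omr(pair, blocks, FitOptions(jackknife=False))
    mom = moment_init(pair)
    assert fit.converged
    assert abs(fit.alpha_hat - mom.alpha) < 0.03


def test_pleiotropy_near_zero_when_absent():
    rng = np.random.default_rng(10)
    hats = []
    for _ in range(5):
        pair = _ldfree_pair(rng, 6000, 5e4, 3e4, 0.2, 0.3, 0.0)
        fit = fit_omr(pair, _identity_blocks(6000, 50), FitOptions(jackknife=False))
        hats.append(fit.sigma2_gamma_hat)
    assert np.mean(hats) < 0.02


def test_se_shrinks_with_more_snps():
    """Monotone information: more SNPs at fixed architecture -> smaller SE."""
    ses = {}
    for p in (600, 2400):
        vals = []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            pair = _ldfree_pair(rng, p, 5e4, 3e4, 0.2, 0.3, 0.05)
            fit = fit_omr(pair, _identity_blocks(p, 50))
            vals.append(fit.se_alpha)
        ses[p] = np.median(vals)
    assert ses[2400] < ses[600]


def test_jackknife_se_positive_and_fit_fields(small_pair):
    pair, blocks = small_pair
    fit = fit_omr(pair, blocks)
    assert fit.se_alpha > 0
    assert 0 < fit.p_value <= 1
    assert 0 <= fit.pve_pleiotropy < 1
    assert fit.pve_pleiotropy == fit.sigma2_gamma_hat
    assert fit.n_blocks == len(blocks)
    assert len(fit.alpha_jackknife) == len(blocks)
    # jackknife formula recomputed independently
    jk = fit.alpha_jackknife
    B = len(jk)
    se = np.sqrt((B - 1) / B * np.sum((jk - jk.mean()) ** 2))
    assert fit.se_alpha == pytest.approx(se, rel=1e-12)
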