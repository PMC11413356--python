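"""Two-round MR screening cascade with layered Bonferroni correction.

Round 1 tests one exposure against K candidate mediators at the
family-wise threshold alpha_level / K.  Mediators that survive become
the exposures of round 2, which tests each of the k survivors against M
outcomes at alpha_level / (M * k).  With the published design of K = 42
inflammation markers, k = 7 survivors and M = 15 brain phenotypes those
thresholds instantiate to 0.05/42 ~ 1.19e-3 and 0.05/105 ~ 4.77e-4.
Results that clear 0.05 but not the Bonferroni layer are flagged as
nominal.  An optional replication pass reruns every significant round-2
pair through the mixture-grid estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import OmnimrError, ParameterError
from .estimator import FitOptions, OmrFit, build_blocks, fit_omr
from .harmonize import QCSettings, merge_pair
from .mixture import default_grid, grid_search_theta, select_instruments
from .sumstats import (
    ReferencePanel,
    SumStatsTable,
    read_panel_vcf,
    read_sumstats,
    write_table,
)
from ._stats import Z_975, z_from_p

logger = logging.getLogger(__name__)

#: a dataset reference: an in-memory table or a path to one
DatasetRef = "SumStatsTable | str | Path"


@dataclass
class ReplicationSettings:
    enabled: bool = False
    p_threshold: float = 5e-8
    r2_max: float = 0.1
    grid_lo: float = -1.0
    grid_hi: float = 1.0
    grid_step: float = 0.005


@dataclass
class CascadeConfig:
    """One exposure, K labeled mediators, M labeled outcomes."""

    exposure: object
    mediators: list[tuple[str, object]]
    outcomes: list[tuple[str, object]] = field(default_factory=list)
    panel: object = None
    alpha_level: float = 0.05
    fit_options: FitOptions = field(default_factory=FitOptions)
    qc: QCSettings = field(default_factory=QCSettings)
    replication: ReplicationSettings = field(default_factory=ReplicationSettings)

    def __post_init__(self) -> None:
        if len(self.mediators) < 1:
            raise ParameterError("need at least one mediator dataset")
        labels = [lab for lab, _ in self.mediators] + [lab for lab, _ in self.outcomes]
        if len(set(labels)) != len(labels):
            raise ParameterError("dataset labels must be unique")
        if not (0.0 < self.alpha_level < 1.0):
            raise ParameterError("alpha_level must be in (0, 1)")


@dataclass
class CascadeReport:
    round1: pd.DataFrame
    survivors: list[str]
    round2: pd.DataFrame
    thresholds: tuple[float, float | None]
    replication: dict[str, object] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(self.round1, out / "round1.tsv", columns=list(self.round1.columns))
        if len(self.round2):
            write_table(
                self.round2, out / "round2.tsv", columns=list(self.round2.columns)
            )
        (out / "survivors.txt").write_text("".join(s + "\n" for s in self.survivors))
        t1, t2 = self.thresholds
        t2_str = f"{t2:.6e}" if t2 is not None else "NA"
        (out / "thresholds.txt").write_text(
            f"round1\t{t1:.6e}\nround2\t{t2_str}\n"
        )
        for label, fit in self.replication.items():
            rows = [
                {"theta": th, "pi0": p0, "tau2": tv, "loglik": lv}
                for th, p0, tv, lv in zip(
                    fit.theta_grid, fit.pi0_curve, fit.tau2_curve, fit.loglik_curve
                )
            ]
            rep_dir = out / "replication"
            rep_dir.mkdir(exist_ok=True)
            write_table(rows, rep_dir / f"{label}.tsv",
                        columns=["theta", "pi0", "tau2", "loglik"])


def bonferroni_threshold(alpha_level: float, m: int) -> float:
    """Family-wise threshold alpha_level / m (full precision)."""
    if m < 1:
        raise ParameterError(f"number of tests must be >= 1, got {m}")
    if not (0.0 < alpha_level < 1.0):
        raise ParameterError(f"alpha_level must be in (0, 1), got {alpha_level}")
    return alpha_level / m


def wald_interval(
    estimate: float, p: float | None = None, *, log_p: float | None = None
) -> tuple[float, float, float]:
    """Reconstruct (se, ci_low, ci_high) from an estimate and its p-value.

    The implied |z| comes from the two-sided normal quantile of p (in
    log space, so p ~ 1e-32 is handled exactly); se = |estimate| / z and
    the 95% interval is estimate +/- q(0.975) * se.
    """
    if estimate == 0:
        raise ParameterError("SE is undefined for a zero estimate")
    if log_p is None:
        if p is None or not (0.0 < p < 1.0):
            raise ParameterError(f"need a p-value in (0, 1), got {p}")
        log_p = float(np.log(p))
    elif log_p >= 0.0:
        raise ParameterError("log_p must be negative")
    zstar = float(z_from_p(log_p=log_p))
    se = abs(estimate) / zstar
    return se, estimate - Z_975 * se, estimate + Z_975 * se


def _load_sumstats(ref, label: str | None = None) -> SumStatsTable:
    if isinstance(ref, SumStatsTable):
        if label and not ref.trait_label:
            ref.trait_label = label
        return ref
    table = read_sumstats(ref, trait_label=label)
    return table


def _load_panel(ref) -> ReferencePanel:
    if isinstance(ref, ReferencePanel):
        return ref
    return read_panel_vcf(ref)


def _fit_row(label: str, fit: OmrFit, exposure_label: str) -> dict:
    se, lo, hi = (np.nan, np.nan, np.nan)
    if fit.alpha_hat != 0 and fit.se_alpha > 0:
        lo = fit.alpha_hat - Z_975 * fit.se_alpha
        hi = fit.alpha_hat + Z_975 * fit.se_alpha
        se = fit.se_alpha
    return {
        "exposure": exposure_label,
        "outcome": label,
        "n_snps": fit.n_snps,
        "n_blocks": fit.n_blocks,
        "alpha": fit.alpha_hat,
        "se": se,
        "ci_low": lo,
        "ci_high": hi,
        "p": fit.p_value,
        "log10_p": fit.log10_p,
        "sigma2_beta": fit.sigma2_beta_hat,
        "sigma2_gamma": fit.sigma2_gamma_hat,
        "pve_pleiotropy": fit.pve_pleiotropy,
        "converged": fit.converged,
        "status": "ok",
        "error": "",
    }


def run_round(
    exposure,
    targets: list[tuple[str, object]],
    panel,
    fit_options: FitOptions | None = None,
    qc: QCSettings | None = None,
    exposure_label: str | None = None,
) -> pd.DataFrame:
    """Fit exposure -> target for every target; one row per target.

    Failures (unreadable file, insufficient overlap, ...) become rows
    with an error status instead of aborting the round.
    """
    fit_options = fit_options or FitOptions()
    panel = _load_panel(panel)
    exp_table = _load_sumstats(exposure)
    exposure_label = exposure_label or exp_table.trait_label or "exposure"

    rows = []
    n_failed = 0
    for label, ref in targets:
        try:
            target = _load_sumstats(ref, label)
            pair = merge_pair(exp_table, target, panel, qc)
            blocks = build_blocks(pair, panel, fit_options)
            fit = fit_omr(pair, blocks, fit_options)
            rows.append(_fit_row(label, fit, exposure_label))
        except Exception as exc:  # noqa: BLE001 - failures become report rows
            n_failed += 1
            logger.warning("target %s failed: %s", label, exc)
            rows.append(
                {
                    "exposure": exposure_label,
                    "outcome": label,
                    "status": "error",
                    "error": f"{type(exc).__name__}: {exc}",
                }
            )
    if targets and n_failed == len(targets):
        raise OmnimrError(f"all {len(targets)} targets failed in this round")
    return pd.DataFrame(rows)


def _flag(df: pd.DataFrame, threshold: float, alpha_level: float) -> pd.DataFrame:
    df = df.copy()
    ok = df.get("status", "ok") == "ok"
    df["threshold"] = threshold
    df["pass_bonferroni"] = ok & (df.get("p", np.nan) < threshold)
    df["nominal_only"] = ok & (df.get("p", np.nan) < alpha_level) & ~df["pass_bonferroni"]
    return df


def run_cascade(config: CascadeConfig) -> CascadeReport:
    """Run the full two-round screen and assemble the report.

    Round-2's Bonferroni denominator is M * k with k the realized
    survivor count, so the familywise level covers exactly the tests
    actually performed.  No survivors is a valid (empty) outcome, not an
    error.
    """
    panel = _load_panel(config.panel)
    K = len(config.mediators)
    t1 = bonferroni_threshold(config.alpha_level, K)

    round1 = run_round(
        config.exposure, config.mediators, panel, config.fit_options, config.qc
    )
    round1 = _flag(round1, t1, config.alpha_level)
    survivors = list(round1.loc[round1["pass_bonferroni"], "outcome"])

    M = len(config.outcomes)
    t2 = None
    round2 = pd.DataFrame()
    replication: dict[str, object] = {}
    if survivors and M:
        t2 = bonferroni_threshold(config.alpha_level, M * len(survivors))
        med_refs = dict(config.mediators)
        parts = []
        for label in survivors:
            part = run_round(
                _load_sumstats(med_refs[label], label),
                config.outcomes,
                panel,
                config.fit_options,
                config.qc,
                exposure_label=label,
            )
            parts.append(part)
        round2 = _flag(pd.concat(parts, ignore_index=True), t2, config.alpha_level)

        if config.replication.enabled:
            rep = config.replication
            grid = default_grid(rep.grid_lo, rep.grid_hi, rep.grid_step)
            out_refs = dict(config.outcomes)
            hits = round2[round2["pass_bonferroni"]]
            for row in hits.itertuples():
                key = f"{row.exposure}__{row.outcome}"
                try:
                    pair = merge_pair(
                        _load_sumstats(med_refs[row.exposure], row.exposure),
                        _load_sumstats(out_refs[row.outcome], row.outcome),
                        panel,
                        config.qc,
                    )
                    blocks = build_blocks(pair, panel, config.fit_options)
                    instr = select_instruments(
                        pair, blocks, rep.p_threshold, rep.r2_max
                    )
                    replication[key] = grid_search_theta(instr, grid)
                except OmnimrError as exc:
                    logger.warning("replication for %s skipped: %s", key, exc)

    return CascadeReport(
        round1=round1,
        survivors=survivors,
        round2=round2,
        thresholds=(t1, t2),
        replication=replication,
    )
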