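"""Quality control and merging of GWAS summary statistics with a panel.

Alignment follows standard two-sample MR practice: effect signs are
flipped when the effect/other alleles are swapped relative to the panel,
strand flips are resolved through base complements, and palindromic
(A/T, C/G) SNPs — whose orientation cannot be recovered from the letters
— are oriented by allele-frequency agreement and dropped entirely when
the panel frequency is too close to 0.5 for frequencies to be
informative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyOverlapError, InsufficientOverlapError
from .sumstats import ReferencePanel, SumStatsTable

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class QCSettings:
    """Thresholds of the merge step, echoed into the QC log."""

    drop_ambiguous_palindromes: bool = True
    palindrome_freq_window: tuple[float, float] = (0.4, 0.6)
    maf_min: float = 0.01
    z_cap: float | None = None  # |z| outlier cap, disabled by default
    min_snps: int = 100


@dataclass
class HarmonizedPair:
    """Allele-aligned, panel-matched exposure/outcome z-scores.

    ``panel_indices`` maps each retained SNP to its column in the panel
    dosage matrix; ``block_id`` comes from the panel sidecar when
    present (otherwise -1, and blocks are assigned downstream).
    """

    snp_id: np.ndarray
    panel_indices: np.ndarray
    z_x: np.ndarray
    z_y: np.ndarray
    n_x: float
    n_y: float
    block_id: np.ndarray
    qc_log: dict[str, int] = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    def qc_table(self) -> pd.DataFrame:
        """QC log as (filter, removed, remaining), in application order."""
        remaining = self.n_snps + sum(self.qc_log.values())
        rows = []
        for k, v in self.qc_log.items():
            remaining -= v
            rows.append({"filter": k, "removed": v, "remaining": remaining})
        return pd.DataFrame(rows)


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return a2 == a1.map(_COMPLEMENT)


def align_to_panel(
    ss: SumStatsTable, panel: ReferencePanel
) -> tuple[SumStatsTable, dict[str, int]]:
    """Orient a summary table's effects to the panel's allele coding.

    Matching is by snp_id.  Per matched SNP: identical allele pairs keep
    their sign; swapped pairs negate beta and flip freq; strand
    complements of either orientation resolve the same way; anything
    else is dropped as a mismatch.  Palindromic SNPs are oriented by
    frequency agreement (they stay in the table here; the merge step
    owns the ambiguity drop).  Returns the aligned table and a count
    dict {"unmatched": ..., "mismatch": ...}.
    """
    df = ss.df.copy()
    pan = panel.snp.set_index("snp_id")
    in_panel = df["snp_id"].isin(pan.index)
    counts = {"unmatched": int((~in_panel).sum()), "mismatch": 0}
    df = df[in_panel].copy()
    if df.empty:
        raise EmptyOverlapError(f"{ss.trait_label}: no SNPs shared with the panel")

    p1 = pan.loc[df["snp_id"], "a1"].to_numpy()
    p2 = pan.loc[df["snp_id"], "a2"].to_numpy()
    pf = pan.loc[df["snp_id"], "freq"].to_numpy()
    a1 = df["a1"].to_numpy()
    a2 = df["a2"].to_numpy()
    c1 = df["a1"].map(_COMPLEMENT).to_numpy()
    c2 = df["a2"].map(_COMPLEMENT).to_numpy()

    palin = _is_palindromic(df["a1"], df["a2"]).to_numpy()
    same = (a1 == p1) & (a2 == p2)
    swap = (a1 == p2) & (a2 == p1)
    same_c = (c1 == p1) & (c2 == p2)
    swap_c = (c1 == p2) & (c2 == p1)

    keep_sign = (same | same_c) & ~palin
    flip_sign = (swap | swap_c) & ~palin & ~keep_sign
    # palindromes: letters cannot distinguish same from swap+strand-flip;
    # orient by whichever frequency interpretation agrees better
    freq = df["freq"].to_numpy(dtype=float)
    has_freq = np.isfinite(freq)
    agree_direct = np.abs(freq - pf) <= np.abs(freq - (1.0 - pf))
    pal_match = palin & (same | swap | same_c | swap_c)
    keep_sign |= pal_match & (agree_direct | ~has_freq)
    flip_sign |= pal_match & ~agree_direct & has_freq

    matched = keep_sign | flip_sign
    counts["mismatch"] = int((~matched).sum())
    if counts["mismatch"]:
        logger.info(
            "%s: dropped %d allele-mismatched SNPs", ss.trait_label, counts["mismatch"]
        )

    df = df[matched].copy()
    flip = flip_sign[matched]
    df.loc[flip, "beta"] = -df.loc[flip, "beta"]
    df.loc[flip, "freq"] = 1.0 - df.loc[flip, "freq"]
    # adopt the panel's allele coding for retained rows
    df["a1"] = p1[matched]
    df["a2"] = p2[matched]
    return SumStatsTable(df.reset_index(drop=True), ss.trait_label), counts


def merge_pair(
    ss_x: SumStatsTable,
    ss_y: SumStatsTable,
    panel: ReferencePanel,
    qc: QCSettings | None = None,
) -> HarmonizedPair:
    """Intersect exposure, outcome and panel; apply QC filters in order.

    Filter order: (1) palindromic SNPs with panel frequency inside the
    ambiguity window; (2) panel MAF below ``maf_min``; (3) optional |z|
    cap.  Removal counts per filter (plus alignment mismatches) are
    recorded in ``qc_log``; the counts sum to |three-way intersection|
    minus |retained|.
    """
    qc = qc or QCSettings()
    ax, cx = align_to_panel(ss_x, panel)
    ay, cy = align_to_panel(ss_y, panel)

    pan = panel.snp.reset_index().rename(columns={"index": "panel_idx"})
    # mismatches relative to the three-way id intersection
    ids_x_all = ss_x.df.loc[ss_x.df["snp_id"].isin(pan["snp_id"]), "snp_id"]
    ids_y_all = ss_y.df.loc[ss_y.df["snp_id"].isin(pan["snp_id"]), "snp_id"]
    inter_all = np.intersect1d(ids_x_all.to_numpy(), ids_y_all.to_numpy())

    merged = (
        ax.df[["snp_id", "beta", "se", "n"]]
        .merge(ay.df[["snp_id", "beta", "se", "n"]], on="snp_id", suffixes=("_x", "_y"))
        .merge(pan[["snp_id", "panel_idx", "a1", "a2", "freq"]], on="snp_id")
    )
    qc_log = {"mismatch": int(len(inter_all) - len(merged))}

    palin = _is_palindromic(merged["a1"], merged["a2"]).to_numpy()
    if qc.drop_ambiguous_palindromes:
        lo, hi = qc.palindrome_freq_window
        drop = palin & merged["freq"].between(lo, hi).to_numpy()
        qc_log["palindrome"] = int(drop.sum())
        merged = merged[~drop]
    else:
        qc_log["palindrome"] = 0

    maf = np.minimum(merged["freq"], 1.0 - merged["freq"])
    drop = (maf < qc.maf_min).to_numpy()
    qc_log["maf"] = int(drop.sum())
    merged = merged[~drop]

    if qc.z_cap is not None:
        zx = (merged["beta_x"] / merged["se_x"]).abs()
        zy = (merged["beta_y"] / merged["se_y"]).abs()
        drop = ((zx > qc.z_cap) | (zy > qc.z_cap)).to_numpy()
        qc_log["z_outlier"] = int(drop.sum())
        merged = merged[~drop]
    else:
        qc_log["z_outlier"] = 0

    if len(merged) < max(qc.min_snps, 1):
        raise InsufficientOverlapError(
            f"{len(merged)} SNPs retained after QC (floor {qc.min_snps}); qc_log={qc_log}"
        )
    merged = merged.sort_values("panel_idx").reset_index(drop=True)

    block_id = np.full(len(merged), -1, dtype=int)
    if panel.blocks is not None:
        starts = panel.blocks["start"].to_numpy()
        ends = panel.blocks["end"].to_numpy()
        bids = panel.blocks["block_id"].to_numpy()
        pos = merged["panel_idx"].to_numpy()
        which = np.searchsorted(starts, pos, side="right") - 1
        ok = (which >= 0) & (pos < ends[np.clip(which, 0, len(ends) - 1)])
        block_id[ok] = bids[which[ok]]

    logger.info(
        "harmonized %s vs %s: %d SNPs retained, qc=%s",
        ss_x.trait_label, ss_y.trait_label, len(merged), qc_log,
    )
    return HarmonizedPair(
        snp_id=merged["snp_id"].to_numpy(),
        panel_indices=merged["panel_idx"].to_numpy(),
        z_x=(merged["beta_x"] / merged["se_x"]).to_numpy(dtype=float),
        z_y=(merged["beta_y"] / merged["se_y"]).to_numpy(dtype=float),
        n_x=float(np.median(merged["n_x"])),
        n_y=float(np.median(merged["n_y"])),
        block_id=block_id,
        qc_log=qc_log,
    )
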