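import numpy as np
import pandas as pd
import pytest

import omnimr as om
from omnimr.sumstats import SUMSTATS_COLUMNS


@pytest.fixture(scope="session")
def small_sim():
    """A desk-scale simulated study shared by read-only tests."""
    cfg = om.SimulationConfig(p_snps=1200, n_blocks=24, n_ref=400, seed=42)
    panel = om.simulate_reference_panel(cfg)
    effects = om.draw_effects(cfg)
    ss_x, ss_y = om.simulate_summary_gwas(cfg, panel, effects)
    return {"config": cfg, "panel": panel, "effects": effects, "ss_x": ss_x, "ss_y": ss_y}


@pytest.fixture(scope="session")
def small_pair(small_sim):
    pair = om.merge_pair(small_sim["ss_x"], small_sim["ss_y"], small_sim["panel"])
    blocks = om.build_blocks(pair, small_sim["panel"])
    return pair, blocks


def _sumstats(records, label="toy"):
    df = pd.DataFrame(records, columns=SUMSTATS_COLUMNS)
    return om.SumStatsTable(df, label)


@pytest.fixture
def toy_harmonize():
    """Hand-built 10-SNP merge fixture.

    Exposure table vs panel: 6 clean SNPs (various orientations), 2
    allele mismatches, 1 ambiguous palindrome (panel freq 0.5), 1 SNP
    at panel MAF 0.005.  Outcome table is panel-coded throughout.
    """
    rng = np.random.default_rng(0)
    panel_rows = [
        # snp_id, a1(ALT/counted), a2(REF), freq of a1
        ("s1", "A", "G", 0.30),
        ("s2", "C", "T", 0.20),
        ("s3", "G", "T", 0.45),
        ("s4", "A", "C", 0.25),
        ("s5", "A", "T", 0.50),   # palindrome in the ambiguity window
        ("s6", "A", "G", 0.005),  # below the MAF floor
        ("s7", "A", "G", 0.30),   # exposure table carries A/C -> mismatch
        ("s8", "C", "T", 0.30),   # exposure table carries A/C -> mismatch
        ("s9", "T", "C", 0.35),
        ("s10", "G", "A", 0.40),
    ]
    snp = pd.DataFrame(panel_rows, columns=["snp_id", "a1", "a2", "freq"])
    snp.insert(1, "chr", "1")
    snp.insert(2, "pos", np.arange(1, 11) * 1000)
    dosages = rng.binomial(2, snp["freq"].to_numpy(), size=(50, 10)).astype(float)
    panel = om.ReferencePanel(dosages=dosages, snp=snp[
        ["snp_id", "chr", "pos", "a1", "a2", "freq"]
    ])

    def row(sid, a1, a2, freq, beta):
        return dict(
            snp_id=sid, chr="1", pos=1000, a1=a1, a2=a2, freq=freq,
            beta=beta, se=0.05, p=float(om._stats.p_from_z(beta / 0.05)), n=10000,
        )

    ss_x = _sumstats(
        [
            row("s1", "A", "G", 0.30, 0.10),   # identical coding
            row("s2", "T", "C", 0.80, -0.08),  # swapped alleles
            row("s3", "C", "A", 0.45, 0.06),   # strand complement
            row("s4", "G", "T", 0.75, 0.04),   # complement + swap
            row("s5", "A", "T", 0.50, 0.02),
            row("s6", "A", "G", 0.005, 0.01),
            row("s7", "A", "C", 0.30, 0.05),
            row("s8", "A", "C", 0.30, 0.05),
            row("s9", "T", "C", 0.35, -0.03),
            row("s10", "G", "A", 0.40, 0.07),
        ],
        label="exposure_toy",
    )
    ss_y = _sumstats(
        [row(sid, a1, a2, f, 0.02 * i) for i, (sid, a1, a2, f) in enumerate(panel_rows)],
        label="outcome_toy",
    )
    return ss_x, ss_y, panel
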