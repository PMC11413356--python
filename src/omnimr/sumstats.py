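"""Read/write GWAS summary statistics and genotype reference panels.

Canonical in-memory containers:

* :class:`SumStatsTable` — one GWAS's per-SNP marginal statistics, backed
  by a pandas DataFrame with fixed column names.
* :class:`ReferencePanel` — a dosage matrix with a SNP map and optional
  LD-block boundaries, loaded from VCF plus a TSV sidecar.

File dialects: summary statistics are tab-delimited with remappable
column names (defaults SNP, CHR, BP, A1, A2, FREQ, BETA, SE, P, N);
panels are VCF 4.x with GT genotypes; block boundaries are a TSV sidecar
(block_id, chr, start_index, end_index; indices 0-based, end exclusive,
into the panel's SNP order).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError
from ._stats import log_p_from_z

logger = logging.getLogger(__name__)

#: canonical column order of a summary-statistics table
SUMSTATS_COLUMNS = ["snp_id", "chr", "pos", "a1", "a2", "freq", "beta", "se", "p", "n"]

#: default file-column spelling of each canonical column
DEFAULT_DIALECT = {
    "snp_id": "SNP",
    "chr": "CHR",
    "pos": "BP",
    "a1": "A1",
    "a2": "A2",
    "freq": "FREQ",
    "beta": "BETA",
    "se": "SE",
    "p": "P",
    "n": "N",
}

#: fixed column order of the results table dialect
RESULT_COLUMNS = [
    "exposure", "outcome", "n_snps", "n_blocks", "alpha", "se",
    "ci_low", "ci_high", "p", "sigma2_beta", "sigma2_gamma",
    "pve_pleiotropy", "converged",
]

_VALID_BASES = frozenset("ACGT")


@dataclass
class SumStatsTable:
    """Marginal association statistics of one GWAS.

    ``df`` columns follow :data:`SUMSTATS_COLUMNS`; ``z`` is derived as
    beta/se.  ``log_p`` (natural log) is carried alongside ``p`` so that
    magnitudes far below the double-underflow limit survive round trips.
    """

    df: pd.DataFrame
    trait_label: str = ""

    @property
    def z(self) -> np.ndarray:
        return (self.df["beta"] / self.df["se"]).to_numpy(dtype=float)

    @property
    def n_records(self) -> int:
        return len(self.df)

    def check_zp_consistency(self, rtol: float = 1e-3) -> np.ndarray:
        """Boolean mask of rows whose stored p disagrees with beta/se.

        Comparison is on the natural-log scale, which is the only scale
        on which a relative check is meaningful for p ~ 1e-32.
        """
        with np.errstate(divide="ignore"):
            stored = np.log(self.df["p"].to_numpy(dtype=float))
        expected = log_p_from_z(self.z)
        denom = np.maximum(np.abs(expected), 1.0)
        return np.abs(stored - expected) / denom > rtol


@dataclass
class ReferencePanel:
    """Genotype dosages (samples x SNPs) with a SNP map.

    ``snp`` columns: snp_id, chr, pos, a1 (counted allele), a2, freq
    (frequency of a1).  ``blocks``, when present, has columns block_id,
    chr, start, end (0-based, end exclusive) partitioning SNP indices.
    """

    dosages: np.ndarray
    snp: pd.DataFrame
    blocks: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.dosages.shape[1] != len(self.snp):
            raise FormatError(
                f"SNP map length {len(self.snp)} != dosage columns {self.dosages.shape[1]}"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def block_slices(self) -> list[tuple[int, int]]:
        """(start, end) index pairs, from the sidecar if loaded."""
        if self.blocks is None:
            return [(0, self.n_snps)]
        return [(int(r.start), int(r.end)) for r in self.blocks.itertuples()]


def read_sumstats(
    path: str | Path,
    dialect: dict[str, str] | None = None,
    trait_label: str | None = None,
) -> SumStatsTable:
    """Load a tab/whitespace-delimited (optionally gzipped) GWAS file.

    ``dialect`` maps canonical column names to the file's spelling and is
    merged over :data:`DEFAULT_DIALECT`.  If beta/se are absent but a Z
    column is present, effects are taken on the standardized scale with
    se = 1/sqrt(n).  Rows failing basic sanity (se <= 0, missing fields,
    non-SNP alleles) are dropped and counted in the log.
    """
    path = Path(path)
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    raw = pd.read_csv(path, sep=r"\s+", compression="infer", dtype={colmap["chr"]: str})

    inverse = {v: k for k, v in colmap.items()}
    raw = raw.rename(columns=inverse)

    required = ["snp_id", "chr", "pos", "a1", "a2", "p", "n"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required columns {','.join(sorted(missing))}"
        )

    if "beta" not in raw.columns or "se" not in raw.columns:
        zcol = colmap.get("z", "Z")
        if zcol in raw.columns or "z" in raw.columns:
            z = raw[zcol] if zcol in raw.columns else raw["z"]
            raw["se"] = 1.0 / np.sqrt(raw["n"].astype(float))
            raw["beta"] = z.astype(float) * raw["se"]
        else:
            raise FormatError(f"{path.name}: missing required columns beta,se (or z)")
    if "freq" not in raw.columns:
        raw["freq"] = np.nan

    n_in = len(raw)
    df = raw[SUMSTATS_COLUMNS].copy()
    df["a1"] = df["a1"].astype(str).str.upper()
    df["a2"] = df["a2"].astype(str).str.upper()

    ok = df[["snp_id", "pos", "beta", "se", "p", "n"]].notna().all(axis=1)
    ok &= df["se"] > 0
    ok &= df["p"].between(0, 1, inclusive="right")
    # SNP-only pipeline: single-base alleles, no indels
    ok &= df["a1"].isin(_VALID_BASES) & df["a2"].isin(_VALID_BASES)
    dropped = int(n_in - ok.sum())
    if dropped:
        logger.info("%s: dropped %d malformed rows of %d", path.name, dropped, n_in)
    df = df[ok]

    # duplicate ids: keep the record with the largest n
    if df["snp_id"].duplicated().any():
        before = len(df)
        df = (
            df.sort_values("n", ascending=False)
            .drop_duplicates("snp_id", keep="first")
            .sort_index()
        )
        logger.info("%s: dropped %d duplicate snp ids", path.name, before - len(df))

    if df.empty:
        raise EmptyInputError(f"{path.name}: no usable records")

    table = SumStatsTable(df.reset_index(drop=True), trait_label or path.stem)
    bad = table.check_zp_consistency()
    if bad.any():
        logger.warning(
            "%s: %d rows with p inconsistent with beta/se", path.name, int(bad.sum())
        )
    return table


def write_sumstats(table: SumStatsTable, path: str | Path) -> None:
    """Write a summary table in the default dialect (round-trip safe)."""
    out = table.df[SUMSTATS_COLUMNS].rename(columns=DEFAULT_DIALECT)
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_panel_vcf(path: str | Path, blocks_path: str | Path | None = None) -> ReferencePanel:
    """Load a diploid GT-based VCF as a dosage panel.

    Dosage is the ALT-allele count, so a1 := ALT and a2 := REF; a1
    frequencies are computed from the dosages.  Non-biallelic or non-SNP
    records are skipped with a logged count; missing genotypes are
    imputed to the record mean.
    """
    from cyvcf2 import VCF

    rows, dosage_cols = [], []
    skipped = 0
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            skipped += 1
            continue
        gts = np.asarray(var.genotypes, dtype=float)[:, :2]
        gts[gts < 0] = np.nan
        dos = gts.sum(axis=1)
        if np.isnan(dos).any():
            fill = np.nanmean(dos) if not np.isnan(dos).all() else 0.0
            dos = np.where(np.isnan(dos), fill, dos)
        dosage_cols.append(dos)
        rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chr": str(var.CHROM),
                "pos": int(var.POS),
                "a1": var.ALT[0].upper(),
                "a2": var.REF.upper(),
            }
        )
    vcf.close()
    if skipped:
        logger.info("%s: skipped %d non-biallelic/non-SNP records", Path(path).name, skipped)
    if not rows:
        raise EmptyInputError(f"{Path(path).name}: no biallelic SNP records")

    dosages = np.column_stack(dosage_cols)
    snp = pd.DataFrame(rows)
    snp["freq"] = dosages.mean(axis=0) / 2.0

    blocks = None
    if blocks_path is not None:
        blocks = _read_blocks_sidecar(blocks_path, len(snp))
    return ReferencePanel(dosages=dosages, snp=snp, blocks=blocks)


def _read_blocks_sidecar(path: str | Path, n_snps: int) -> pd.DataFrame:
    sidecar = pd.read_csv(path, sep="\t", dtype={"chr": str})
    need = {"block_id", "chr", "start_index", "end_index"}
    if not need.issubset(sidecar.columns):
        raise FormatError(f"block sidecar missing columns {sorted(need - set(sidecar.columns))}")
    blocks = sidecar.rename(columns={"start_index": "start", "end_index": "end"})
    blocks = blocks.sort_values("start").reset_index(drop=True)
    prev_end = 0
    for r in blocks.itertuples():
        if r.start < prev_end:
            raise FormatError(f"block sidecar: block {r.block_id} overlaps its predecessor")
        if not (0 <= r.start < r.end <= n_snps):
            raise FormatError(f"block sidecar: block {r.block_id} out of range")
        prev_end = r.end
    return blocks


def write_panel_vcf(
    panel: ReferencePanel, path: str | Path, blocks_path: str | Path | None = None
) -> None:
    """Write the panel as an uncompressed VCF 4.2 plus optional sidecar.

    Dosages are emitted as unphased GT (0 -> 0/0, 1 -> 0/1, 2 -> 1/1);
    fractional dosages are rounded.  ALT carries a1, REF carries a2.
    """
    n = panel.n_samples
    samples = [f"S{i + 1}" for i in range(n)]
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j, r in enumerate(panel.snp.itertuples()):
            dos = np.clip(np.rint(panel.dosages[:, j]).astype(int), 0, 2)
            gts = "\t".join(gt_strings[d] for d in dos)
            fh.write(f"{r.chr}\t{r.pos}\t{r.snp_id}\t{r.a2}\t{r.a1}\t.\tPASS\t.\tGT\t{gts}\n")
    if blocks_path is not None and panel.blocks is not None:
        out = panel.blocks.rename(columns={"start": "start_index", "end": "end_index"})
        out[["block_id", "chr", "start_index", "end_index"]].to_csv(
            blocks_path, sep="\t", index=False
        )


def _format_value(col: str, val) -> str:
    if isinstance(val, (bool, np.bool_)):
        return str(bool(val))
    if val is None or (isinstance(val, float) and math.isnan(val)):
        return "NA"
    if isinstance(val, (float, np.floating)):
        if col == "p" or col.endswith("_p"):  # p-values in scientific notation
            return f"{val:.6e}"
        return f"{val:.6g}"
    return str(val)


def write_table(rows, path: str | Path, columns: list[str] | None = None) -> None:
    """Write result records as TSV with fixed column order.

    ``rows`` is a sequence of mappings (or a DataFrame).  Columns default
    to :data:`RESULT_COLUMNS` plus any extra keys in encounter order.
    Floats are serialized at 6 significant digits; p-values in scientific
    notation so Table-1-scale magnitudes (1e-32) survive.
    """
    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict("records")
    rows = list(rows)
    if columns is None:
        seen = [c for c in RESULT_COLUMNS if any(c in r for r in rows)]
        extra = []
        for r in rows:
            for k in r:
                if k not in seen and k not in extra:
                    extra.append(k)
        columns = seen + extra
        if not columns:
            columns = RESULT_COLUMNS
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for r in rows:
            fh.write("\t".join(_format_value(c, r.get(c)) for c in columns) + "\n")
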