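"""Readers, writers and QC filters for the standard file formats.

Summary statistics, annotation tables, gene tables and plain genotype
matrices travel as TSV; peak tracks as broadPeak/BED (optionally gzipped);
genotypes alternatively as VCF (GT field, biallelic records only).  Allele
columns are passed through untouched: no strand or allele harmonization is
performed between summary statistics and the reference panel (a mismatch
checker can warn on allele-column disagreement, but alignment is the
caller's responsibility).
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .annotations import PeakTrack, SnpTable
from .gee import SummaryStats

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig",
    "qc_filter",
    "hwe_exact_test",
    "read_sumstats",
    "read_annotation_table",
    "read_genotypes",
    "read_genes",
    "read_peaks",
    "write_table",
    "write_weights",
    "read_weights",
]

#: MHC region excluded from enrichment analyses (1-based, bounds inclusive)
MHC_CHROM = "6"
MHC_START = 25_000_000
MHC_END = 34_000_000


@dataclass(frozen=True)
class QCConfig:
    """SNP-level quality-control thresholds.

    Rules are applied in fixed order — missingness, MAF, HWE, MHC — and a
    SNP is attributed to the first rule it fails.
    """

    max_missing: float = 0.05
    min_maf: float = 0.05
    min_hwe_p: float = 1e-4
    exclude_mhc: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.max_missing <= 1 and 0 < self.min_maf <= 0.5
                and 0 <= self.min_hwe_p <= 1):
            raise ValueError("QC thresholds out of range")


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg equilibrium test on genotype counts.

    Two-sided exact p-value: the probability, under HWE conditional on the
    allele counts, of a heterozygote count at most as probable as the one
    observed (Wigginton-style enumeration via log-factorials).
    """
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom1, n_hom2) + n_het
    hets = np.arange(rare % 2, rare + 1, 2)

    def logp(h):
        r_hom = (rare - h) // 2
        c_hom = n - h - r_hom
        return (gammaln(n + 1) - gammaln(h + 1) - gammaln(r_hom + 1)
                - gammaln(c_hom + 1) + h * np.log(2.0)
                + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1))

    logs = logp(hets.astype(np.float64))
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def qc_filter(genotypes: np.ndarray, snps: pd.DataFrame, cfg: QCConfig = QCConfig()):
    """Filter SNPs by missingness, MAF, HWE and the MHC region.

    ``genotypes`` is n x m with missing entries as negative values or NaN;
    ``snps`` carries chrom and pos per column.  Returns (kept column
    indices, report) where the report counts removals by first-failing
    rule, so input = survivors + sum of per-rule removals.
    """
    G = np.asarray(genotypes, dtype=np.float64)
    n, m = G.shape
    if len(snps) != m:
        raise ValueError("SNP table and genotype matrix disagree on SNP count")
    missing = np.isnan(G) | (G < 0)
    miss_rate = missing.mean(axis=0)
    report = {"input": m, "missingness": 0, "maf": 0, "hwe": 0, "mhc": 0}
    keep = np.ones(m, dtype=bool)
    chrom = snps["chrom"].astype(str).str.removeprefix("chr").to_numpy()
    pos = snps["pos"].to_numpy()
    for j in range(m):
        if miss_rate[j] > cfg.max_missing:
            report["missingness"] += 1
            keep[j] = False
            continue
        g = G[~missing[:, j], j]
        counts = [int(np.sum(g == k)) for k in (0, 1, 2)]
        total = sum(counts)
        freq = (counts[1] + 2 * counts[2]) / (2 * total) if total else 0.0
        maf = min(freq, 1 - freq)
        if maf < cfg.min_maf:
            report["maf"] += 1
            keep[j] = False
            continue
        if hwe_exact_test(*counts) < cfg.min_hwe_p:
            report["hwe"] += 1
            keep[j] = False
            continue
        if (cfg.exclude_mhc and chrom[j] == MHC_CHROM
                and MHC_START <= pos[j] <= MHC_END):
            report["mhc"] += 1
            keep[j] = False
    report["survivors"] = int(keep.sum())
    if report["survivors"] == 0:
        logger.warning("QC removed every SNP")
    logger.info("QC report: %s", report)
    return np.flatnonzero(keep), report


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_sumstats(path) -> tuple[SummaryStats, pd.DataFrame]:
    """Summary-statistics TSV with columns SNP, CHR, BP, Z and/or CHISQ, N.

    Z takes precedence when both Z and CHISQ are present; a squared-Z /
    CHISQ mismatch beyond 1e-6 is logged.  Returns the validated
    SummaryStats plus the full table (allele columns, if any, untouched).
    """
    df = pd.read_csv(path, sep="\t")
    _require(df, path, ["SNP", "N"])
    if "Z" not in df and "CHISQ" not in df:
        raise ValueError(f"{path}: need a Z or CHISQ column")
    if df["SNP"].duplicated().any():
        dup = df["SNP"][df["SNP"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate SNP id {dup!r}")
    if "Z" in df:
        _numeric(df, path, "Z")
        chisq = df["Z"].to_numpy(dtype=np.float64) ** 2
        if "CHISQ" in df:
            mismatch = np.abs(chisq - df["CHISQ"].to_numpy(dtype=np.float64)) > 1e-6
            if mismatch.any():
                logger.warning("%s: %d rows where CHISQ != Z^2 (Z takes precedence)",
                               path, int(mismatch.sum()))
        df["CHISQ"] = chisq
    else:
        _numeric(df, path, "CHISQ")
        chisq = df["CHISQ"].to_numpy(dtype=np.float64)
    n = int(df["N"].iloc[0])
    return SummaryStats(df["SNP"].to_numpy(dtype=object), chisq, n), df


def read_annotation_table(path) -> pd.DataFrame:
    """Annotation TSV: header ``snp_id<TAB>anno1<TAB>...``, one row per SNP."""
    df = pd.read_csv(path, sep="\t")
    _require(df, path, ["snp_id"])
    if df["snp_id"].duplicated().any():
        dup = df["snp_id"][df["snp_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate snp_id {dup!r}")
    for col in df.columns[1:]:
        _numeric(df, path, col)
    return df


def read_genotypes(path):
    """Genotypes as plain TSV matrix (rows = individuals, header = SNP ids)
    or VCF (GT dosages; multi-allelic records skipped with a warning).

    Returns (matrix n x m float with NaN for missing, snp table DataFrame).
    """
    path = Path(path)
    if path.suffix in (".vcf",) or path.name.endswith(".vcf.gz"):
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t")
    G = df.to_numpy(dtype=np.float64)
    snps = pd.DataFrame({"snp_id": df.columns, "chrom": "NA", "pos": 0})
    return G, snps


def _read_vcf(path):
    from cyvcf2 import VCF

    ids, chroms, poss, cols = [], [], [], []
    vcf = VCF(str(path))
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning("%s: skipping multi-allelic record at %s:%d",
                           path, rec.CHROM, rec.POS)
            continue
        gt = np.asarray(rec.gt_types, dtype=np.float64)
        # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        cols.append(dosage)
    G = np.column_stack(cols) if cols else np.empty((0, 0))
    snps = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": poss})
    return G, snps


def read_genes(path) -> pd.DataFrame:
    """Gene TSV with columns gene_id, chrom, start, end and optional strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    _require(df, path, ["gene_id", "chrom", "start", "end"])
    _numeric(df, path, "start")
    _numeric(df, path, "end")
    return df


def read_peaks(path, tissue_label: str = "", mark_label: str = "") -> PeakTrack:
    """broadPeak/BED reader; only chrom/start/end are used; gzip accepted."""
    opener = gzip.open if str(path).endswith(".gz") else open
    intervals = []
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            try:
                intervals.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    return PeakTrack.from_intervals(intervals, tissue_label, mark_label)


def snp_table_from_frame(df: pd.DataFrame) -> SnpTable:
    return SnpTable(df["snp_id"].to_numpy(), df["chrom"].astype(str).to_numpy(),
                    df["pos"].to_numpy())


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_weights(path, snp_ids, sigma2, weights, pp: float,
                  alpha_star_hat, centering_means) -> None:
    """SNP-weights TSV plus a JSON sidecar with the fit provenance.

    The sidecar carries the fitted coefficients and the genome-wide
    annotation means of the fitting cohort: the same centering must be
    replayed on the testing cohort's annotations.
    """
    path = Path(path)
    write_table(pd.DataFrame({"SNP": snp_ids, "sigma2": sigma2, "weight": weights}),
                path)
    sidecar = {
        "pp": float(pp),
        "alpha_star_hat": np.asarray(alpha_star_hat, dtype=float).tolist(),
        "centering_means": np.asarray(centering_means, dtype=float).tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def write_ld_blocks(ld, path, min_abs_r: float = 0.0) -> None:
    """Per-block correlations as TSV (block, i, j, r); upper triangle only,
    global SNP indices, entries with |r| <= min_abs_r omitted."""
    rows = []
    for b, sl in enumerate(ld.block_slices()):
        r = ld.corr[b]
        ii, jj = np.triu_indices_from(r)
        keep = np.abs(r[ii, jj]) > min_abs_r
        for i, j in zip(ii[keep], jj[keep]):
            rows.append((b, sl.start + i, sl.start + j, r[i, j]))
    write_table(pd.DataFrame(rows, columns=["block", "i", "j", "r"]), path)


def read_block_bounds(path) -> np.ndarray:
    """Block boundary TSV with columns start_snp_index, end_snp_index
    (0-based, half-open) -> bounds vector for estimate_ld_blocks."""
    df = pd.read_csv(path, sep="\t")
    _require(df, path, ["start_snp_index", "end_snp_index"])
    starts = df["start_snp_index"].to_numpy()
    ends = df["end_snp_index"].to_numpy()
    if not np.all(starts[1:] == ends[:-1]):
        raise ValueError(f"{path}: blocks must be contiguous")
    return np.append(starts, ends[-1])


def read_weights(path):
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    _require(df, path, ["SNP", "sigma2", "weight"])
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return df, sidecar


# ---------------------------------------------------------------------------

def _require(df: pd.DataFrame, path, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, path, col) -> None:
    try:
        df[col] = pd.to_numeric(df[col], errors="raise")
    except (ValueError, TypeError):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
        raise ValueError(
            f"{path}: non-numeric value in column {col!r} at data line {bad + 2}"
        ) from None
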