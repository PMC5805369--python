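"""Per-SNP functional annotation matrices.

A tissue is described by ``c`` per-SNP annotations (binary histone-mark
indicators, tissue-group occupancy averages, chromatin-state posteriors,
CADD-like scores, ...).  The annotation matrix ``A`` for a tissue is the
m x (c+1) matrix whose j-th row is ``(1, C_j1, ..., C_jc)``: an intercept
column followed by the annotation values of SNP j.  The intercept sets the
genome-wide average per-SNP effect-size variance, so the annotation columns
must be centered to mean zero across SNPs and must not be collinear with
the intercept (reference coding of genome partitions).

This module builds annotation matrices from peak tracks or precomputed
tables, averages them across tissues within a group, centers them, and
checks identifiability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnpTable",
    "PeakTrack",
    "AnnotationMatrix",
    "binarize_overlap",
    "group_average",
    "center_annotations",
    "check_identifiability",
    "build_annotation_matrix",
]

#: relative singular-value tolerance for the numerical rank used by
#: :func:`check_identifiability`
RANK_TOL = 1e-8

#: tolerance on the column means of a centered annotation matrix
CENTER_TOL = 1e-10


@dataclass(frozen=True)
class SnpTable:
    """Positions of the m SNPs, sorted by position within chromosome.

    Positions are 1-based (VCF convention).
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        snp_id = np.asarray(self.snp_id, dtype=object)
        chrom = np.asarray(self.chrom, dtype=object)
        pos = np.asarray(self.pos, dtype=np.int64)
        if len(snp_id) != len(set(snp_id)):
            raise ValueError("duplicate snp_id in SnpTable")
        if np.any(pos < 1):
            raise ValueError("SNP positions must be >= 1 (1-based)")
        # stable sort by (chromosome, position), keeping input chromosome order
        order = np.lexsort((pos, _chrom_rank(chrom)))
        object.__setattr__(self, "snp_id", snp_id[order])
        object.__setattr__(self, "chrom", chrom[order])
        object.__setattr__(self, "pos", pos[order])

    def __len__(self) -> int:
        return len(self.snp_id)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SnpTable":
        return cls(df["snp_id"].to_numpy(), df["chrom"].to_numpy(), df["pos"].to_numpy())


def _chrom_rank(chrom: np.ndarray) -> np.ndarray:
    seen: dict = {}
    ranks = np.empty(len(chrom), dtype=np.int64)
    for i, ch in enumerate(chrom):
        if ch not in seen:
            seen[ch] = len(seen)
        ranks[i] = seen[ch]
    return ranks


@dataclass(frozen=True)
class PeakTrack:
    """Peak intervals for one histone mark in one tissue.

    Intervals are 0-based half-open (BED/broadPeak convention) and are merged
    on construction, so overlapping or bookended input intervals collapse.
    """

    intervals: tuple
    tissue_label: str = ""
    mark_label: str = ""

    @classmethod
    def from_intervals(
        cls,
        intervals: Sequence[tuple],
        tissue_label: str = "",
        mark_label: str = "",
    ) -> "PeakTrack":
        merged: dict[str, list] = {}
        for chrom, start, end in intervals:
            if not start < end:
                raise ValueError(f"peak interval with start >= end: ({chrom}, {start}, {end})")
            merged.setdefault(str(chrom), []).append((int(start), int(end)))
        out = []
        for chrom, ivals in merged.items():
            ivals.sort()
            cur_s, cur_e = ivals[0]
            for s, e in ivals[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append((chrom, cur_s, cur_e))
        return cls(tuple(out), tissue_label, mark_label)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Merged intervals per chromosome as (k, 2) arrays of [start, end)."""
        out: dict[str, list] = {}
        for chrom, s, e in self.intervals:
            out.setdefault(chrom, []).append((s, e))
        return {ch: np.array(v, dtype=np.int64) for ch, v in out.items()}


@dataclass
class AnnotationMatrix:
    """m x (c+1) matrix ``A``; first column is the intercept (all ones).

    ``col_means``/``col_sds`` record the centering (and optional scaling)
    statistics of the annotation columns so that the same transformation can
    be replayed on a new cohort (SNP-weight construction requires the
    fitting cohort's genome-wide means).
    """

    values: np.ndarray
    column_labels: list[str]
    centered: bool = False
    tissue_label: str = ""
    col_means: np.ndarray | None = None
    col_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("annotation values must be a 2-d matrix")
        if not np.all(self.values[:, 0] == 1.0):
            raise ValueError("first column of an AnnotationMatrix must be the intercept (all 1)")
        if len(self.column_labels) != self.values.shape[1] - 1:
            raise ValueError("need one label per annotation column (intercept excluded)")
        if self.centered:
            mu = self.values[:, 1:].mean(axis=0)
            if self.n_annotations and np.max(np.abs(mu)) > CENTER_TOL:
                raise ValueError("centered flag set but annotation columns are not mean-zero")

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n_annotations(self) -> int:
        return self.values.shape[1] - 1

    @property
    def annotations(self) -> np.ndarray:
        """The annotation columns C (intercept excluded)."""
        return self.values[:, 1:]


def build_annotation_matrix(
    columns: Sequence[np.ndarray],
    labels: Sequence[str],
    tissue_label: str = "",
) -> AnnotationMatrix:
    """Stack raw (uncentered) annotation columns behind an intercept column."""
    cols = [np.asarray(c, dtype=np.float64) for c in columns]
    m = len(cols[0])
    if any(len(c) != m for c in cols):
        raise ValueError("annotation columns differ in length")
    values = np.column_stack([np.ones(m)] + cols)
    return AnnotationMatrix(values, list(labels), centered=False, tissue_label=tissue_label)


def binarize_overlap(snps: SnpTable, peaks: PeakTrack) -> np.ndarray:
    """Binary annotation: 1 iff the SNP lies inside a peak region.

    A 1-based SNP position p overlaps the 0-based half-open interval
    [start, end) iff ``start <= p - 1 < end``.  The vector follows the
    (sorted) SNP order of ``snps``.
    """
    out = np.zeros(len(snps), dtype=np.int8)
    by_chrom = peaks.by_chrom()
    peak_chroms = set(by_chrom)
    snp_chroms = set(snps.chrom)
    if peaks.intervals and not (peak_chroms & snp_chroms):
        logger.warning(
            "no shared chromosomes between SNPs (%s) and peaks (%s); annotation is all zero",
            sorted(map(str, snp_chroms)), sorted(map(str, peak_chroms)),
        )
    for chrom, ivals in by_chrom.items():
        mask = snps.chrom == chrom
        if not np.any(mask):
            continue
        p0 = snps.pos[mask] - 1  # 0-based coordinate of the SNP base
        starts, ends = ivals[:, 0], ivals[:, 1]
        # intervals are merged and sorted: SNP is inside iff the rightmost
        # start <= p0 belongs to an interval whose end > p0
        idx = np.searchsorted(starts, p0, side="right") - 1
        inside = (idx >= 0) & (p0 < ends[np.clip(idx, 0, None)])
        out[mask] = inside.astype(np.int8)
    return out


def group_average(columns: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of per-SNP columns across the tissues of a group.

    Used both for binary mark indicators (yielding a continuous occupancy
    fraction) and for chromatin-state posteriors.
    """
    if len(columns) == 0:
        raise ValueError("group_average requires at least one column")
    cols = [np.asarray(c, dtype=np.float64) for c in columns]
    m = len(cols[0])
    if any(len(c) != m for c in cols):
        raise ValueError("columns differ in length")
    return np.mean(cols, axis=0)


def center_annotations(A: AnnotationMatrix, standardize: bool = False) -> AnnotationMatrix:
    """Center annotation columns to mean zero across SNPs (intercept untouched).

    With ``standardize=True`` the columns are additionally scaled to unit
    standard deviation.  Constant columns cannot be standardized; without
    standardization they are allowed but flagged in the log (they become
    all-zero and will fail the identifiability check downstream).
    """
    if A.centered:
        raise ValueError("annotation matrix is already centered")
    C = A.annotations
    means = C.mean(axis=0)
    sds = C.std(axis=0)
    constant = sds == 0.0
    if np.any(constant):
        names = [A.column_labels[i] for i in np.flatnonzero(constant)]
        if standardize:
            raise ValueError(f"cannot standardize constant annotation column(s): {names}")
        logger.warning("constant annotation column(s) after centering: %s", names)
    Cc = C - means
    if standardize:
        Cc = Cc / sds
    values = np.column_stack([np.ones(A.m), Cc])
    return replace(
        A,
        values=values,
        centered=True,
        col_means=means,
        col_sds=sds if standardize else None,
    )


@dataclass(frozen=True)
class IdentifiabilityResult:
    ok: bool
    #: coefficients b with [1 | C] b ~= 0 when not identifiable (witness)
    witness: np.ndarray | None = None
    message: str = ""

    def __bool__(self) -> bool:
        return self.ok


def check_identifiability(A: AnnotationMatrix) -> IdentifiabilityResult:
    """Check that no linear combination of annotations equals the intercept.

    Passes iff rank([1 | C]) == rank(C) + 1 (numerical rank, relative
    tolerance :data:`RANK_TOL`).  Two complementary binary annotations that
    partition the genome fail; dropping one cell of the partition
    (reference coding) restores identifiability.  On failure the returned
    witness is the right-singular vector of the near-null direction.
    """
    full = A.values
    C = A.annotations
    s_full = np.linalg.svd(full, compute_uv=False)
    rank_full = int(np.sum(s_full > RANK_TOL * s_full[0]))
    if C.shape[1] == 0:
        return IdentifiabilityResult(True, message="intercept-only matrix")
    s_c = np.linalg.svd(C, compute_uv=False)
    rank_c = int(np.sum(s_c > RANK_TOL * (s_c[0] if s_c[0] > 0 else 1.0)))
    if rank_full == rank_c + 1:
        return IdentifiabilityResult(True)
    _, _, vt = np.linalg.svd(full)
    witness = vt[-1]
    return IdentifiabilityResult(
        False,
        witness=witness,
        message=(
            "annotation columns are collinear with the intercept "
            f"(rank([1|C])={rank_full}, rank(C)={rank_c}); "
            "use reference coding (drop one cell of any genome partition)"
        ),
    )
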