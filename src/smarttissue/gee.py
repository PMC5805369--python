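"""GEE fit of annotation coefficients to marginal chi-square statistics.

Model.  Phenotypes follow y = X beta + e with standardized genotypes, and
each SNP effect is beta_j ~ N(0, sigma_j^2 / m) with sigma_j^2 = A_j' alpha*
a linear function of the SNP's (centered) annotations.  Under this model
the marginal association chi-square of SNP j satisfies the moment equation

    E[chi2_j] = 1 + (n/m) * sum_l r_jl^2 A_l' alpha*

where r_jl is the LD correlation between SNPs j and l, restricted to SNP
j's LD block under the block-diagonal approximation.  Writing
d_j = (n/m) sum_l r_jl^2 A_l, the coefficients alpha* solve a linear
system that generalized estimating equations fit in closed form:

    alpha_hat = (D' V^-1 D)^-1 D' V^-1 (s - 1)

with a working covariance V that is either the identity (independence,
the LDSC/MQS regime) or the block-diagonal null covariance of chi-square
statistics V_jl = 2 r_jl^2 (the polyGEE regime).  The robust sandwich
covariance B^-1 M B^-1 with LD blocks as independent clusters is valid
under either working choice.  The per-tissue multivariate Wald statistic
alpha_hat' V(alpha_hat)^-1 alpha_hat (annotation coefficients only,
df = c) measures trait-tissue relevance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import AnnotationMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SummaryStats",
    "LDBlocks",
    "DesignMatrix",
    "GEEFit",
    "chisq_from_z",
    "winsorize_chisq",
    "estimate_ld_blocks",
    "identity_ld",
    "build_design",
    "gee_fit",
    "GEESolver",
    "wald_statistic",
    "fit_all_tissues",
]


@dataclass(frozen=True)
class SummaryStats:
    """Per-SNP marginal chi-square statistics from a GWAS of n individuals."""

    snp_id: np.ndarray
    chisq: np.ndarray
    n: int

    def __post_init__(self) -> None:
        chisq = np.asarray(self.chisq, dtype=np.float64)
        if np.any(chisq < 0) or not np.all(np.isfinite(chisq)):
            raise ValueError("chi-square statistics must be finite and >= 0")
        if self.n < 1:
            raise ValueError("sample size n must be >= 1")
        object.__setattr__(self, "chisq", chisq)
        object.__setattr__(self, "snp_id", np.asarray(self.snp_id, dtype=object))

    @property
    def m(self) -> int:
        return len(self.chisq)


def chisq_from_z(z: np.ndarray, n: int, snp_id: Sequence | None = None) -> SummaryStats:
    """Square marginal z-scores into chi-square statistics; drop missing SNPs."""
    z = np.asarray(z, dtype=np.float64)
    if snp_id is None:
        snp_id = np.array([f"snp{i}" for i in range(len(z))], dtype=object)
    snp_id = np.asarray(snp_id, dtype=object)
    keep = np.isfinite(z)
    if not np.all(keep):
        dropped = snp_id[~keep]
        logger.info("dropping %d SNP(s) with missing z-scores: %s%s",
                    len(dropped), list(dropped[:5]), "..." if len(dropped) > 5 else "")
    return SummaryStats(snp_id[keep], z[keep] ** 2, n)


def winsorize_chisq(stats: SummaryStats, max_chisq: float) -> SummaryStats:
    """Cap extreme chi-square statistics at ``max_chisq`` (opt-in only;
    no winsorization is applied unless a cap is requested)."""
    if max_chisq <= 0:
        raise ValueError("max_chisq must be positive")
    capped = np.minimum(stats.chisq, max_chisq)
    n_cap = int(np.sum(stats.chisq > max_chisq))
    if n_cap:
        logger.info("winsorized %d chi-square statistic(s) at %g", n_cap, max_chisq)
    return SummaryStats(stats.snp_id, capped, stats.n)


@dataclass(frozen=True)
class LDBlocks:
    """Block-diagonal LD approximation: per-block correlation matrices.

    ``bounds`` holds B+1 SNP-index boundaries; block b covers SNP indices
    [bounds[b], bounds[b+1]).  ``corr[b]`` is the symmetric correlation
    matrix of that block with unit diagonal.
    """

    bounds: np.ndarray
    corr: tuple
    n_ref: int

    def __post_init__(self) -> None:
        bounds = np.asarray(self.bounds, dtype=np.int64)
        if bounds[0] != 0 or np.any(np.diff(bounds) <= 0):
            raise ValueError("block bounds must start at 0 and be strictly increasing")
        for b, r in enumerate(self.corr):
            size = bounds[b + 1] - bounds[b]
            if r.shape != (size, size):
                raise ValueError(f"block {b}: correlation shape {r.shape} != block size {size}")
        object.__setattr__(self, "bounds", bounds)

    @property
    def m(self) -> int:
        return int(self.bounds[-1])

    @property
    def n_blocks(self) -> int:
        return len(self.bounds) - 1

    def block_slices(self) -> list[slice]:
        return [slice(int(self.bounds[b]), int(self.bounds[b + 1])) for b in range(self.n_blocks)]


def identity_ld(m: int, block_size: int = 1000) -> LDBlocks:
    """LD-independent blocks (identity correlation), mainly for testing."""
    bounds = np.arange(0, m, block_size).tolist() + [m]
    bounds = np.unique(np.asarray(bounds, dtype=np.int64))
    corr = tuple(np.eye(int(b - a)) for a, b in zip(bounds[:-1], bounds[1:]))
    return LDBlocks(bounds, corr, n_ref=0)


def estimate_ld_blocks(
    ref_genotypes: np.ndarray,
    block_size: int = 1000,
    bounds: Sequence[int] | None = None,
    adjust_r2: bool = True,
) -> LDBlocks:
    """Per-block Pearson correlations from a reference genotype panel.

    ``ref_genotypes`` is n_ref x m (individuals x SNPs).  Blocks default to
    contiguous windows of ``block_size`` SNPs; explicit ``bounds`` override.
    Monomorphic SNPs have undefined correlation and are treated as
    LD-independent (identity row/column).  With ``adjust_r2`` the squared
    correlations consumed downstream are bias-adjusted toward the panel:
    r2_adj = r2 - (1 - r2)/(n_ref - 2); the adjustment is recorded and
    applied in :func:`build_design` and the LD working covariance.
    """
    G = np.asarray(ref_genotypes, dtype=np.float64)
    n_ref, m = G.shape
    if bounds is None:
        bnds = np.unique(np.asarray(list(range(0, m, block_size)) + [m], dtype=np.int64))
    else:
        bnds = np.asarray(bounds, dtype=np.int64)
    corr = []
    for a, b in zip(bnds[:-1], bnds[1:]):
        block = G[:, a:b]
        sd = block.std(axis=0)
        mono = sd == 0.0
        if np.any(mono):
            logger.warning("block [%d,%d): %d monomorphic SNP(s) treated as LD-independent",
                           a, b, int(mono.sum()))
        safe = np.where(mono, 1.0, sd)
        Z = (block - block.mean(axis=0)) / safe
        r = (Z.T @ Z) / n_ref
        r[mono, :] = 0.0
        r[:, mono] = 0.0
        np.fill_diagonal(r, 1.0)
        corr.append(r)
    ld = LDBlocks(bnds, tuple(corr), n_ref=n_ref)
    object.__setattr__(ld, "_adjust_r2", bool(adjust_r2) and n_ref > 2)
    return ld


def _block_r2(ld: LDBlocks, b: int) -> np.ndarray:
    """Squared correlations of block b, bias-adjusted if the panel asked for it."""
    r2 = ld.corr[b] ** 2
    if getattr(ld, "_adjust_r2", False):
        r2 = r2 - (1.0 - r2) / (ld.n_ref - 2)
        np.fill_diagonal(r2, 1.0)
    return r2


@dataclass(frozen=True)
class DesignMatrix:
    """GEE design rows d_j = (n/m) sum_{l in block(j)} r_jl^2 A_l and LD scores."""

    D: np.ndarray
    ld_scores: np.ndarray
    n: int
    m: int


def build_design(ld: LDBlocks, A: AnnotationMatrix, n: int) -> DesignMatrix:
    """LD-aggregate the annotation matrix into the chi-square regression design.

    With identity LD this reduces to d_j = (n/m) A_j and LD score 1.
    """
    if not A.centered:
        raise ValueError("annotation matrix must be centered before building the design")
    m = A.m
    if ld.m != m:
        raise ValueError(f"LD blocks cover {ld.m} SNPs but annotation matrix has {m}")
    D = np.empty_like(A.values)
    ell = np.empty(m)
    scale = n / m
    for b, sl in enumerate(ld.block_slices()):
        r2 = _block_r2(ld, b)
        D[sl] = scale * (r2 @ A.values[sl])
        ell[sl] = r2.sum(axis=1)
    return DesignMatrix(D, ell, n=n, m=m)


@dataclass(frozen=True)
class GEEFit:
    """Closed-form GEE estimates of alpha* = (alpha_0, alpha) with sandwich covariance."""

    alpha_star_hat: np.ndarray
    cov: np.ndarray
    wald: float
    df: int
    working: str
    labels: tuple = ()
    #: estimated additive chi-square inflation when fitted with a free
    #: intercept (confounding guard); None under the model-implied fixed
    #: intercept of 1
    free_intercept_hat: float | None = None

    @property
    def alpha0_hat(self) -> float:
        return float(self.alpha_star_hat[0])

    @property
    def alpha_hat(self) -> np.ndarray:
        return self.alpha_star_hat[1:]

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


class GEESolver:
    """Precomputed GEE system for one design matrix and working covariance.

    Factorizes everything that does not depend on the response so repeated
    fits on new summary statistics (simulation replicates) are cheap:
    per-block K_b = V_b^-1 D_b and the bread B = D' V^-1 D are cached.
    """

    def __init__(self, design: DesignMatrix, ld: LDBlocks,
                 working: str = "independence", free_intercept: bool = False):
        if working not in ("independence", "ld"):
            raise ValueError("working must be 'independence' or 'ld'")
        if ld.m != design.m:
            raise ValueError("LD blocks and design matrix disagree on m")
        self.design = design
        self.ld = ld
        self.working = working
        self.free_intercept = free_intercept
        self.slices = ld.block_slices()
        D = design.D
        if free_intercept:
            # extra constant column absorbs additive chi-square inflation
            # (confounding), LDSC-style; off by default (model implies 1)
            D = np.column_stack([D, np.ones(design.m)])
        self._D = D
        p = D.shape[1]
        if design.m < p:
            raise ValueError(f"fewer SNPs ({design.m}) than coefficients ({p})")
        self.K = []  # V_b^-1 D_b per block
        B = np.zeros((p, p))
        for b, sl in enumerate(self.slices):
            Db = D[sl]
            if working == "independence":
                Kb = Db
            else:
                Vb = 2.0 * _block_r2(ld, b)
                # null covariance of chi-squares; guard against singular blocks
                Kb = _solve_psd(Vb, Db)
            self.K.append(Kb)
            B += Db.T @ Kb
        self.B = B
        try:
            self.B_inv = np.linalg.inv(B)
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "singular GEE system: annotation columns "
                "are collinear after LD aggregation"
            ) from None

    def fit(self, stats: SummaryStats, labels: Sequence[str] = ()) -> GEEFit:
        if stats.m != self.design.m:
            raise ValueError("summary statistics and design matrix disagree on m")
        u = stats.chisq - 1.0
        D = self._D
        p = D.shape[1]
        rhs = np.zeros(p)
        for sl, Kb in zip(self.slices, self.K):
            rhs += Kb.T @ u[sl]
        alpha = self.B_inv @ rhs
        M = np.zeros((p, p))
        for sl, Kb in zip(self.slices, self.K):
            g = Kb.T @ (u[sl] - D[sl] @ alpha)  # cluster score
            M += np.outer(g, g)
        cov = self.B_inv @ M @ self.B_inv
        extra = None
        if self.free_intercept:
            extra = float(alpha[-1])
            alpha, cov = alpha[:-1], cov[:-1, :-1]
        fit = GEEFit(alpha, cov, wald=np.nan, df=len(alpha) - 1,
                     working=self.working, labels=tuple(labels),
                     free_intercept_hat=extra)
        return wald_statistic(fit)


def _solve_psd(V: np.ndarray, B: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.solve(V, B)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(V) @ B


def gee_fit(
    design: DesignMatrix,
    stats: SummaryStats,
    ld: LDBlocks,
    working: str = "independence",
    labels: Sequence[str] = (),
) -> GEEFit:
    """One-shot closed-form GEE fit (see :class:`GEESolver` for repeated fits)."""
    return GEESolver(design, ld, working).fit(stats, labels=labels)


def wald_statistic(fit: GEEFit) -> GEEFit:
    """Multivariate Wald statistic over the c annotation coefficients.

    The intercept alpha_0 is excluded; df equals the number of annotations.
    A numerically singular sub-covariance falls back to the pseudo-inverse
    with the effective df reduced to its rank.
    """
    from dataclasses import replace

    a = fit.alpha_hat
    V = fit.cov[1:, 1:]
    df = len(a)
    if df == 0:
        return replace(fit, wald=0.0, df=0)
    try:
        w = float(a @ np.linalg.solve(V, a))
        eff_df = df
    except np.linalg.LinAlgError:
        logger.warning("singular Wald sub-covariance; using pseudo-inverse")
        w = float(a @ np.linalg.pinv(V) @ a)
        eff_df = int(np.linalg.matrix_rank(V))
    return replace(fit, wald=max(w, 0.0), df=eff_df)


def fit_all_tissues(
    stats: SummaryStats,
    tissue_annotations: Sequence[AnnotationMatrix],
    ld: LDBlocks,
    working: str = "independence",
    mode: str = "joint",
) -> pd.DataFrame:
    """Fit the model per tissue and tabulate Wald statistics.

    mode='joint' fits all c annotations of a tissue together (the SMART
    statistic, df=c).  mode='unimax' fits one annotation at a time and keeps
    the larger univariate Wald statistic (df=1).  Per-tissue failures are
    recorded as NA rows and the scan continues.
    """
    rows = []
    for t, A in enumerate(tissue_annotations):
        tissue = A.tissue_label or f"tissue{t}"
        try:
            if mode == "joint":
                design = build_design(ld, A, stats.n)
                fit = gee_fit(design, stats, ld, working, labels=A.column_labels)
                rows.append(_row(tissue, fit))
            elif mode == "unimax":
                best = None
                for k in range(A.n_annotations):
                    sub = AnnotationMatrix(
                        A.values[:, [0, k + 1]], [A.column_labels[k]],
                        centered=A.centered, tissue_label=A.tissue_label,
                    )
                    design = build_design(ld, sub, stats.n)
                    fit = gee_fit(design, stats, ld, working, labels=sub.column_labels)
                    if best is None or fit.wald > best.wald:
                        best = fit
                rows.append(_row(tissue, best))
            else:
                raise ValueError(f"unknown mode {mode!r}")
        except (np.linalg.LinAlgError, ValueError) as exc:
            if mode not in ("joint", "unimax"):
                raise
            logger.warning("tissue %s failed: %s", tissue, exc)
            rows.append({"tissue": tissue, "wald": np.nan, "df": np.nan})
    return pd.DataFrame(rows)


def _row(tissue: str, fit: GEEFit) -> dict:
    row = {"tissue": tissue, "wald": fit.wald, "df": fit.df,
           "alpha0_hat": fit.alpha0_hat}
    for i, lab in enumerate(fit.labels or [f"anno{i+1}" for i in range(len(fit.alpha_hat))]):
        row[f"alpha_{lab}"] = fit.alpha_hat[i]
        row[f"se_{lab}"] = fit.se[i + 1]
    return row
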