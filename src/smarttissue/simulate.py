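"""Synthetic data generation and the two simulation study designs.

Design 1 (tissue identification).  All m SNPs are causal under the
annotation-dependent variance model: one of ten tissues is trait-relevant
per replicate, and SNP effect variances follow sigma_j^2 = A_j' alpha*
with the relevant tissue's two (binary, cross-tissue-correlated)
annotations.  Marginal chi-square statistics from the simulated cohort are
scanned per tissue with the GEE, Wald statistics are classified by the
mixture EM, and power to recover the relevant tissue is evaluated at fixed
false discovery rates.

Design 2 (weighted SNP-set test).  10,000 SNPs in 100 blocks of 100;
10 non-adjacent causal blocks with 20% causal SNPs each (200 causal SNPs).
Causal SNPs fall into three groups that determine which of the two
continuous annotations is elevated (mean 10 vs 0), controlling the
annotation correlation at causal SNPs.  Phenotypes are formed on the full
cohort, split 7,000 train / 3,000 test; SNP weights built on the training
side feed a weighted SKAT on the test side, and power to detect causal
blocks is evaluated at a genome-wide threshold of 1e-4.

Synthetic genotypes use a latent Gaussian AR(1) copula within LD blocks,
standing in for the real cohort genotypes used in the original analyses;
reference-panel LD comes from an independently simulated panel.  All
randomness flows from one master seed through numpy SeedSequence spawning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotationMatrix, build_annotation_matrix, center_annotations
from .gee import (GEESolver, LDBlocks, SummaryStats, build_design,
                  estimate_ld_blocks)
from .mixture import em_fit
from .skat import construct_weights, tail_pvalue

logger = logging.getLogger(__name__)

__all__ = [
    "Design1Config",
    "Design2Config",
    "simulate_genotypes",
    "standardize_genotypes",
    "simulate_tissue_annotations",
    "simulate_causal_annotations",
    "simulate_effects_phenotype",
    "marginal_scan",
    "per_block_pve",
    "evaluate_power_at_fdr",
    "Design1Runner",
    "Design2Runner",
    "run_design1",
    "run_design2",
    "skat_null_calibration",
]


# ---------------------------------------------------------------------------
# study configurations (defaults are the study conditions, desk-scaled where
# the original used cohort-scale real genotypes; see docs/methods.md)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Design1Config:
    n: int = 2_000            # GWAS cohort size (original: 10,000 real individuals)
    m: int = 2_000            # SNPs (original: 27,640)
    n_tissues: int = 10
    alpha0: float = 0.1       # variance intercept -> SNP heritability 0.1
    sigma_e2: float = 0.9
    coef_grid: tuple = (-0.1, 0.0, 0.05, 0.1, 0.25, 0.5)
    occupancies: tuple = (0.18, 0.107)   # H3K4me1 / H3K4me3 genome fractions
    cross_tissue_corr: float = 0.7       # "highly correlated" annotation regime
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.8
    ld_block: int = 100
    n_ref: int = 500          # simulated reference panel (original: 503 1000G EUR)
    working: str = "ld"
    n_reps: int = 100
    fdr_levels: tuple = (0.05, 0.1, 0.2)

    @property
    def heritability(self) -> float:
        """Implied SNP heritability alpha0 / (alpha0 + sigma_e2) (centered annotations)."""
        return self.alpha0 / (self.alpha0 + self.sigma_e2)


@dataclass(frozen=True)
class Design2Config:
    n: int = 10_000
    m: int = 10_000
    block_size: int = 100
    n_causal_blocks: int = 10
    causal_frac: float = 0.2  # 20% of SNPs per causal block -> 200 causal SNPs
    alpha0: float = 0.5
    sigma_e2: float = 0.5
    coef_settings: tuple = ((0.4, 0.4), (0.4, 0.0))
    group_proportions: tuple = ((0.5, 0.5, 0.0), (1 / 3, 1 / 3, 1 / 3), (0.0, 0.0, 1.0))
    elevated_mean: float = 10.0
    n_tissues: int = 10
    n_train: int = 7_000
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.8
    n_ref: int = 500
    working: str = "ld"
    sig_threshold: float = 1e-4
    n_reps: int = 200

    @property
    def n_causal(self) -> int:
        return int(round(self.n_causal_blocks * self.block_size * self.causal_frac))


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple = (0.05, 0.5),
    ld="independent",
    rng=None,
) -> np.ndarray:
    """Dosage genotypes in {0,1,2} with optional blockwise AR(1) LD.

    ``ld`` is either "independent" or a tuple ("ar1", rho, block_size): two
    latent Gaussian haplotypes with within-block correlation rho**|i-j| are
    thresholded at the allele frequency quantile, so the realized LD decays
    geometrically inside blocks and vanishes across block boundaries.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(rng)
    maf = rng.uniform(lo, hi, size=m)
    if ld == "independent":
        return rng.binomial(2, maf, size=(n, m)).astype(np.int8)
    kind, rho, block = ld
    if kind != "ar1" or not 0.0 <= rho < 1.0:
        raise ValueError(f"unsupported ld spec {ld!r}")
    thr = stats.norm.ppf(maf)
    G = np.empty((n, m), dtype=np.int8)
    c = np.sqrt(1.0 - rho ** 2)
    for a in range(0, m, block):
        b = min(a + block, m)
        L = b - a
        acc = np.zeros((n, L), dtype=np.int8)
        for _hap in range(2):
            e = rng.standard_normal((n, L))
            z = np.empty((n, L))
            z[:, 0] = e[:, 0]
            for j in range(1, L):
                z[:, j] = rho * z[:, j - 1] + c * e[:, j]
            acc += (z < thr[a:b]).astype(np.int8)
        G[:, a:b] = acc
    return G


def standardize_genotypes(G: np.ndarray, dtype=np.float64):
    """Column-standardize dosages (zero mean, unit variance); returns
    (X, means, sds).  Monomorphic columns are zeroed and flagged."""
    G = np.asarray(G)
    means = G.mean(axis=0, dtype=np.float64)
    sds = G.std(axis=0, dtype=np.float64)
    mono = sds == 0.0
    if np.any(mono):
        logger.warning("%d monomorphic column(s) zeroed during standardization",
                       int(mono.sum()))
    safe = np.where(mono, 1.0, sds)
    X = ((G - means) / safe).astype(dtype)
    X[:, mono] = 0.0
    return X, means, sds


def simulate_tissue_annotations(
    m: int,
    n_tissues: int = 10,
    occupancies: Sequence[float] = (0.18, 0.107),
    cross_tissue_corr: float = 0.7,
    rng=None,
    mark_labels: Sequence[str] | None = None,
) -> list[AnnotationMatrix]:
    """Binary mark annotations, correlated across tissues.

    One latent genome template per mark (occupancy p) is shared by all
    tissues; each tissue keeps a template bit with probability
    sqrt(cross_tissue_corr) and redraws it from Bernoulli(p) otherwise, so
    the between-tissue correlation of a mark equals ``cross_tissue_corr``
    (bits are shared only through the template) and grows monotonically in
    the parameter, reaching identical tissues at 1.
    """
    if not 0.0 <= cross_tissue_corr < 1.0:
        raise ValueError("cross_tissue_corr must lie in [0, 1)")
    rng = np.random.default_rng(rng)
    if mark_labels is None:
        mark_labels = [f"mark{k+1}" for k in range(len(occupancies))]
    keep_p = np.sqrt(cross_tissue_corr)
    templates = [rng.random(m) < occ for occ in occupancies]
    out = []
    for t in range(n_tissues):
        cols = []
        for tmpl, occ in zip(templates, occupancies):
            keep = rng.random(m) < keep_p
            fresh = rng.random(m) < occ
            cols.append(np.where(keep, tmpl, fresh).astype(np.float64))
        out.append(build_annotation_matrix(cols, mark_labels, tissue_label=f"tissue{t}"))
    return out


def simulate_causal_annotations(
    m: int,
    causal_idx: np.ndarray,
    group_proportions: Sequence[float],
    rng=None,
    elevated_mean: float = 10.0,
):
    """Two continuous annotations predictive of SNP causality.

    Non-causal SNPs draw both annotations from N(0, 1).  Causal SNPs are
    split into three groups by ``group_proportions``: annotation 1 is
    elevated (mean ``elevated_mean``) in groups 2 and 3, annotation 2 in
    groups 1 and 3, so the third group's share controls the correlation
    between the two annotations at causal SNPs.  Returns (C1, C2, groups)
    with groups in {1,2,3} aligned to ``causal_idx``.
    """
    props = np.asarray(group_proportions, dtype=np.float64)
    if props.shape != (3,) or abs(props.sum() - 1.0) > 1e-9 or np.any(props < 0):
        raise ValueError("group_proportions must be 3 nonnegative values summing to 1")
    rng = np.random.default_rng(rng)
    causal_idx = np.asarray(causal_idx)
    k = len(causal_idx)
    counts = np.floor(props * k).astype(int)
    for i in np.argsort(-(props * k - counts))[: k - counts.sum()]:
        counts[i] += 1
    groups = np.repeat([1, 2, 3], counts)
    groups = groups[rng.permutation(k)]
    C1 = rng.standard_normal(m)
    C2 = rng.standard_normal(m)
    C1[causal_idx[groups >= 2]] += elevated_mean   # groups 2, 3
    C2[causal_idx[groups != 2]] += elevated_mean   # groups 1, 3
    return C1, C2, groups


def simulate_effects_phenotype(
    X: np.ndarray,
    A: AnnotationMatrix,
    alpha_star: Sequence[float],
    sigma_e2: float,
    rng=None,
    causal_mask: np.ndarray | None = None,
):
    """Draw SNP effects beta_j ~ N(0, sigma_j^2 / m) and the phenotype y.

    sigma_j^2 = A_j' alpha* with centered annotations, clamped below at
    zero (a negative annotation coefficient can push the linear variance
    model negative; the clamp is the variance-respecting choice).  With
    ``causal_mask``, non-causal SNPs get exactly zero effect.  Returns
    (beta, y) with y = X beta + e, e ~ N(0, sigma_e2).
    """
    if not A.centered:
        raise ValueError("annotation matrix must be centered")
    rng = np.random.default_rng(rng)
    n, m = X.shape
    sigma2 = A.values @ np.asarray(alpha_star, dtype=np.float64)
    clamped = sigma2 < 0
    sigma2 = np.where(clamped, 0.0, sigma2)
    if causal_mask is not None:
        sigma2 = np.where(causal_mask, sigma2, 0.0)
    if np.all(sigma2 == 0.0) and np.any(np.asarray(alpha_star) != 0):
        logger.warning("all SNP variances clamped to zero: degenerate design")
    beta = rng.standard_normal(m) * np.sqrt(sigma2 / m)
    nz = np.flatnonzero(beta)
    if len(nz) > m // 2:
        g = np.asarray(X @ beta.astype(X.dtype), dtype=np.float64)
    else:
        g = X[:, nz].astype(np.float64) @ beta[nz]
    y = g + rng.standard_normal(n) * np.sqrt(sigma_e2)
    return beta, y


def marginal_scan(X: np.ndarray, y: np.ndarray):
    """Single-SNP regression z-scores and chi-squares (columns standardized).

    For standardized x and centered y the slope is b_j = x_j'y/n and
    z_j = b_j sqrt(n) / sigma_hat_j with the residual variance on n-2 df.
    Zero-variance columns yield NaN.
    """
    n, m = X.shape
    yc = y - y.mean()
    xvar = np.einsum("ij,ij->j", X, X, dtype=np.float64) / n
    zero = xvar <= 0
    # match the matrix dtype to avoid a full-matrix upcast copy
    b = np.asarray(X.T @ yc.astype(X.dtype), dtype=np.float64) / n
    yss = float(yc @ yc)
    rss = np.maximum(yss - n * b ** 2, 1e-30)
    z = b * np.sqrt(n) / np.sqrt(rss / (n - 2))
    if np.any(zero):
        logger.warning("%d zero-variance SNP(s) in marginal scan set to NaN", zero.sum())
        z = np.where(zero, np.nan, z)
    return z, z ** 2


def per_block_pve(beta: np.ndarray, X: np.ndarray, blocks: Sequence, y: np.ndarray):
    """Per-block proportion of phenotype variance explained Var(X_b beta_b)/Var(y)."""
    var_y = float(np.var(y))
    out = np.zeros(len(blocks))
    for i, sl in enumerate(blocks):
        idx = np.arange(sl.start, sl.stop) if isinstance(sl, slice) else np.asarray(sl)
        nz = idx[beta[idx] != 0]
        if len(nz):
            g = X[:, nz].astype(np.float64) @ beta[nz]
            out[i] = float(np.var(g)) / var_y
    return out


def evaluate_power_at_fdr(
    pp_table: np.ndarray,
    truth: np.ndarray,
    fdr_levels: Sequence[float] = (0.05, 0.1, 0.2),
    col_tissue: np.ndarray | None = None,
) -> dict:
    """Power to detect the trait-relevant tissue at empirical FDR levels.

    All (replicate, column) calls are pooled and sorted by posterior
    probability (descending; ties broken by stable input order).  Walking
    down the list, FDR = FP/(FP+TP) and power = TP / #replicates; the power
    at level t is taken at the most permissive cutoff with FDR <= t.  When
    several columns map to one tissue (``col_tissue``), a replicate counts
    as detected at most once.
    """
    pp = np.asarray(pp_table, dtype=np.float64)
    truth = np.asarray(truth)
    R, K = pp.shape
    flat = pp.ravel()
    order = np.argsort(-flat, kind="stable")
    rep = order // K
    col = order % K
    tissue = col if col_tissue is None else np.asarray(col_tissue)[col]
    is_true = truth[rep] == tissue
    if col_tissue is None:
        tp = np.cumsum(is_true)
    else:
        tp = np.empty(len(order), dtype=np.int64)
        seen: set = set()
        count = 0
        for i, (r, hit) in enumerate(zip(rep, is_true)):
            if hit and r not in seen:
                seen.add(r)
                count += 1
            tp[i] = count
    fp = np.arange(1, len(order) + 1) - np.cumsum(is_true)
    fdr = fp / np.maximum(fp + tp, 1)
    power = {}
    for level in fdr_levels:
        ok = np.flatnonzero(fdr <= level)
        power[level] = float(tp[ok[-1]] / R) if len(ok) else 0.0
    return power


# ---------------------------------------------------------------------------
# design 1: tissue identification power
# ---------------------------------------------------------------------------

class Design1Runner:
    """Shared state for design-1 replicates.

    Genotypes, the reference panel, the tissue annotations and hence the
    per-tissue GEE systems are fixed across replicates (the original study
    reused one real cohort and real annotation tracks); only the relevant
    tissue, the SNP effects and the residuals are redrawn.
    """

    def __init__(self, cfg: Design1Config = Design1Config(), seed: int = 0):
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        s_geno, s_ref, s_anno, self._ss_rep = ss.spawn(4)
        ld_spec = ("ar1", cfg.ld_rho, cfg.ld_block)
        G = simulate_genotypes(cfg.n, cfg.m, cfg.maf_range, ld_spec,
                               np.random.default_rng(s_geno))
        self.X, _, _ = standardize_genotypes(G)
        G_ref = simulate_genotypes(cfg.n_ref, cfg.m, cfg.maf_range, ld_spec,
                                   np.random.default_rng(s_ref))
        self.ld = estimate_ld_blocks(G_ref, block_size=cfg.ld_block)
        raw = simulate_tissue_annotations(
            cfg.m, cfg.n_tissues, cfg.occupancies, cfg.cross_tissue_corr,
            np.random.default_rng(s_anno))
        self.annotations = [center_annotations(A) for A in raw]
        self.snp_id = np.array([f"snp{i}" for i in range(cfg.m)], dtype=object)
        self._joint = []
        self._uni = []
        for A in self.annotations:
            self._joint.append(
                GEESolver(build_design(self.ld, A, cfg.n), self.ld, cfg.working))
            per_anno = []
            for k in range(A.n_annotations):
                sub = AnnotationMatrix(A.values[:, [0, k + 1]], [A.column_labels[k]],
                                       centered=True, tissue_label=A.tissue_label)
                per_anno.append(
                    GEESolver(build_design(self.ld, sub, cfg.n), self.ld, cfg.working))
            self._uni.append(per_anno)

    def run_setting(self, alpha1: float, alpha2: float, n_reps: int | None = None,
                    include_uni: bool = False):
        """Replicates at one (alpha1, alpha2): per-replicate tissue PPs for
        the joint (SMART) and max-univariate statistics, plus the joint
        coefficient estimates in the true tissue.

        ``include_uni`` additionally classifies every (tissue, annotation)
        univariate statistic separately (the classical one-annotation-at-a-
        time scan); its EM over the larger pooled set is markedly slower,
        so it is opt-in."""
        cfg = self.cfg
        n_reps = cfg.n_reps if n_reps is None else n_reps
        # per-setting independent stream keyed by the coefficients, so the
        # settings can be run in any order or subset deterministically
        rng = np.random.default_rng(
            np.random.SeedSequence([self._seed_key(alpha1), self._seed_key(alpha2),
                                    self._base_entropy()]))
        T = cfg.n_tissues
        n_anno = self.annotations[0].n_annotations
        pp_joint = np.empty((n_reps, T))
        pp_unimax = np.empty((n_reps, T))
        pp_uni = np.empty((n_reps, T * n_anno))
        truth = np.empty(n_reps, dtype=np.int64)
        alpha_hats = np.empty((n_reps, 1 + n_anno))
        alpha_star = (cfg.alpha0, alpha1, alpha2)
        for r in range(n_reps):
            t_true = int(rng.integers(T))
            truth[r] = t_true
            _, y = simulate_effects_phenotype(
                self.X, self.annotations[t_true], alpha_star, cfg.sigma_e2, rng)
            _, chisq = marginal_scan(self.X, y)
            ss = SummaryStats(self.snp_id, chisq, cfg.n)
            wald_joint = np.empty(T)
            wald_uni = np.empty(T * n_anno)
            for t in range(T):
                fit = self._joint[t].fit(ss)
                wald_joint[t] = fit.wald
                if t == t_true:
                    alpha_hats[r] = fit.alpha_star_hat
                wald_uni[t * n_anno:(t + 1) * n_anno] = [
                    s.fit(ss).wald for s in self._uni[t]]
            wald_unimax = wald_uni.reshape(T, n_anno).max(axis=1)
            em_seed = int(rng.integers(2 ** 31))
            pp_joint[r] = em_fit(wald_joint, df=2, seed=em_seed).pp
            pp_unimax[r] = em_fit(wald_unimax, df=1, seed=em_seed).pp
            if include_uni:
                pp_uni[r] = em_fit(wald_uni, df=1, seed=em_seed).pp
        out = {
            "pp_smart": pp_joint,
            "pp_unimax": pp_unimax,
            "truth": truth,
            "alpha_hats": alpha_hats,
            "power_smart": evaluate_power_at_fdr(pp_joint, truth, cfg.fdr_levels),
            "power_unimax": evaluate_power_at_fdr(pp_unimax, truth, cfg.fdr_levels),
        }
        if include_uni:
            col_tissue = np.repeat(np.arange(T), n_anno)
            out["pp_uni"] = pp_uni
            out["power_uni"] = evaluate_power_at_fdr(pp_uni, truth, cfg.fdr_levels,
                                                     col_tissue=col_tissue)
        return out

    def _seed_key(self, x: float) -> int:
        return int(np.array(x, dtype=np.float64).view(np.uint64) % (2 ** 31))

    def _base_entropy(self) -> int:
        ent = self._ss_rep.entropy
        ent = ent[0] if isinstance(ent, (list, tuple)) else ent
        return int(ent % (2 ** 31))


def run_design1(
    cfg: Design1Config = Design1Config(),
    seed: int = 0,
    settings: Sequence[tuple] | None = None,
    n_reps: int | None = None,
    include_uni: bool = True,
) -> pd.DataFrame:
    """Power table over (alpha1, alpha2) settings for SMART, UniMax and Uni."""
    runner = Design1Runner(cfg, seed)
    if settings is None:
        settings = [(a1, a2) for a1 in cfg.coef_grid for a2 in cfg.coef_grid]
    rows = []
    for a1, a2 in settings:
        res = runner.run_setting(a1, a2, n_reps, include_uni=include_uni)
        row = {"alpha1": a1, "alpha2": a2}
        for lvl in cfg.fdr_levels:
            row[f"power_smart_fdr{lvl}"] = res["power_smart"][lvl]
            row[f"power_unimax_fdr{lvl}"] = res["power_unimax"][lvl]
            if include_uni:
                row[f"power_uni_fdr{lvl}"] = res["power_uni"][lvl]
        rows.append(row)
        logger.info("design1 (%s, %s): SMART %.3f UniMax %.3f at FDR 0.1",
                    a1, a2, res["power_smart"].get(0.1, np.nan),
                    res["power_unimax"].get(0.1, np.nan))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# design 2: weighted SNP-set test power
# ---------------------------------------------------------------------------

class Design2Runner:
    """Shared state for design-2 replicates.

    The genotype matrix and the train/test split are fixed across
    replicates (the original reused one real cohort), which lets the
    per-block test kernels G_c' G_c be precomputed once.  Causal blocks,
    causal SNPs, annotations, effects and residuals are redrawn per
    replicate.  ``with_training=True`` additionally standardizes the
    training genotypes and prepares per-tissue GEE machinery so the
    estimated-weight methods (smart/unimax) can run.
    """

    def __init__(self, cfg: Design2Config = Design2Config(), seed: int = 0,
                 with_training: bool = False):
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        s_geno, s_ref, s_split, self._ss_rep = ss.spawn(4)
        ld_spec = ("ar1", cfg.ld_rho, cfg.block_size)
        self.G = simulate_genotypes(cfg.n, cfg.m, cfg.maf_range, ld_spec,
                                    np.random.default_rng(s_geno))
        self.col_mean = self.G.mean(axis=0, dtype=np.float64)
        self.col_sd = self.G.std(axis=0, dtype=np.float64)
        perm = np.random.default_rng(s_split).permutation(cfg.n)
        self.train_idx = perm[: cfg.n_train]
        self.test_idx = perm[cfg.n_train:]
        self.n_blocks = cfg.m // cfg.block_size
        self.blocks = [slice(b * cfg.block_size, (b + 1) * cfg.block_size)
                       for b in range(self.n_blocks)]
        # centered test genotypes and per-block kernels for the SKAT side
        Gt = self.G[self.test_idx].astype(np.float32)
        self.G_test_c = Gt - Gt.mean(axis=0)
        self.kernels = [np.asarray(self.G_test_c[:, sl], dtype=np.float64).T
                        @ np.asarray(self.G_test_c[:, sl], dtype=np.float64)
                        for sl in self.blocks]
        self.with_training = with_training
        if with_training:
            G_ref = simulate_genotypes(cfg.n_ref, cfg.m, cfg.maf_range, ld_spec,
                                       np.random.default_rng(s_ref))
            self.ld = estimate_ld_blocks(G_ref, block_size=cfg.block_size)
            self.X_train, _, _ = standardize_genotypes(self.G[self.train_idx])
            self.snp_id = np.array([f"snp{i}" for i in range(cfg.m)], dtype=object)

    # -- replicate pieces ---------------------------------------------------

    def _draw_causal(self, rng):
        """10 non-adjacent causal blocks and 20% causal SNPs inside each.

        Non-adjacent k-subsets of [0, N) biject onto plain k-subsets of
        [0, N-k+1) via b_i = c_(i) + i, giving a uniform draw without
        rejection."""
        cfg = self.cfg
        k = cfg.n_causal_blocks
        if self.n_blocks - k + 1 < k:
            raise ValueError("not enough blocks for non-adjacent causal blocks")
        picks = np.sort(rng.choice(self.n_blocks - k + 1, k, replace=False))
        blocks = picks + np.arange(k)
        per_block = int(round(cfg.block_size * cfg.causal_frac))
        causal = np.concatenate([
            b * cfg.block_size + rng.choice(cfg.block_size, per_block, replace=False)
            for b in blocks
        ])
        return blocks, np.sort(causal)

    def _standardized_cols(self, idx: np.ndarray) -> np.ndarray:
        cols = self.G[:, idx].astype(np.float64)
        sd = np.where(self.col_sd[idx] == 0, 1.0, self.col_sd[idx])
        return (cols - self.col_mean[idx]) / sd

    def simulate_replicate(self, alpha: tuple, proportions: tuple, rng):
        """One replicate: annotations, effects, phenotype, split pieces."""
        cfg = self.cfg
        blocks, causal = self._draw_causal(rng)
        C1, C2, groups = simulate_causal_annotations(
            cfg.m, causal, proportions, rng, cfg.elevated_mean)
        A = center_annotations(
            build_annotation_matrix([C1, C2], ["anno1", "anno2"], "tissue_true"))
        alpha_star = np.array([cfg.alpha0, alpha[0], alpha[1]])
        sigma2 = A.values @ alpha_star
        mask = np.zeros(cfg.m, dtype=bool)
        mask[causal] = True
        sigma2 = np.where(mask, np.maximum(sigma2, 0.0), 0.0)
        beta = np.zeros(cfg.m)
        beta[causal] = rng.standard_normal(len(causal)) * np.sqrt(sigma2[causal] / cfg.m)
        Xc = self._standardized_cols(causal)
        y = Xc @ beta[causal] + rng.standard_normal(cfg.n) * np.sqrt(cfg.sigma_e2)
        return {
            "blocks": blocks, "causal": causal, "groups": groups,
            "A": A, "alpha_star": alpha_star, "beta": beta, "y": y,
        }

    def _skat_pvalues(self, rep: dict, weights_by_block: dict) -> np.ndarray:
        """Weighted set-test p-values for the causal blocks on the test split."""
        y_test = rep["y"][self.test_idx]
        r = y_test - y_test.mean()
        n_test = len(r)
        k = 1  # intercept-only null
        sigma2_hat = float(r @ r) / (n_test - k)
        S = np.asarray(self.G_test_c.T @ r.astype(self.G_test_c.dtype),
                       dtype=np.float64)
        pvals = np.empty(len(rep["blocks"]))
        for i, b in enumerate(rep["blocks"]):
            sl = self.blocks[b]
            w = weights_by_block[b]
            s = S[sl]
            Q = float(np.sum(w * s ** 2))
            sw = np.sqrt(w)
            K = sw[:, None] * self.kernels[b] * sw[None, :]
            xi = np.linalg.eigvalsh(sigma2_hat * (K + K.T) / 2.0)
            xi = xi[xi > 1e-10 * max(xi[-1], 1e-300)]
            if len(xi) == 0:
                pvals[i] = 1.0
                continue
            pvals[i], _ = tail_pvalue(Q, xi)
        return pvals

    def _train_weights(self, rep: dict, mode: str, rng) -> dict:
        """Estimated weights: fit the GEE per tissue on the training split,
        classify tissues by the mixture EM, and build PP-shrunk weights from
        the top tissue's coefficients (mode 'smart' joint, 'unimax' best
        single annotation)."""
        cfg = self.cfg
        y_train = rep["y"][self.train_idx]
        _, chisq = marginal_scan(self.X_train, y_train)
        ss = SummaryStats(self.snp_id, chisq, len(self.train_idx))
        tissues = [rep["A"]]
        for t in range(1, cfg.n_tissues):  # irrelevant tissues: pure-noise annotations
            C1 = rng.standard_normal(cfg.m)
            C2 = rng.standard_normal(cfg.m)
            tissues.append(center_annotations(
                build_annotation_matrix([C1, C2], ["anno1", "anno2"], f"tissue{t}")))
        walds, fits = [], []
        for A in tissues:
            if mode == "smart":
                fit = GEESolver(build_design(self.ld, A, ss.n), self.ld,
                                cfg.working).fit(ss)
            else:
                best = None
                for kk in range(2):
                    sub = AnnotationMatrix(A.values[:, [0, kk + 1]],
                                           [A.column_labels[kk]], centered=True)
                    f = GEESolver(build_design(self.ld, sub, ss.n), self.ld,
                                  cfg.working).fit(ss)
                    if best is None or f.wald > best[0].wald:
                        best = (f, kk)
                fit = best
            walds.append(fit.wald if mode == "smart" else fit[0].wald)
            fits.append(fit)
        mix = em_fit(np.asarray(walds), df=2 if mode == "smart" else 1,
                     seed=int(rng.integers(2 ** 31)))
        top = int(np.argmax(mix.pp))
        pp = float(mix.pp[top])
        A_top = tissues[top]
        if mode == "smart":
            sigma2 = A_top.values @ fits[top].alpha_star_hat
        else:
            f, kk = fits[top]
            sigma2 = A_top.values[:, [0, kk + 1]] @ f.alpha_star_hat
        return {b: construct_weights(sigma2[self.blocks[b]], pp).weights
                for b in rep["blocks"]}

    def weights_for(self, rep: dict, method: str, rng=None) -> dict:
        cfg = self.cfg
        if method == "equal":
            return {b: np.ones(cfg.block_size) for b in rep["blocks"]}
        if method == "oracle":
            sigma2 = rep["A"].values @ rep["alpha_star"]
            return {b: construct_weights(sigma2[self.blocks[b]], 1.0).weights
                    for b in rep["blocks"]}
        if method in ("smart", "unimax"):
            if not self.with_training:
                raise ValueError("runner built without training support")
            return self._train_weights(rep, method, rng)
        raise ValueError(f"unknown weighting method {method!r}")

    def run_setting(self, alpha: tuple, proportions: tuple,
                    n_reps: int | None = None,
                    methods: Sequence[str] = ("equal", "oracle")):
        """Power (fraction of causal blocks at p < threshold) per method,
        plus per-replicate causal-block PVEs."""
        cfg = self.cfg
        n_reps = cfg.n_reps if n_reps is None else n_reps
        rng = np.random.default_rng(np.random.SeedSequence(
            [self._key(alpha), self._key(proportions),
             int(self._ss_rep.entropy % (2 ** 31))]))
        power = {meth: np.empty(n_reps) for meth in methods}
        pve = np.empty((n_reps, cfg.n_causal_blocks))
        for r in range(n_reps):
            rep = self.simulate_replicate(alpha, proportions, rng)
            causal_slices = [self.blocks[b] for b in rep["blocks"]]
            pve[r] = per_block_pve(rep["beta"], self._pve_matrix(rep), causal_slices,
                                   rep["y"])
            for meth in methods:
                w = self.weights_for(rep, meth, rng)
                p = self._skat_pvalues(rep, w)
                power[meth][r] = float(np.mean(p < cfg.sig_threshold))
        out = {f"power_{m}": float(v.mean()) for m, v in power.items()}
        out["power_per_rep"] = power
        out["pve"] = pve
        return out

    def _pve_matrix(self, rep):
        # standardized causal columns embedded back for per-block variance
        class _Cols:
            def __init__(self, runner, causal):
                self.runner = runner
                self.causal = causal

            def __getitem__(self, key):
                _, idx = key
                return self.runner._standardized_cols(np.asarray(idx))

        return _Cols(self, rep["causal"])

    def _key(self, vals) -> int:
        arr = np.atleast_1d(np.asarray(vals, dtype=np.float64))
        return int(np.sum(arr.view(np.uint64) % (2 ** 20)) % (2 ** 31))


def run_design2(
    cfg: Design2Config = Design2Config(),
    seed: int = 0,
    methods: Sequence[str] = ("equal", "oracle"),
    n_reps: int | None = None,
) -> pd.DataFrame:
    """Power table over the coefficient x group-proportion settings."""
    with_training = any(m in ("smart", "unimax") for m in methods)
    runner = Design2Runner(cfg, seed, with_training=with_training)
    rows = []
    for alpha in cfg.coef_settings:
        for props in cfg.group_proportions:
            res = runner.run_setting(alpha, props, n_reps, methods)
            row = {"alpha1": alpha[0], "alpha2": alpha[1],
                   "prop_shared": props[2]}
            for m in methods:
                row[f"power_{m}"] = res[f"power_{m}"]
            row["min_block_pve"] = float(res["pve"].mean(axis=0).min())
            rows.append(row)
            logger.info("design2 alpha=%s props=%s: %s", alpha, props,
                        {m: row[f"power_{m}"] for m in methods})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# null calibration of the weighted set test
# ---------------------------------------------------------------------------

def skat_null_calibration(
    n_reps: int = 5000,
    n: int = 1000,
    p: int = 100,
    maf_range: tuple = (0.05, 0.5),
    ld: tuple = ("ar1", 0.8, 100),
    weights: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Null p-values of the weighted set test: one fixed genotype block,
    phenotypes redrawn as pure noise each replicate (no causal SNPs)."""
    ss = np.random.SeedSequence(seed)
    s_geno, s_y = ss.spawn(2)
    G = simulate_genotypes(n, p, maf_range, ld, np.random.default_rng(s_geno))
    Gc = G.astype(np.float64) - G.mean(axis=0)
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=np.float64)
    sw = np.sqrt(w)
    K = sw[:, None] * (Gc.T @ Gc) * sw[None, :]
    xi0 = np.linalg.eigvalsh((K + K.T) / 2.0)
    xi0 = xi0[xi0 > 1e-10 * xi0[-1]]
    rng = np.random.default_rng(s_y)
    pvals = np.empty(n_reps)
    for i in range(n_reps):
        y = rng.standard_normal(n)
        r = y - y.mean()
        sigma2_hat = float(r @ r) / (n - 1)
        s = Gc.T @ r
        Q = float(np.sum(w * s ** 2))
        pvals[i], _ = tail_pvalue(Q, sigma2_hat * xi0)
    return pvals
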