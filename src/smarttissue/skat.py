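"""Annotation-weighted sequence kernel association test (SKAT).

The annotation-dependent variance model assigns SNP j the effect-size
variance sigma_j^2 = A_j' alpha*.  Fitted in the top trait-relevant tissue,
sigma_hat_j^2 is a natural per-SNP weight for a SKAT-style set test in a
new cohort: SNPs predicted to carry larger effects are up-weighted.  The
weights are shrunk toward equal weights by the tissue's posterior
probability PP, so an uncertain tissue call degrades gracefully to the
unweighted test:

    v_j = sigma_hat_j^2 - min_k sigma_hat_k^2 + 1e-15
    w_j = PP * v_j + (1 - PP)

The test statistic for a gene's genotype block G (columns centered) is
Q = r' G W G' r with null-model residuals r and W = diag(w); its null
distribution is a weighted sum of chi-square(1) variables whose weights are
the eigenvalues of the projected weighted kernel.  Tail probabilities use
numerical inversion of the characteristic function (Imhof/Davies) in the
bulk, a Lugannani-Rice saddlepoint approximation in the far tail, and Liu
moment matching as the fallback.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, optimize, stats

from .annotations import AnnotationMatrix, SnpTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "SNPWeights",
    "NullModel",
    "SKATResult",
    "snp_variances",
    "construct_weights",
    "fit_null_model",
    "skat_test",
    "assemble_gene_sets",
    "liu_pvalue",
    "davies_pvalue",
    "saddlepoint_pvalue",
    "tail_pvalue",
]

#: eigenvalues below this fraction of the largest are dropped from the tail sum
EIG_REL_TOL = 1e-10
#: the small constant added so all weights are strictly positive
WEIGHT_FLOOR = 1e-15


@dataclass(frozen=True)
class GeneSet:
    gene_id: str
    chrom: str
    window_start: int  # 1-based inclusive, after +-10 kb extension
    window_end: int
    snp_indices: np.ndarray


@dataclass(frozen=True)
class SNPWeights:
    sigma2: np.ndarray
    weights: np.ndarray
    pp_used: float

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.weights) <= 0):
            raise ValueError("all SNP weights must be > 0")


@dataclass(frozen=True)
class NullModel:
    family: str
    mu: np.ndarray
    residuals: np.ndarray
    covariates: np.ndarray
    #: residual variance (quantitative) — None for binary
    sigma2: float | None
    #: per-sample working variances mu(1-mu) (binary) — None for quantitative
    var_weights: np.ndarray | None


@dataclass(frozen=True)
class SKATResult:
    gene_id: str
    n_snps: int
    Q: float
    pvalue: float
    method: str = "davies"
    flag: str = ""


def snp_variances(A: AnnotationMatrix, alpha_star_hat: np.ndarray,
                  rows: np.ndarray | None = None) -> np.ndarray:
    """Model SNP-specific variances sigma_hat_j^2 = A_j' alpha_star_hat.

    ``A`` must be centered with the same genome-wide statistics used when
    fitting the coefficients; ``rows`` restricts to a gene's SNPs.  Values
    may be negative — the weight transformation handles that.
    """
    alpha = np.asarray(alpha_star_hat, dtype=np.float64)
    if alpha.shape[0] != A.values.shape[1]:
        raise ValueError(
            f"coefficient vector of length {alpha.shape[0]} does not match "
            f"annotation matrix with {A.values.shape[1]} columns"
        )
    V = A.values if rows is None else A.values[rows]
    return V @ alpha


def construct_weights(sigma2: np.ndarray, pp: float) -> SNPWeights:
    """PP-averaged SNP weights from model variances (shift-positivize, blend)."""
    sigma2 = np.asarray(sigma2, dtype=np.float64)
    if len(sigma2) < 1:
        raise ValueError("need at least one SNP")
    if not 0.0 <= pp <= 1.0:
        raise ValueError(f"posterior probability must lie in [0, 1], got {pp}")
    v = sigma2 - sigma2.min() + WEIGHT_FLOOR
    w = pp * v + (1.0 - pp)
    return SNPWeights(sigma2, w, pp)


def fit_null_model(y: np.ndarray, covariates: np.ndarray | None = None,
                   family: str = "quantitative") -> NullModel:
    """Null model of phenotype on covariates only (intercept always included)."""
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    X = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=np.float64)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    if family == "quantitative":
        fit = sm.OLS(y, X).fit()
        resid = y - fit.fittedvalues
        sigma2 = float(resid @ resid / (n - X.shape[1]))
        return NullModel(family, fit.fittedvalues, resid, X, sigma2, None)
    if family == "binary":
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])) or len(uniq) < 2:
            raise ValueError("binary family requires a 0/1 phenotype with both classes")
        glm = sm.GLM(y, X, family=sm.families.Binomial())
        fit = glm.fit()
        mu = np.asarray(fit.fittedvalues)
        if np.any(mu < 1e-10) or np.any(mu > 1 - 1e-10):
            raise ValueError(
                "fitted probabilities at 0/1 indicate (quasi-)separation; "
                "remove or recode the offending covariate"
            )
        return NullModel(family, mu, y - mu, X, None, mu * (1.0 - mu))
    raise ValueError(f"unknown family {family!r}")


def _null_eigenvalues(Gc: np.ndarray, w: np.ndarray, nm: NullModel) -> np.ndarray:
    """Eigenvalues xi_k of the null distribution sum_k xi_k chi2_1 of Q."""
    X = nm.covariates
    if nm.family == "quantitative":
        # P = sigma2 * (I - X (X'X)^-1 X')
        XtG = X.T @ Gc
        PG = Gc - X @ np.linalg.solve(X.T @ X, XtG)
        K = nm.sigma2 * (Gc.T @ PG)
    else:
        V = nm.var_weights
        VG = Gc * V[:, None]
        VX = X * V[:, None]
        K = Gc.T @ VG - (VG.T @ X) @ np.linalg.solve(X.T @ VX, VX.T @ Gc)
    sw = np.sqrt(w)
    K = sw[:, None] * K * sw[None, :]
    xi = np.linalg.eigvalsh((K + K.T) / 2.0)
    if len(xi) == 0 or xi[-1] <= 0:
        return np.array([])
    return xi[xi > EIG_REL_TOL * xi[-1]]


def davies_pvalue(q: float, xi: np.ndarray) -> tuple[float, bool]:
    """P(sum xi_k chi2_1 > q) by numerical inversion of the characteristic
    function (Imhof's integral).  Returns (p, ok).

    The integrand envelope decays like u^(-1-K/2) for K eigenvalues, so the
    quadrature is reliable for K >= 3; with fewer eigenvalues the caller's
    moment-matching fallback is reported instead (exact for K = 1).
    """
    xi = np.asarray(xi, dtype=np.float64)
    if len(xi) < 3:
        return np.nan, False

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(xi * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((xi * u) ** 2)))
        return np.sin(theta) / (u * rho)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", integrate.IntegrationWarning)
            val, err = integrate.quad(integrand, 0.0, np.inf, limit=300,
                                      epsabs=1e-13, epsrel=1e-10)
    except (integrate.IntegrationWarning, Exception):  # noqa: BLE001
        return np.nan, False
    p = 0.5 + val / np.pi
    if not np.isfinite(p) or err > 1e-6:
        return np.nan, False
    return float(min(max(p, 0.0), 1.0)), True


def saddlepoint_pvalue(q: float, xi: np.ndarray) -> tuple[float, bool]:
    """Lugannani-Rice saddlepoint tail probability for sum xi_k chi2_1.

    Highly accurate deep in the right tail, where the oscillatory Imhof
    integral becomes numerically treacherous.  Returns (p, ok); fails near
    the distribution mean where the saddlepoint degenerates (t ~ 0).
    """
    xi = np.asarray(xi, dtype=np.float64)
    mean = float(xi.sum())
    tmax = 1.0 / (2.0 * xi.max())

    def kprime(t):
        return float(np.sum(xi / (1.0 - 2.0 * t * xi)))

    lo, hi = -1.0, tmax * (1.0 - 1e-12)
    while kprime(lo) > q:
        lo *= 8.0
        if lo < -1e12:
            return np.nan, False
    try:
        t = optimize.brentq(lambda t: kprime(t) - q, lo, hi, xtol=1e-14)
    except ValueError:
        return np.nan, False
    if abs(t) < 1e-8 * (1.0 + abs(q)):
        return np.nan, False  # q too close to the mean for the expansion
    K = -0.5 * float(np.sum(np.log1p(-2.0 * t * xi)))
    Kpp = float(np.sum(2.0 * xi ** 2 / (1.0 - 2.0 * t * xi) ** 2))
    w = np.sign(t) * np.sqrt(max(2.0 * (t * q - K), 0.0))
    v = t * np.sqrt(Kpp)
    if w == 0.0 or v == 0.0:
        return np.nan, False
    p = float(stats.norm.sf(w + np.log(v / w) / w))
    return p, np.isfinite(p)


def tail_pvalue(q: float, xi: np.ndarray) -> tuple[float, str]:
    """P(sum xi_k chi2_1 > q): Davies/Imhof inversion in the bulk, the
    saddlepoint in the far tail (where the inversion integrand oscillates at
    frequency ~q and defeats adaptive quadrature), Liu moment matching as
    the last resort.  Returns (p, method)."""
    p_liu = liu_pvalue(q, xi)
    if p_liu >= 1e-3:
        p, ok = davies_pvalue(q, xi)
        if ok and p > 0.0:
            return p, "davies"
        return p_liu, "liu"
    p, ok = saddlepoint_pvalue(q, xi)
    if ok and 0.0 < p <= 1.0:
        return p, "saddlepoint"
    return p_liu, "liu"


def liu_pvalue(q: float, xi: np.ndarray) -> float:
    """Moment-matching (Liu et al.) noncentral chi-square approximation."""
    c1, c2, c3, c4 = (np.sum(xi ** k) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        ell = a ** 2 - 2.0 * delta
    else:
        delta = 0.0
        ell = c2 ** 3 / c3 ** 2 if c3 > 0 else 1.0 / s2
    t = (q - c1) / np.sqrt(2.0 * c2)
    x = t * np.sqrt(2.0 * (ell + 2.0 * delta)) + (ell + delta)
    if x < 0:
        return 1.0
    if delta > 0:
        return float(stats.ncx2.sf(x, ell, delta))
    return float(stats.chi2.sf(x, ell))


def skat_test(G: np.ndarray, weights: SNPWeights | np.ndarray, nm: NullModel,
              gene_id: str = "") -> SKATResult:
    """Weighted kernel set test of a genotype block against the null model.

    Genotype columns are centered by their sample mean (common-variant
    kernel; the annotation weights replace SKAT's MAF-beta weights).
    """
    G = np.asarray(G, dtype=np.float64)
    w = weights.weights if isinstance(weights, SNPWeights) else np.asarray(weights, float)
    if G.shape[1] != len(w):
        raise ValueError("genotype block and weight vector disagree on SNP count")
    Gc = G - G.mean(axis=0)
    if not np.any(Gc):
        logger.warning("gene %s: all-zero genotype block", gene_id)
        return SKATResult(gene_id, G.shape[1], 0.0, 1.0, flag="zero_genotypes")
    r = nm.residuals
    s = Gc.T @ r
    Q = float(np.sum(w * s ** 2))
    xi = _null_eigenvalues(Gc, w, nm)
    if len(xi) == 0:
        return SKATResult(gene_id, G.shape[1], Q, 1.0, flag="null_kernel")
    p, method = tail_pvalue(Q, xi)
    p = float(min(max(p, np.finfo(float).tiny), 1.0))
    return SKATResult(gene_id, G.shape[1], Q, p, method=method)


def assemble_gene_sets(
    genes: pd.DataFrame,
    snps: SnpTable,
    window: int = 10_000,
    min_snps: int = 10,
    stranded: bool = False,
    window_down: int | None = None,
) -> list[GeneSet]:
    """Map SNPs to genes extended by ``window`` bp on both sides.

    Gene rows need gene_id, chrom, start, end (1-based, start <= end) and
    optionally strand.  Unstranded windows are [start - w, end + w],
    boundaries inclusive.  ``stranded=True`` applies ``window`` upstream of
    the TSS and ``window_down`` (default: ``window``) downstream of the TES
    by strand — distinguishable from the unstranded rule only when the two
    extensions differ.  Genes with fewer than ``min_snps`` SNPs in the
    window are dropped.
    """
    w_up = window
    w_down = window if window_down is None else window_down
    out = []
    n_dropped, n_malformed = 0, 0
    for _, row in genes.iterrows():
        try:
            gene_id = str(row["gene_id"])
            chrom = str(row["chrom"])
            start, end = int(row["start"]), int(row["end"])
            if start > end:
                raise ValueError("start > end")
        except (KeyError, ValueError, TypeError):
            n_malformed += 1
            logger.warning("skipping malformed gene row: %s", dict(row))
            continue
        if stranded and str(row.get("strand", "+")) == "-":
            lo, hi = start - w_down, end + w_up  # TSS at `end` on the minus strand
        else:
            lo, hi = start - w_up, end + w_down
        mask = (snps.chrom == chrom) & (snps.pos >= lo) & (snps.pos <= hi)
        idx = np.flatnonzero(mask)
        if len(idx) < min_snps:
            n_dropped += 1
            continue
        out.append(GeneSet(gene_id, chrom, lo, hi, idx))
    logger.info("assembled %d gene sets (%d dropped with < %d SNPs, %d malformed)",
                len(out), n_dropped, min_snps, n_malformed)
    return out


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Family-wise significance threshold alpha / #genes."""
    return alpha / n_genes
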