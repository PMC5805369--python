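"""Two-component noncentral chi-square mixture over per-tissue Wald statistics.

Across candidate tissues, Wald statistics from trait-irrelevant tissues are
inflated above the theoretical central chi-square null because the same
annotation is highly correlated across tissues; statistics from
trait-relevant tissues are inflated further.  Both groups are therefore
modeled as noncentral chi-square with the same degrees of freedom c (the
number of annotations fitted) but different noncentrality: lambda_0 for the
empirical null and lambda_1 > lambda_0 for the trait-relevant component,
with mixing proportion pi on the alternative.  EM yields the parameters and,
per tissue, the posterior probability (PP) of trait relevance — turning
tissue identification into a classification problem rather than a test
against a misspecified theoretical null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

logger = logging.getLogger(__name__)

__all__ = ["MixtureFit", "ncchisq_density", "em_fit", "classify"]

#: relative log-likelihood convergence tolerance of the EM iteration
EM_TOL = 1e-8
#: iteration cap per EM start
EM_MAX_ITER = 1000
#: number of jittered restarts; the best final log-likelihood is kept
EM_RESTARTS = 10

_EPS = 1e-300


def _log_density(x: np.ndarray, df: float, lam: float) -> np.ndarray:
    """Log noncentral chi-square density in the stable Bessel form.

    f(x; k, lam) = 1/2 exp(-(sqrt(x)-sqrt(lam))^2 / 2)
                   (x/lam)^(k/4 - 1/2) ive(k/2 - 1, sqrt(lam x))
    with the exponentially scaled Bessel function ive; at lam = 0 the
    central chi-square closed form is used.
    """
    x = np.maximum(x, _EPS)
    k2 = df / 2.0
    if lam < 1e-12:
        return (k2 - 1.0) * np.log(x) - x / 2.0 - k2 * np.log(2.0) - special.gammaln(k2)
    v = k2 - 1.0
    sq = np.sqrt(lam * x)
    bessel = np.maximum(special.ive(v, sq), _EPS)
    return (-np.log(2.0)
            - 0.5 * (np.sqrt(x) - np.sqrt(lam)) ** 2
            + (v / 2.0) * np.log(x / lam)
            + np.log(bessel))


def ncchisq_density(x, df: int, lam: float):
    """Noncentral chi-square density, stable at lam = 0 (central limit case)."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("noncentral chi-square density requires x >= 0")
    if df <= 0:
        raise ValueError("df must be a positive integer")
    if lam < 0:
        raise ValueError("noncentrality must be >= 0")
    out = np.exp(_log_density(x, df, lam))
    # the density diverges at x = 0 for df < 2 and is finite only via the
    # central closed form at exactly x = 0, df = 2
    return out if out.ndim else float(out)


@dataclass
class MixtureFit:
    df: int
    lambda0: float
    lambda1: float
    pi: float
    loglik: float
    pp: np.ndarray
    converged: bool
    n_iter: int
    degenerate: bool = False
    #: log-likelihood trace of the winning EM start (non-decreasing)
    loglik_trace: np.ndarray | None = None


def _loglik_and_pp(w, df, lam0, lam1, pi):
    l0 = _log_density(w, df, lam0) + np.log(max(1.0 - pi, _EPS))
    l1 = _log_density(w, df, lam1) + np.log(max(pi, _EPS))
    mx = np.maximum(l0, l1)
    lse = mx + np.log(np.exp(l0 - mx) + np.exp(l1 - mx))
    ll = float(np.sum(lse))
    pp = np.exp(l1 - lse)
    return ll, pp


def _weighted_lambda_mle(w, df, g, lam_start):
    """Maximize sum_j g_j log f(w_j; df, lambda) over lambda >= 0."""
    if g.sum() <= 0:
        return lam_start

    def neg(lam):
        return -float(g @ _log_density(w, df, max(lam, 0.0)))

    hi = max(2.0 * lam_start + 10.0, float(w.max()))
    res = optimize.minimize_scalar(neg, bounds=(0.0, hi), method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x)


def _em_single(w, df, lam0, lam1, pi, tol, max_iter):
    """One EM run.  M-step uses the closed-form moment-matching update
    lambda_k = max(0, weighted mean of (w - df)); if that update would
    decrease the observed log-likelihood, the lambdas are instead refined by
    a bounded 1-d maximization of the weighted component log-likelihood,
    which restores the EM ascent property."""
    ll, pp = _loglik_and_pp(w, df, lam0, lam1, pi)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g1 = pp
        g0 = 1.0 - pp
        pi_new = float(np.mean(g1))
        # moment matching: E[w] = df + lambda within each component
        lam0_new = max(0.0, float(g0 @ (w - df) / g0.sum())) if g0.sum() > 0 else lam0
        lam1_new = max(0.0, float(g1 @ (w - df) / g1.sum())) if g1.sum() > 0 else lam1
        ll_new, pp_new = _loglik_and_pp(w, df, lam0_new, lam1_new, pi_new)
        if ll_new < ll - 1e-12 * max(1.0, abs(ll)):
            lam0_new = _weighted_lambda_mle(w, df, g0, lam0)
            lam1_new = _weighted_lambda_mle(w, df, g1, lam1)
            ll_new, pp_new = _loglik_and_pp(w, df, lam0_new, lam1_new, pi_new)
            if ll_new < ll:  # numeric refinement cannot improve either: stop
                break
        lam0, lam1, pi, pp = lam0_new, lam1_new, pi_new, pp_new
        trace.append(ll_new)
        if abs(ll_new - ll) < tol * max(1.0, abs(ll)):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    # relabel so that component 1 is the high-noncentrality component
    if lam1 < lam0:
        lam0, lam1 = lam1, lam0
        pi = 1.0 - pi
        _, pp = _loglik_and_pp(w, df, lam0, lam1, pi)
    return lam0, lam1, pi, ll, pp, converged, it, np.asarray(trace)


def em_fit(
    wald_stats,
    df: int,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
    n_restarts: int = EM_RESTARTS,
    seed: int | None = 0,
) -> MixtureFit:
    """Fit the two-component noncentral chi-square mixture by EM.

    Initialization: lambda_0 = max(0, median(w) - df),
    lambda_1 = max(lambda_0 + 1, max(w) - df), pi = 0.2, with jittered
    restarts; the start with the best final log-likelihood wins.  A sample
    with no separation (all statistics effectively equal) returns a flagged
    degenerate fit with pp == pi rather than raising.
    """
    w = np.asarray(wald_stats, dtype=np.float64)
    if len(w) < 2:
        raise ValueError("mixture fit needs at least 2 statistics")
    if np.any(~np.isfinite(w)) or np.any(w < 0):
        raise ValueError("Wald statistics must be finite and >= 0")
    rng = np.random.default_rng(seed)

    if np.ptp(w) < 1e-12:
        lam = max(0.0, float(w[0]) - df)
        pi = 0.5
        ll, _ = _loglik_and_pp(w, df, lam, lam, pi)
        logger.warning("all statistics identical: degenerate mixture fit")
        return MixtureFit(df, lam, lam, pi, ll, np.full(len(w), pi), True, 0,
                          degenerate=True, loglik_trace=np.array([ll]))

    lam0_init = max(0.0, float(np.median(w)) - df)
    lam1_init = max(lam0_init + 1.0, float(np.max(w)) - df)
    best = None
    for r in range(n_restarts):
        if r == 0:
            lam0, lam1, pi = lam0_init, lam1_init, 0.2
        else:
            lam0 = lam0_init * rng.uniform(0.5, 1.5) + rng.uniform(0, 1)
            lam1 = max(lam0 + 1.0, lam1_init * rng.uniform(0.5, 1.5))
            pi = rng.uniform(0.05, 0.5)
        result = _em_single(w, df, lam0, lam1, pi, tol, max_iter)
        if best is None or result[3] > best[3]:
            best = result
    lam0, lam1, pi, ll, pp, converged, n_iter, trace = best
    degenerate = abs(lam1 - lam0) < 1e-9
    if degenerate:
        logger.info("mixture collapsed to a single component (lambda0 == lambda1)")
    return MixtureFit(df, lam0, lam1, pi, ll, pp, converged, n_iter,
                      degenerate=degenerate, loglik_trace=trace)


def classify(fit: MixtureFit, tissues=None, threshold: float = 0.5) -> dict:
    """Trait-relevant tissues: PP above threshold, plus the argmax 'top tissue'."""
    pp = np.asarray(fit.pp)
    if tissues is None:
        tissues = [f"tissue{i}" for i in range(len(pp))]
    tissues = list(tissues)
    relevant = [t for t, p in zip(tissues, pp) if p > threshold]
    top = int(np.argmax(pp))
    return {
        "relevant": relevant,
        "top_tissue": tissues[top],
        "top_pp": float(pp[top]),
        "pp": dict(zip(tissues, pp.tolist())),
    }
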