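"""Phylogenetic signal statistics and their null distributions.

Implements Blomberg's K — the ratio of the observed to the Brownian-expected
partitioning of trait variance on a tree — in its plain form and with
within-species measurement error folded in (per-tip standard errors enter as
an extra diagonal variance whose scale relative to the Brownian rate σ² is
estimated by maximum likelihood). Pagel's λ is estimated by maximizing the
profile likelihood of the λ-transformed covariance and tested against λ = 0
with a 1-df likelihood ratio. Significance of K against the no-signal null
uses tip permutation; departure from the Brownian expectation (K = 1) uses a
simulation null of BM traits on the same tree, classified by the 2.5%/97.5%
quantiles of log simulated K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve, get_lapack_funcs
from statsmodels.stats.multitest import multipletests

from .tree import (
    Phylogeny,
    PhyloCovariance,
    lambda_max,
    lambda_transform,
    phylo_covariance,
    simulate_bm,
)

__all__ = [
    "KResult",
    "LambdaResult",
    "SignalDecision",
    "phylo_mean",
    "blomberg_k",
    "blomberg_k_with_se",
    "permutation_test_k",
    "bm_simulation_test",
    "pagel_lambda_ml",
    "bh_adjust",
    "holm_adjust",
    "dual_decision",
]


@dataclass
class KResult:
    """Blomberg's K and the pieces it is built from.

    ``expected_ratio`` is the Brownian expectation of MSE0/MSE on this tree,
    so K = (MSE0/MSE)/expected_ratio equals 1 under BM on average.
    Null-test fields are populated by the permutation and simulation tests.
    """

    K: float
    MSE0: float
    MSE: float
    expected_ratio: float
    a_hat: float
    sigma2_hat: float | None = None
    p_perm: float | None = None
    p_perm_adj: float | None = None
    p_sim: float | None = None
    sim_q025: float | None = None
    sim_q975: float | None = None
    bm_class: str | None = None


@dataclass
class LambdaResult:
    """Pagel's λ maximum-likelihood fit and likelihood-ratio test against λ = 0."""

    lam_hat: float
    sigma2_hat: float
    a_hat: float
    logL: float
    logL0: float
    p_lr: float
    p_lr_adj: float | None = None
    lam_max: float = 1.0
    at_upper_bound: bool = False
    flat_likelihood: bool = False


@dataclass
class SignalDecision:
    """Dual-criterion call: signal accepted only when both K and λ are significant."""

    k_significant: bool
    lambda_significant: bool

    @property
    def signal_present(self) -> bool:
        return self.k_significant and self.lambda_significant


def _as_cov(C) -> np.ndarray:
    return C.C if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)


def _chol(C: np.ndarray):
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"covariance matrix not positive definite: {exc}") from exc


def phylo_mean(x, C) -> float:
    """GLS (phylogenetic) mean: â = (1ᵀC⁻¹1)⁻¹ 1ᵀC⁻¹x."""
    Cm = _as_cov(C)
    x = np.asarray(x, dtype=float)
    cf = _chol(Cm)
    one = np.ones(len(x))
    Ci1 = cho_solve(cf, one)
    return float(Ci1 @ x / (one @ Ci1))


def _k_core(x: np.ndarray, Cm: np.ndarray) -> tuple[float, float, float, float, float]:
    n = len(x)
    cf = _chol(Cm)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    d = one @ Ci1
    a = float(Ci1 @ x / d)
    r = x - a
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ cho_solve(cf, r)) / (n - 1)
    er = (np.trace(Cm) - n / d) / (n - 1)
    return (mse0 / mse) / er, mse0, mse, er, a


def _k_batch(X: np.ndarray, Cm: np.ndarray) -> np.ndarray:
    """Plain K for each column of X (n × m) under covariance Cm; vectorized."""
    n = X.shape[0]
    cf = _chol(Cm)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    d = one @ Ci1
    er = (np.trace(Cm) - n / d) / (n - 1)
    a = (Ci1 @ X) / d
    R = X - a
    mse0 = np.einsum("ij,ij->j", R, R)
    mse = np.einsum("ij,ij->j", R, cho_solve(cf, R))
    return (mse0 / mse) / er


def blomberg_k(x, C) -> KResult:
    """Blomberg's K of one trait vector under phylogenetic covariance C.

    K = (MSE0/MSE) / E[MSE0/MSE | BM], where MSE0 is the variance of tip
    values about the GLS mean under an identity structure and MSE the
    generalized variance under C. Scale- and shift-invariant in the trait.
    """
    Cm = _as_cov(C)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("Blomberg's K needs at least 3 taxa")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant: K is undefined (0/0)")
    K, mse0, mse, er, a = _k_core(x, Cm)
    return KResult(K=K, MSE0=mse0, MSE=mse, expected_ratio=er, a_hat=a)


_potrf, _potrs = get_lapack_funcs(("potrf", "potrs"), (np.empty((1, 1)),))
_LN2PI = np.log(2 * np.pi)


def _neg_loglik_sigma2(s2: float, x: np.ndarray, Cm: np.ndarray, d2: np.ndarray) -> float:
    """−logL of N(â·1, s2·C + diag(d2)) with the GLS mean â profiled out."""
    n = len(x)
    V = s2 * Cm
    V[np.diag_indices(n)] += d2
    c, info = _potrf(V, lower=1, overwrite_a=1, clean=0)
    if info != 0:
        return np.inf
    rhs = np.empty((n, 2))
    rhs[:, 0] = 1.0
    rhs[:, 1] = x
    sol, _ = _potrs(c, rhs, lower=1)
    d = sol[:, 0].sum()  # 1'V⁻¹1
    b = x @ sol[:, 0]  # 1'V⁻¹x
    q = x @ sol[:, 1]  # x'V⁻¹x
    logdet = 2.0 * np.sum(np.log(np.diagonal(c)))
    return 0.5 * (n * _LN2PI + logdet + q - b * b / d)


_INVPHI = (np.sqrt(5.0) - 1.0) / 2.0


def _fit_sigma2(x: np.ndarray, Cm: np.ndarray, d2: np.ndarray, xatol_rel: float = 1e-9) -> float:
    """ML Brownian rate σ² of N(â·1, σ²C + diag(se²)) by golden-section search.

    Without measurement error the optimum is exactly r'C⁻¹r/n (the plain GLS
    variance), and adding a diagonal error term can only pull σ̂² downward,
    so the interval (0, r'C⁻¹r/n] brackets the maximum; the likelihood is
    unimodal in σ² there. The search runs on log σ² to ``xatol_rel``
    relative precision.
    """
    n = len(x)
    cf = _chol(Cm)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    a0 = float(Ci1 @ x / (one @ Ci1))
    r = x - a0
    s2_max = float(r @ cho_solve(cf, r)) / n
    lo, hi = np.log(s2_max) - 18.5, np.log(s2_max) + 1e-7  # e^-18.5 ≈ 1e-8 relative floor
    tol = np.log1p(xatol_rel)

    def f(t: float) -> float:
        return _neg_loglik_sigma2(float(np.exp(t)), x, Cm, d2)

    c1 = hi - _INVPHI * (hi - lo)
    c2 = lo + _INVPHI * (hi - lo)
    f1, f2 = f(c1), f(c2)
    while hi - lo > tol:
        if f1 <= f2:
            hi, c2, f2 = c2, c1, f1
            c1 = hi - _INVPHI * (hi - lo)
            f1 = f(c1)
        else:
            lo, c1, f1 = c1, c2, f2
            c2 = lo + _INVPHI * (hi - lo)
            f2 = f(c2)
    t_best = c1 if f1 <= f2 else c2
    if not np.isfinite(min(f1, f2)):
        raise RuntimeError(f"sigma2 likelihood search failed to converge on (0, {s2_max:.3g}]")
    return float(np.exp(t_best))


def blomberg_k_with_se(x, se, C, *, sigma2_xatol_rel: float = 1e-9) -> KResult:
    """Blomberg's K accounting for within-species measurement error.

    The trait is modelled as N(â·1, σ²C + diag(se²)); σ² is estimated by
    maximum likelihood and K is computed with the error-adjusted structure
    C' = C + diag(se²)/σ̂². With all-zero standard errors this reduces
    exactly to the plain K.
    """
    Cm = _as_cov(C)
    x = np.asarray(x, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se < 0):
        raise ValueError("standard errors must be nonnegative")
    if not np.any(se > 0):
        return blomberg_k(x, Cm)
    if np.ptp(x) == 0:
        raise ValueError("trait is constant: K is undefined (0/0)")
    s2 = _fit_sigma2(x, Cm, se**2, xatol_rel=sigma2_xatol_rel)
    Cprime = Cm + np.diag(se**2) / s2
    K, mse0, mse, er, a = _k_core(x, Cprime)
    return KResult(K=K, MSE0=mse0, MSE=mse, expected_ratio=er, a_hat=a, sigma2_hat=s2)


def permutation_test_k(
    x,
    se,
    C,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for K against the no-signal null (H0: K = 0 structure).

    Tip assignments of the (trait, se) pairs are shuffled uniformly
    ``n_perm`` times and K recomputed; the one-tailed add-one estimator
    p = (1 + #{K_perm ≥ K_obs}) / (n_perm + 1) is returned.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Cm = _as_cov(C)
    x = np.asarray(x, dtype=float)
    n = len(x)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    has_se = se is not None and np.any(np.asarray(se, dtype=float) > 0)
    if has_se:
        se = np.asarray(se, dtype=float)
        k_obs = blomberg_k_with_se(x, se, Cm).K
        count = 0
        # per-permutation σ² refits use a relaxed tolerance: a 1e-3 relative
        # error in σ̂² moves K far less than permutation noise moves the null
        for _ in range(n_perm):
            p = rng.permutation(n)
            if blomberg_k_with_se(x[p], se[p], Cm, sigma2_xatol_rel=1e-3).K >= k_obs:
                count += 1
    else:
        k_obs = blomberg_k(x, Cm).K
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        K_perm = _k_batch(x[perms].T, Cm)
        count = int(np.sum(K_perm >= k_obs))
    return (1 + count) / (n_perm + 1)


def bm_simulation_test(
    K_obs: float,
    tree: Phylogeny,
    n_sim: int = 5000,
    seed: int | np.random.Generator = 0,
    se=None,
) -> tuple[float, float, float, str]:
    """Test K against the Brownian-motion expectation (H0: K = 1).

    ``n_sim`` traits are simulated under BM (σ² = 1; K is invariant to the
    rate) on the tree and plain K computed for each. The observed K is
    classified against the 2.5% and 97.5% quantiles of log simulated K as
    ``lower`` / ``consistent`` / ``higher``, and a two-tailed p-value
    p = 2·min(F, 1−F) is formed from the empirical CDF F at log K_obs.
    If per-tip standard errors are supplied, each simulated trait receives
    Gaussian measurement noise and is analysed with the error-adjusted K.

    Returns (p_sim, sim_q025, sim_q975, bm_class) with quantiles on the K scale.
    """
    if K_obs <= 0:
        raise ValueError("K_obs must be positive")
    if n_sim < 100:
        warnings.warn("n_sim < 100: simulated-K quantiles will be unstable", stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = simulate_bm(tree, sigma2=1.0, n_traits=n_sim, seed=rng)
    Cm = phylo_covariance(tree).C
    if se is not None and np.any(np.asarray(se, dtype=float) > 0):
        se = np.asarray(se, dtype=float)
        X = X + rng.standard_normal(X.shape) * se[:, None]
        K_sim = np.array([blomberg_k_with_se(X[:, j], se, Cm).K for j in range(n_sim)])
    else:
        K_sim = _k_batch(X, Cm)
    logK = np.log(K_sim)
    q025, q975 = np.quantile(logK, [0.025, 0.975])
    lk = np.log(K_obs)
    F = float(np.mean(logK <= lk))
    p_sim = min(1.0, 2 * min(F, 1 - F))
    if lk < q025:
        bm_class = "lower"
    elif lk > q975:
        bm_class = "higher"
    else:
        bm_class = "consistent"
    return p_sim, float(np.exp(q025)), float(np.exp(q975)), bm_class


def _lambda_profile_loglik(lam: float, x: np.ndarray, Coff: np.ndarray, Cdiag: np.ndarray):
    """Profile log-likelihood of λ with â and σ² maximized out."""
    n = len(x)
    V = lam * Coff + np.diag(Cdiag)
    try:
        cf = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    one = np.ones(n)
    Vi1 = cho_solve(cf, one)
    a = float(Vi1 @ x / (one @ Vi1))
    r = x - a
    s2 = float(r @ cho_solve(cf, r)) / n
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    logL = -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
    return logL, s2, a


def pagel_lambda_ml(
    x,
    tree: Phylogeny | None = None,
    *,
    cov: PhyloCovariance | None = None,
    lam_max: float | None = None,
    n_grid: int = 25,
    xatol: float = 1e-8,
) -> LambdaResult:
    """Maximum-likelihood Pagel's λ with a likelihood-ratio test against λ = 0.

    λ scales the off-diagonal (shared-history) covariances; the search runs
    over [0, λ_max], where λ_max keeps the transform a valid tree (≥ 1 for
    ultrametric trees with internal structure). A coarse grid pre-scan
    precedes bounded scalar refinement to dodge local optima. When the
    likelihood is flat in λ (e.g. a star tree), the result carries
    ``flat_likelihood=True`` rather than an arbitrary estimate.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("Pagel's lambda needs at least 3 taxa")
    if np.ptp(x) == 0:
        raise ValueError("trait is constant: lambda is undefined")
    if cov is None:
        if tree is None:
            raise ValueError("provide a tree or a covariance")
        cov = phylo_covariance(tree)
    if lam_max is None:
        lam_max = lambda_max(tree) if tree is not None else 1.0
    Cdiag = np.diag(cov.C).copy()
    Coff = cov.C - np.diag(Cdiag)

    def f(lam):
        return _lambda_profile_loglik(lam, x, Coff, Cdiag)[0]

    grid = np.linspace(0.0, lam_max, n_grid)
    vals = np.array([f(l) for l in grid])
    if not np.any(np.isfinite(vals)):
        raise RuntimeError(f"lambda likelihood not finite anywhere on [0, {lam_max}]")
    spread = np.nanmax(vals) - np.nanmin(vals[np.isfinite(vals)])
    logL0, _, _ = _lambda_profile_loglik(0.0, x, Coff, Cdiag)
    if spread < 1e-10 * max(1.0, abs(float(np.nanmax(vals)))):
        # flat in λ: every transform fits equally well (star-tree geometry)
        s2 = _lambda_profile_loglik(0.0, x, Coff, Cdiag)[1]
        a = _lambda_profile_loglik(0.0, x, Coff, Cdiag)[2]
        return LambdaResult(
            lam_hat=np.nan, sigma2_hat=s2, a_hat=a, logL=logL0, logL0=logL0,
            p_lr=1.0, lam_max=lam_max, flat_likelihood=True,
        )
    i = int(np.nanargmax(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    candidates = [(vals[i], grid[i]), (logL0, 0.0), (f(lam_max), lam_max)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda l: -f(l), bounds=(lo, hi), method="bounded", options={"xatol": xatol}
        )
        if np.isfinite(res.fun):
            candidates.append((-res.fun, float(res.x)))
    logL, lam_hat = max(candidates, key=lambda t: t[0])
    _, s2, a = _lambda_profile_loglik(lam_hat, x, Coff, Cdiag)
    lr = max(0.0, 2.0 * (logL - logL0))
    p_lr = float(stats.chi2.sf(lr, df=1)) if lr > 0 else 1.0
    return LambdaResult(
        lam_hat=float(lam_hat),
        sigma2_hat=s2,
        a_hat=a,
        logL=float(logL),
        logL0=float(logL0),
        p_lr=p_lr,
        lam_max=lam_max,
        at_upper_bound=bool(lam_hat >= lam_max - 1e-6),
    )


def _check_pvals(p: np.ndarray) -> None:
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up FDR adjustment, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    _check_pvals(p)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down familywise-error adjustment, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    _check_pvals(p)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def dual_decision(k: KResult, lam: LambdaResult, alpha: float = 0.05) -> SignalDecision:
    """Accept phylogenetic signal only when both adjusted tests are significant.

    Uses strict inequality on the BH-adjusted permutation p of K and the
    BH-adjusted likelihood-ratio p of λ.
    """
    if k.p_perm_adj is None or lam.p_lr_adj is None:
        raise ValueError("adjusted p-values must be computed before the decision")
    return SignalDecision(
        k_significant=bool(k.p_perm_adj < alpha),
        lambda_significant=bool(lam.p_lr_adj < alpha),
    )
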