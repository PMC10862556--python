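"""Pagel's lambda: phylogenetic signal in a continuous tip trait.

Under Brownian-motion evolution the tip trait vector is multivariate normal
with covariance sigma^2 * C, where C_ij is the depth of the most recent
common ancestor of tips i and j.  Pagel's lambda rescales the off-diagonal
of C: lambda = 0 removes all phylogenetic covariance (trait independent of
the tree), lambda = 1 leaves the Brownian structure intact.  The estimate
maximizes the profiled Gaussian likelihood over lambda with the rate and
root state profiled out by generalized least squares; significance against
lambda = 0 comes from a Monte-Carlo permutation of trait values across tips
(or, optionally, a chi-square likelihood-ratio test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .datatypes import Phylogeny


def phylo_covariance(phy: Phylogeny):
    """Brownian tip covariance matrix: MRCA depths; diagonal root-to-tip.

    Returns (C, tip_order).
    """
    tips = phy.tip_names
    depths = phy.depths()
    d = np.array([depths[t] for t in tips])
    dist = phy.tree.tip_tip_distances(endpoints=tips).data
    C = 0.5 * (d[:, None] + d[None, :] - dist)
    np.fill_diagonal(C, d)
    C[C < 0] = 0.0  # round-off guard for unrelated tips
    return C, list(tips)


def lambda_transform(C: np.ndarray, lam: float, lam_max: float | None = None) -> np.ndarray:
    """Multiply off-diagonal phylogenetic covariances by lambda."""
    upper = 1.0 if lam_max is None else lam_max
    if not 0.0 <= lam <= upper + 1e-12:
        raise ValueError(f"lambda {lam} outside [0, {upper}]")
    out = lam * np.asarray(C, dtype=float)
    np.fill_diagonal(out, np.diag(C))
    return out


def _profiled_loglik_chol(L, y):
    """Profiled Gaussian log-likelihood given Cholesky factor L of V(lambda).

    Accepts a single trait vector or an (n, m) matrix of trait columns;
    the root state and rate are profiled out per column.
    """
    Y = np.atleast_2d(np.asarray(y, dtype=float).T).T  # (n, m)
    n = Y.shape[0]
    one = np.ones(n)
    A = solve_triangular(L, Y, lower=True)
    o = solve_triangular(L, one, lower=True)
    oo = float(o @ o)
    mu = (o @ A) / oo
    R = A - np.outer(o, mu)
    s2 = np.einsum("ij,ij->j", R, R) / n
    logdet_half = float(np.sum(np.log(np.diag(L))))
    with np.errstate(divide="ignore"):
        ll = -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0) - logdet_half
    if np.ndim(y) == 1:
        return float(ll[0]), float(mu[0]), float(s2[0])
    return ll


class PagelLambda(BaseEstimator):
    """Maximum-likelihood Pagel's lambda with a Monte-Carlo significance test.

    Parameters
    ----------
    n_sims : int
        Monte-Carlo replicates for the null test (the permutation count);
        p = (1 + exceedances) / (n_sims + 1).
    method : {"permutation", "lr"}
        "permutation" permutes trait values across tips and compares the
        observed likelihood-ratio statistic (maximized on a fixed lambda
        grid for observed and permuted traits alike) against the permuted
        distribution.  "lr" uses the chi-square(1) likelihood-ratio test.
    grid_size : int
        Lambda grid points for the pre-scan and the permutation statistic.
    tol : float
        Bounded 1-D optimizer tolerance for the reported lambda.
    random_state : int or numpy Generator
        Seed for the permutation null; required for reproducibility.

    Attributes
    ----------
    lambda_ : float
        ML estimate (NaN when the likelihood is flat; see `identifiable_`).
    sigma2_, root_state_ : float
        Profiled rate and root state at the optimum.
    log_likelihood_, log_likelihood_0_ : float
        Profiled log-likelihood at the optimum and at lambda = 0.
    p_value_ : float
    lambda_max_ : float
        Upper bound of the search (1 for ultrametric trees; else the
        largest lambda keeping the transformed covariance positive
        definite, found numerically).
    identifiable_ : bool
        False on star-like trees where lambda has no effect.
    """

    def __init__(self, n_sims=999, method="permutation", grid_size=21,
                 tol=1e-6, random_state=None):
        self.n_sims = n_sims
        self.method = method
        self.grid_size = grid_size
        self.tol = tol
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _chol(C, lam):
        V = lambda_transform(C, lam, lam_max=np.inf)
        return cholesky(V, lower=True)

    def _lambda_max(self, C, ultrametric):
        if ultrametric:
            return 1.0
        lo, hi = 1.0, 1.0
        try:
            self._chol(C, 1.0)
        except np.linalg.LinAlgError:
            lo = 0.0
        else:
            while hi < 16.0:
                try:
                    self._chol(C, hi * 2.0)
                except np.linalg.LinAlgError:
                    break
                hi *= 2.0
            else:
                return hi
            lo = hi
            hi = hi * 2.0
        for _ in range(50):
            mid = 0.5 * (lo + hi)
            try:
                self._chol(C, mid)
                lo = mid
            except np.linalg.LinAlgError:
                hi = mid
        return 0.999 * lo

    # -- API ---------------------------------------------------------------

    def fit(self, X, y, ultrametric: bool | None = None):
        """Fit lambda for tip covariance `X` (n x n) and trait vector `y`."""
        C = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = C.shape[0]
        if y.shape != (n,):
            raise ValueError("trait vector length must match covariance size")
        if n < 4:
            raise ValueError("need at least 4 tips")
        if np.std(y) == 0:
            raise ValueError("constant trait: signal undefined")
        if ultrametric is None:
            d = np.diag(C)
            ultrametric = bool(np.allclose(d, d[0], rtol=1e-8))
        off = C[~np.eye(n, dtype=bool)]
        if np.max(np.abs(off)) < 1e-12 * np.max(np.diag(C)):
            self.identifiable_ = False
            self.lambda_ = np.nan
            warnings.warn(
                "star phylogeny: likelihood is constant in lambda; "
                "signal is non-identifiable"
            )
            ll0, mu, s2 = _profiled_loglik_chol(self._chol(C, 0.0), y)
            self.log_likelihood_ = self.log_likelihood_0_ = ll0
            self.sigma2_, self.root_state_ = s2, mu
            self.p_value_ = 1.0
            self.lambda_max_ = 1.0
            return self

        lam_max = self._lambda_max(C, ultrametric)
        grid = np.linspace(0.0, lam_max, self.grid_size)
        chols = [self._chol(C, g) for g in grid]
        ll_grid = np.array([_profiled_loglik_chol(L, y)[0] for L in chols])

        if ll_grid.max() - ll_grid.min() < 1e-10:
            self.identifiable_ = False
            warnings.warn("likelihood flat in lambda; non-identifiable")
        else:
            self.identifiable_ = True

        # Brent refinement around the best grid point
        i = int(np.argmax(ll_grid))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if hi > lo:
            res = minimize_scalar(
                lambda lam: -_profiled_loglik_chol(self._chol(C, lam), y)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": self.tol},
            )
            lam_hat, ll_hat = float(res.x), -float(res.fun)
            if ll_hat < ll_grid[i]:
                lam_hat, ll_hat = float(grid[i]), float(ll_grid[i])
        else:
            lam_hat, ll_hat = float(grid[i]), float(ll_grid[i])

        ll0, _, _ = _profiled_loglik_chol(chols[0], y)
        _, mu_hat, s2_hat = _profiled_loglik_chol(self._chol(C, lam_hat), y)
        self.lambda_ = lam_hat if self.identifiable_ else np.nan
        self.lambda_max_ = lam_max
        self.sigma2_ = s2_hat
        self.root_state_ = mu_hat
        self.log_likelihood_ = ll_hat
        self.log_likelihood_0_ = ll0

        stat_obs_grid = float(ll_grid.max() - ll_grid[0])
        if self.method == "lr":
            lr = 2.0 * max(ll_hat - ll0, 0.0)
            self.p_value_ = float(chi2.sf(lr, df=1))
        elif self.method == "permutation":
            rng = np.random.default_rng(self.random_state)
            perms = np.column_stack(
                [rng.permutation(y) for _ in range(self.n_sims)]
            )
            ll_perm = np.vstack([_profiled_loglik_chol(L, perms) for L in chols])
            stat_perm = ll_perm.max(axis=0) - ll_perm[0]
            exceed = int(np.sum(stat_perm >= stat_obs_grid - 1e-12))
            self.p_value_ = (1.0 + exceed) / (self.n_sims + 1.0)
        else:
            raise ValueError(f"unknown method {self.method!r}")
        return self


@dataclass
class LambdaFit:
    lambda_hat: float
    lambda_max: float
    sigma2_hat: float
    root_state: float
    log_likelihood: float
    log_likelihood_0: float
    p_value: float
    n_sims: int
    identifiable: bool


def fit_lambda(
    tree: Phylogeny,
    trait,
    n_sims: int = 999,
    method: str = "permutation",
    seed=None,
) -> LambdaFit:
    """Estimate Pagel's lambda for per-tip trait values on a phylogeny.

    `trait` is a mapping tip-name -> value or an array ordered like the
    tree's tips.
    """
    C, order = phylo_covariance(tree)
    if isinstance(trait, dict):
        missing = [t for t in order if t not in trait]
        if missing:
            raise ValueError(f"trait missing for tips: {missing[:5]}")
        y = np.array([trait[t] for t in order], dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    est = PagelLambda(n_sims=n_sims, method=method, random_state=seed).fit(C, y)
    return LambdaFit(
        lambda_hat=est.lambda_,
        lambda_max=est.lambda_max_,
        sigma2_hat=est.sigma2_,
        root_state=est.root_state_,
        log_likelihood=est.log_likelihood_,
        log_likelihood_0=est.log_likelihood_0_,
        p_value=est.p_value_,
        n_sims=n_sims if method == "permutation" else 0,
        identifiable=est.identifiable_,
    )


def abundance_trait(table, sample_id: str, log_transform: bool = True) -> dict:
    """Per-OTU relative abundance on one day, as a tip-trait mapping.

    With ``log_transform`` the proportions are log(x + c) transformed with
    pseudo-count c equal to half the smallest nonzero proportion.
    """
    s = table.sample_ids.index(sample_id)
    rel = table.relative_abundance()[:, s]
    if log_transform:
        nz = rel[rel > 0]
        if nz.size == 0:
            raise ValueError(f"sample {sample_id!r} has no counts")
        c = 0.5 * nz.min()
        rel = np.log(rel + c)
    return dict(zip(table.otu_ids, rel))
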