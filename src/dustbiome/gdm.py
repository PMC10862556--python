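"""Generalized dissimilarity modeling (GDM).

GDM regresses pairwise compositional dissimilarities d_ij in [0, 1) on
monotone I-spline transforms of per-site predictors through the link

    mu_ij = 1 - exp(-eta_ij),
    eta_ij = beta_0 + sum_k |f_k(x_ik) - f_k(x_jk)| ,

where each f_k = sum_m beta_km I_m is a non-negative combination of
I-spline basis functions (here three per predictor with knots at the
0/50/100th percentiles of the site values).  Because every I-spline is
monotone non-decreasing and the coefficients are constrained >= 0, the
absolute difference decomposes as a non-negative linear combination of
per-basis absolute differences, so the model is a non-negative GLM-type
regression fitted by iteratively reweighted non-negative least squares on
the binomial-type deviance.  Fit quality is the percent of the
intercept-only null deviance explained; predictor importance is the mean
drop in deviance explained when that predictor's site values are permuted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import minimize_scalar, nnls
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, RegressorMixin

EPS_ONE = 1e-6  # dissimilarities of exactly 1 are shrunk before link inversion


# ---------------------------------------------------------------------------
# I-spline basis
# ---------------------------------------------------------------------------

@dataclass
class ISplineBasis:
    """Monotone I-spline basis for one predictor.

    Three quadratic I-splines on knots at the predictor's min/median/max.
    Each basis function rises monotonically from 0 at the range minimum to
    1 at the maximum; values outside the range are clamped.
    """

    knots: np.ndarray  # (min, median, max)

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.size != 3 or not np.all(np.diff(self.knots) >= 0):
            raise ValueError("knots must be (min <= median <= max)")
        lo, mid, hi = self.knots
        if hi <= lo:
            raise ValueError("degenerate predictor range")
        # I-splines of order 2 = reversed cumulative sums of degree-2
        # B-splines on the clamped knot vector.
        self._t = np.array([lo, lo, lo, mid, hi, hi, hi])

    @property
    def n_splines(self) -> int:
        return 3

    def __call__(self, x) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.knots[0], self.knots[2])
        dm = BSpline.design_matrix(x, self._t, k=2, extrapolate=False).toarray()
        # cumulative sum from the right, dropping the constant column
        I = np.cumsum(dm[:, ::-1], axis=1)[:, ::-1][:, 1:]
        return np.clip(I, 0.0, 1.0)

    @classmethod
    def from_values(cls, values) -> "ISplineBasis":
        v = np.asarray(values, dtype=float)
        return cls(np.array([v.min(), np.median(v), v.max()]))


# ---------------------------------------------------------------------------
# Site-pair table
# ---------------------------------------------------------------------------

def build_site_pair_table(d, covariates, predictor_names=None):
    """Pair table for GDM: response d_ij plus per-basis |I(x_i) - I(x_j)|.

    Parameters
    ----------
    d : DissimilarityMatrix or square ndarray
    covariates : CovariateTable or (n_sites, p) ndarray
    predictor_names : list of str, optional
        Subset/order of covariates to use.

    Returns
    -------
    dict with keys ``response`` (n_pairs,), ``terms`` (n_pairs, 3p),
    ``pairs`` (i, j index tuples), ``bases`` (per-predictor ISplineBasis),
    ``predictor_names``.
    """
    D = d.matrix if hasattr(d, "matrix") else np.asarray(d, dtype=float)
    X = covariates.values if hasattr(covariates, "values") else np.asarray(covariates, float)
    names = (
        list(covariates.covariate_names)
        if hasattr(covariates, "covariate_names")
        else [f"x{j}" for j in range(X.shape[1])]
    )
    if predictor_names is not None:
        idx = [names.index(p) for p in predictor_names]
        X, names = X[:, idx], list(predictor_names)
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 sites")
    if X.shape[0] != n:
        raise ValueError("covariates and dissimilarities disagree on site count")

    keep, bases = [], []
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            warnings.warn(f"constant predictor {name!r} excluded")
            continue
        keep.append(j)
        bases.append(ISplineBasis.from_values(X[:, j]))
    if not keep:
        raise ValueError("no non-constant predictors")
    names = [names[j] for j in keep]
    X = X[:, keep]

    iu = np.triu_indices(n, k=1)
    response = D[iu]
    cols = []
    for j, basis in enumerate(bases):
        I = basis(X[:, j])                     # (n_sites, 3)
        cols.append(np.abs(I[iu[0]] - I[iu[1]]))
    terms = np.hstack(cols)
    return {
        "response": response,
        "terms": terms,
        "pairs": list(zip(iu[0], iu[1])),
        "bases": bases,
        "predictor_names": names,
        "site_values": X,
    }


# ---------------------------------------------------------------------------
# Deviance
# ---------------------------------------------------------------------------

def _deviance(y, mu):
    y = np.clip(y, 0.0, 1.0)
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1.0 - y) * np.log((1.0 - y) / (1.0 - mu)), 0.0)
    return 2.0 * float(np.sum(t1 + t2))


def _null_deviance(y):
    """Intercept-only model deviance (1-D optimization over beta_0 >= 0)."""

    def obj(b0):
        return _deviance(y, 1.0 - np.exp(-b0))

    res = minimize_scalar(obj, bounds=(1e-9, 20.0), method="bounded")
    return float(res.fun), float(res.x)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------

class GDMRegressor(BaseEstimator, RegressorMixin):
    """Generalized dissimilarity model with I-spline predictor transforms.

    Parameters
    ----------
    n_splines : int
        I-splines per predictor (fixed at 3: min/median/max knots).
    tol : float
        Convergence tolerance on the coefficient vector in the
        iteratively reweighted NNLS loop.
    max_iter : int
        Maximum IRLS iterations.

    Attributes
    ----------
    intercept_ : float  (>= 0)
    coefs_ : ndarray of shape (n_predictors, 3), all >= 0
    deviance_ : float            residual deviance
    null_deviance_ : float
    deviance_explained_ : float  percent, 100 * (1 - residual/null)
    predictor_names_, bases_ : fitted metadata
    n_iter_ : int
    """

    def __init__(self, n_splines=3, tol=1e-8, max_iter=100):
        self.n_splines = n_splines
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y=None, pair_table=None, predictor_names=None):
        """Fit from site covariates + dissimilarities, or a prebuilt pair table.

        ``X`` is a (n_sites, p) covariate matrix (or CovariateTable) and
        ``y`` a square dissimilarity matrix (or DissimilarityMatrix), unless
        `pair_table` (from :func:`build_site_pair_table`) is given directly.
        """
        if pair_table is None:
            pair_table = build_site_pair_table(y, X, predictor_names)
        resp = np.asarray(pair_table["response"], dtype=float)
        terms = np.asarray(pair_table["terms"], dtype=float)
        if np.any((resp < 0) | (resp > 1)):
            raise ValueError("dissimilarities must lie in [0, 1]")
        if np.ptp(resp) == 0:
            raise ValueError("all dissimilarities equal: deviance undefined")

        y_shrunk = np.minimum(resp, 1.0 - EPS_ONE)
        A = np.column_stack([np.ones(len(resp)), terms])
        # init: intercept from the mean response through the inverse link
        beta = np.zeros(A.shape[1])
        beta[0] = -np.log(1.0 - np.clip(np.mean(y_shrunk), 1e-9, 1.0 - 1e-9))
        for it in range(1, self.max_iter + 1):
            eta = A @ beta
            mu = 1.0 - np.exp(-eta)
            mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
            dmu = 1.0 - mu                       # d mu / d eta = exp(-eta)
            z = eta + (y_shrunk - mu) / dmu      # working response
            w = dmu**2 / (mu * (1.0 - mu))       # binomial working weights
            sw = np.sqrt(w)
            beta_new, _ = nnls(A * sw[:, None], z * sw)
            if np.max(np.abs(beta_new - beta)) < self.tol:
                beta = beta_new
                break
            beta = beta_new
        else:
            it = self.max_iter
            warnings.warn("IRLS reached max_iter without meeting tol")

        eta = A @ beta
        mu = 1.0 - np.exp(-eta)
        self.intercept_ = float(beta[0])
        k = self.n_splines
        p = terms.shape[1] // k
        self.coefs_ = beta[1:].reshape(p, k)
        self.deviance_ = _deviance(resp, mu)
        self.null_deviance_, self.null_intercept_ = _null_deviance(resp)
        self.deviance_explained_ = 100.0 * (1.0 - self.deviance_ / self.null_deviance_)
        self.predictor_names_ = pair_table["predictor_names"]
        self.bases_ = pair_table["bases"]
        self.n_iter_ = it
        self._pair_table = pair_table
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted pairwise dissimilarity matrix for site covariates X."""
        X = X.values if hasattr(X, "values") else np.asarray(X, dtype=float)
        n = X.shape[0]
        iu = np.triu_indices(n, k=1)
        eta = np.full(len(iu[0]), self.intercept_)
        for j, basis in enumerate(self.bases_):
            I = basis(X[:, j])
            eta += np.abs(I[iu[0]] - I[iu[1]]) @ self.coefs_[j]
        mu = 1.0 - np.exp(-eta)
        return squareform(mu)

    def spline_curves(self, n_points: int = 200):
        """Fitted monotone transform f_k on a grid over each predictor range."""
        out = {}
        for j, (name, basis) in enumerate(zip(self.predictor_names_, self.bases_)):
            grid = np.linspace(basis.knots[0], basis.knots[2], n_points)
            out[name] = {"x": grid, "f": basis(grid) @ self.coefs_[j]}
        return out


def fit_gdm(d, covariates, predictor_names=None, **kwargs) -> GDMRegressor:
    """Convenience wrapper: fit a GDM from a dissimilarity matrix + covariates."""
    return GDMRegressor(**kwargs).fit(covariates, d, predictor_names=predictor_names)


def predictor_importance(model: GDMRegressor, n_perm: int = 100, seed=None):
    """Permutation importance: mean % drop in deviance explained per predictor.

    For each predictor, its per-site values are permuted across sites
    (`n_perm` times), the pair table rebuilt for that predictor, and the
    model refitted; importance is the mean drop in percent deviance
    explained, floored at 0.
    """
    if n_perm < 10:
        warnings.warn("n_perm < 10 gives unstable importance estimates")
    rng = np.random.default_rng(seed)
    pt = model._pair_table
    X = pt["site_values"]
    n_sites = X.shape[0]
    iu = np.triu_indices(n_sites, k=1)
    base_dev = model.deviance_explained_
    k = model.n_splines
    importance = {}
    for j, name in enumerate(model.predictor_names_):
        drops = np.empty(n_perm)
        for r in range(n_perm):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            basis = model.bases_[j]          # knots stay: same value multiset
            I = basis(Xp[:, j])
            terms = pt["terms"].copy()
            terms[:, j * k:(j + 1) * k] = np.abs(I[iu[0]] - I[iu[1]])
            refit = GDMRegressor(tol=model.tol, max_iter=model.max_iter).fit(
                None,
                pair_table={
                    "response": pt["response"],
                    "terms": terms,
                    "pairs": pt["pairs"],
                    "bases": pt["bases"],
                    "predictor_names": pt["predictor_names"],
                    "site_values": Xp,
                },
            )
            drops[r] = base_dev - refit.deviance_explained_
        importance[name] = max(float(np.mean(drops)), 0.0)
    return importance
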