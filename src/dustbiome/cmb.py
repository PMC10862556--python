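"""Effective-variance chemical mass balance (CMB) receptor modeling.

The receptor model expresses the measured concentration of element *i* in a
sample as a linear combination of source contributions,

    C_i = sum_j F_ij S_j + e_i ,

where F_ij is the mass fraction of element i per unit mass emitted by
source j and S_j is the ambient mass contribution of source j (µg/m^3).
Because both the ambient concentrations and the source profiles carry
measurement uncertainty, the weighted least-squares solution uses the
*effective variance*

    V_i = sigma_Ci^2 + sum_j S_j^2 sigma_Fij^2 ,

which depends on the solution itself and is therefore iterated to a fixed
point (Watson's effective-variance scheme).  Contribution uncertainties
come from the diagonal of the inverse weighted normal matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .datatypes import ElementPanel, SourceProfileSet
from .reference import OXIDE_FACTORS, RMMM_ELEMENTS


class CmbConvergenceError(RuntimeError):
    """Effective-variance iteration failed to converge; carries last iterate."""

    def __init__(self, message, last_solution):
        super().__init__(message)
        self.last_solution = last_solution


class EffectiveVarianceCMB(BaseEstimator, RegressorMixin):
    """Per-sample effective-variance weighted least squares CMB solver.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the maximum relative change in the
        contribution vector between iterations.
    max_iter : int
        Maximum number of effective-variance iterations.
    max_condition : float
        Largest acceptable condition number of the profile matrix on the
        fitted elements; beyond this the profile set is treated as
        collinear and fitting refuses to proceed.
    drop_negative : bool
        When True, sources fitted with negative contributions are removed
        and the sample refitted (standard receptor-modeling practice);
        when False (default), negative contributions are reported with a
        warning.

    Attributes
    ----------
    contributions_ : ndarray of shape (n_sources,)
        Fitted source contributions, µg/m^3.
    contributions_unc_ : ndarray of shape (n_sources,)
        1-sigma uncertainties from the inverse weighted normal matrix.
    r_squared_ : float
        Weighted (uncentered) explained variance of the fit.
    chi_squared_ : float
        Reduced chi-square: weighted residual sum of squares over
        (n_elements - n_sources) degrees of freedom.
    residuals_ : ndarray of shape (n_elements,)
        Per-element residual C - F S (same units as C).
    n_iter_ : int
        Iterations used.
    """

    def __init__(self, tol=1e-4, max_iter=50, max_condition=1e8, drop_negative=False):
        self.tol = tol
        self.max_iter = max_iter
        self.max_condition = max_condition
        self.drop_negative = drop_negative

    def fit(self, X, y, conc_unc=None, frac_unc=None):
        """Fit contributions for one sample.

        Parameters
        ----------
        X : ndarray of shape (n_elements, n_sources)
            Source profile matrix F (mass fractions).
        y : ndarray of shape (n_elements,)
            Measured concentrations C.
        conc_unc : ndarray of shape (n_elements,)
            1-sigma concentration uncertainties (required, > 0).
        frac_unc : ndarray of shape (n_elements, n_sources), optional
            1-sigma profile uncertainties; zero if omitted.
        """
        F = np.asarray(X, dtype=float)
        C = np.asarray(y, dtype=float)
        n_el, n_src = F.shape
        if conc_unc is None:
            raise ValueError("conc_unc is required")
        sC = np.asarray(conc_unc, dtype=float)
        sF = np.zeros_like(F) if frac_unc is None else np.asarray(frac_unc, float)
        if n_el < n_src:
            raise ValueError(
                f"need at least as many fitted elements ({n_el}) as sources ({n_src})"
            )
        if np.any(sC <= 0):
            raise ValueError("all concentration uncertainties must be > 0")
        self._check_conditioning(F)

        S = np.zeros(n_src)
        cov = None
        for it in range(1, self.max_iter + 1):
            V = sC**2 + (sF**2) @ (S**2)
            w = 1.0 / V
            A = F.T @ (F * w[:, None])
            b = F.T @ (C * w)
            try:
                cov = np.linalg.inv(A)
            except np.linalg.LinAlgError as err:
                raise ValueError("singular weighted normal matrix") from err
            S_new = cov @ b
            # relative to the solution scale so near-zero sources cannot
            # stall convergence on meaningless relative wiggle
            scale = max(float(np.max(np.abs(S_new))), 1e-12)
            delta = float(np.max(np.abs(S_new - S))) / scale
            S = S_new
            if delta < self.tol:
                break
        else:
            raise CmbConvergenceError(
                f"effective-variance iteration did not converge in "
                f"{self.max_iter} iterations (last max rel. change {delta:.2e})",
                S,
            )

        if np.any(S < 0):
            neg = [j for j in range(n_src) if S[j] < 0]
            if self.drop_negative:
                keep = np.array([j for j in range(n_src) if j not in neg])
                sub = EffectiveVarianceCMB(
                    self.tol, self.max_iter, self.max_condition, drop_negative=True
                ).fit(F[:, keep], C, conc_unc=sC, frac_unc=sF[:, keep])
                S = np.zeros(n_src)
                S[keep] = sub.contributions_
                unc = np.zeros(n_src)
                unc[keep] = sub.contributions_unc_
                self._finalize(F, C, sC, sF, S, unc, sub.n_iter_)
                self.dropped_sources_ = neg
                return self
            warnings.warn(
                f"negative fitted contributions for source indices {neg}; "
                "consider drop_negative=True"
            )

        unc = np.sqrt(np.diag(cov))
        self._finalize(F, C, sC, sF, S, unc, it)
        self.dropped_sources_ = []
        return self

    def _check_conditioning(self, F):
        # column-normalized condition number: flags truly collinear profiles
        norms = np.linalg.norm(F, axis=0)
        if np.any(norms == 0):
            raise ValueError("a source profile is all-zero on the fitted elements")
        cond = np.linalg.cond(F / norms)
        if cond > self.max_condition or not np.isfinite(cond):
            corr = np.corrcoef(F.T)
            np.fill_diagonal(corr, 0.0)
            i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
            raise ValueError(
                f"profile matrix is rank-deficient/collinear (condition number "
                f"{cond:.3g}); most collinear source pair: ({i}, {j})"
            )

    def _finalize(self, F, C, sC, sF, S, unc, n_iter):
        V = sC**2 + (sF**2) @ (S**2)
        w = 1.0 / V
        resid = C - F @ S
        n_el, n_src = F.shape
        sst = float(np.sum(w * C**2))
        ssr = float(np.sum(w * resid**2))
        self.contributions_ = S
        self.contributions_unc_ = unc
        self.residuals_ = resid
        self.r_squared_ = 1.0 - ssr / sst if sst > 0 else np.nan
        dof = n_el - n_src
        self.chi_squared_ = ssr / dof if dof > 0 else np.nan
        self.effective_variance_ = V
        self.n_iter_ = n_iter

    def predict(self, X):
        return np.asarray(X, float) @ self.contributions_


@dataclass
class ApportionmentResult:
    """Per-sample CMB solutions for a whole campaign.

    Contributions are µg/m^3; concentrations/residuals remain ng/m^3
    (internal element units), so a 1000x factor links `S` to the profile
    equation — handled internally by `fit_cmb`.
    """

    sample_ids: list
    source_names: list
    fit_elements: list
    S: np.ndarray               # (n_samples, n_sources), µg/m^3
    S_unc: np.ndarray
    r_squared: np.ndarray
    chi_squared: np.ndarray
    residuals: np.ndarray       # (n_samples, n_fit_elements), ng/m^3
    pm10_mass: np.ndarray | None = None

    @property
    def pct_mass(self) -> np.ndarray:
        """100 * (sum of contributions) / PM10 per sample."""
        if self.pm10_mass is None:
            raise ValueError("pct_mass requires PM10 masses")
        return 100.0 * self.S.sum(axis=1) / self.pm10_mass

    def source_index(self, name: str) -> int:
        if name not in self.source_names:
            raise KeyError(f"source {name!r} not in result")
        return self.source_names.index(name)


def fit_cmb(
    panel: ElementPanel,
    profiles: SourceProfileSet,
    fit_elements=None,
    **estimator_kwargs,
) -> ApportionmentResult:
    """Apportion every sample of a panel with the effective-variance CMB.

    `fit_elements` defaults to all panel elements present in the profiles,
    excluding elements missing (NaN) in more than half the samples.
    Concentrations are ng/m^3 and contributions µg/m^3, so profiles are
    scaled by 1000 inside the solver.
    """
    if fit_elements is None:
        shared = [e for e in panel.element_names if e in profiles.element_names]
        keep = []
        for e in shared:
            col = panel.conc[:, panel.element_names.index(e)]
            if np.isnan(col).sum() <= panel.n_samples / 2:
                keep.append(e)
        fit_elements = keep
    if len(fit_elements) < profiles.n_sources:
        raise ValueError(
            f"{len(fit_elements)} fitted elements for {profiles.n_sources} sources"
        )
    pidx = panel.element_index(fit_elements)
    prof = profiles.subset_elements(fit_elements)
    F = prof.frac.T * 1000.0       # ng per µg of source mass
    sF = prof.frac_unc.T * 1000.0

    n = panel.n_samples
    k = profiles.n_sources
    S = np.zeros((n, k))
    S_unc = np.zeros((n, k))
    r2 = np.zeros(n)
    chi2 = np.zeros(n)
    resid = np.zeros((n, len(fit_elements)))
    for s in range(n):
        C = panel.conc[s, pidx]
        sC = panel.unc[s, pidx]
        ok = ~np.isnan(C)
        est = EffectiveVarianceCMB(**estimator_kwargs).fit(
            F[ok], C[ok], conc_unc=sC[ok], frac_unc=sF[ok]
        )
        S[s] = est.contributions_
        S_unc[s] = est.contributions_unc_
        r2[s] = est.r_squared_
        chi2[s] = est.chi_squared_
        resid[s, ok] = est.residuals_
        resid[s, ~ok] = np.nan
    return ApportionmentResult(
        sample_ids=list(panel.sample_ids),
        source_names=list(profiles.source_names),
        fit_elements=list(fit_elements),
        S=S,
        S_unc=S_unc,
        r_squared=r2,
        chi_squared=chi2,
        residuals=resid,
        pm10_mass=None if panel.pm10_mass is None else panel.pm10_mass.copy(),
    )


def reconstruct_mineral_mass(
    result: ApportionmentResult,
    panel: ElementPanel,
    mineral_sources,
) -> dict:
    """Apportioned mineral mass vs oxide-reconstructed mineral mass (RMMM).

    Returns per-sample µg/m^3: ``apportioned`` = sum of the named mineral
    source contributions; ``rmmm`` = sum of conventional crustal oxide
    multipliers times the measured Al/Si/Ca/Fe/Ti concentrations (elements
    absent from the panel are skipped).
    """
    idx = [result.source_index(s) for s in mineral_sources]
    apportioned = result.S[:, idx].sum(axis=1) if idx else np.zeros(len(result.sample_ids))
    rmmm = np.zeros(panel.n_samples)
    for e in RMMM_ELEMENTS:
        if e in panel.element_names:
            col = panel.conc[:, panel.element_names.index(e)]
            rmmm += OXIDE_FACTORS[e] * np.nan_to_num(col, nan=0.0)
    rmmm /= 1000.0  # ng -> µg
    return {"apportioned": apportioned, "rmmm": rmmm}


def ratio_diagnostics(panel: ElementPanel) -> dict:
    """Per-sample La/Ce, La/V and PM10/PM2.5 ratios with campaign means.

    Zero or missing denominators yield NaN for that sample, which is
    excluded from the mean with a warning.
    """
    out = {"sample_ids": list(panel.sample_ids)}

    def ratio(num, den, name):
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(den > 0, num / den, np.nan)
        if np.any(~np.isfinite(r)):
            warnings.warn(f"{name}: zero/missing denominator; excluded from mean")
        out[name] = r
        out[f"mean_{name}"] = float(np.nanmean(r))

    for e_num, e_den, name in (("La", "Ce", "la_ce"), ("La", "V", "la_v")):
        if e_num in panel.element_names and e_den in panel.element_names:
            ratio(
                panel.conc[:, panel.element_names.index(e_num)],
                panel.conc[:, panel.element_names.index(e_den)],
                name,
            )
    if panel.pm10_mass is not None and panel.pm25_mass is not None:
        ratio(panel.pm10_mass, panel.pm25_mass, "pm10_pm25")
    return out


def classify_dust_days(dust_contribution, thresholds=(10.0, 30.0)):
    """Label samples low/medium/peak from the apportioned dust mass.

    ``low`` below `thresholds[0]` µg/m^3, ``peak`` above `thresholds[1]`,
    ``medium`` in between.
    """
    low_max, peak_min = thresholds
    if not low_max < peak_min:
        raise ValueError("thresholds must be ordered (low_max < peak_min)")
    dust = np.asarray(dust_contribution, dtype=float)
    return [
        "low" if d < low_max else ("peak" if d > peak_min else "medium")
        for d in dust
    ]


def summarize_contributions(dust, pm10, sample_ids=None, subset=None) -> dict:
    """Percent dust contribution statistics over a sample subset.

    Returns per-sample percentages 100*S_dust/PM10 with their mean,
    population standard deviation, and range.
    """
    dust = np.asarray(dust, dtype=float)
    pm10 = np.asarray(pm10, dtype=float)
    if subset is not None:
        if sample_ids is None:
            raise ValueError("subset selection requires sample_ids")
        keep = [sample_ids.index(s) for s in subset]
        if not keep:
            raise ValueError("empty sample subset")
        dust, pm10 = dust[keep], pm10[keep]
    if dust.size == 0:
        raise ValueError("empty sample subset")
    pct = 100.0 * dust / pm10
    return {
        "pct": pct,
        "mean": float(np.mean(pct)),
        "sd": float(np.std(pct)),  # population SD
        "min": float(np.min(pct)),
        "max": float(np.max(pct)),
    }


def unapportioned_fraction(result: ApportionmentResult) -> dict:
    """Percent of PM10 mass not assigned to any source.

    Negative values (over-apportionment) are reported as-is with a warning,
    never clipped.
    """
    if result.pm10_mass is None:
        raise ValueError("unapportioned_fraction requires PM10 masses")
    pct = 100.0 * (result.pm10_mass - result.S.sum(axis=1)) / result.pm10_mass
    if np.any(pct < 0):
        warnings.warn("apportioned mass exceeds PM10 for some samples")
    return {"pct": pct, "mean": float(np.mean(pct))}
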