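"""Effective-variance CMB solver and its campaign diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dustbiome import (
    EffectiveVarianceCMB,
    classify_dust_days,
    fit_cmb,
    ratio_diagnostics,
    reconstruct_mineral_mass,
    summarize_contributions,
    unapportioned_fraction,
)
from dustbiome.cmb import ApportionmentResult
from dustbiome.datatypes import ElementPanel
from dustbiome.simulate import gen_profiles, gen_samples


def _result(S, pm10, sources=None):
    S = np.atleast_2d(np.asarray(S, float))
    n, k = S.shape
    return ApportionmentResult(
        sample_ids=[f"S{i + 1}" for i in range(n)],
        source_names=sources or [f"src{j}" for j in range(k)],
        fit_elements=["Al"],
        S=S,
        S_unc=np.full_like(S, 0.1),
        r_squared=np.ones(n),
        chi_squared=np.zeros(n),
        residuals=np.zeros((n, 1)),
        pm10_mass=np.asarray(pm10, float),
    )


class TestSolver:
    def test_single_source_identity(self):
        F = np.array([[0.1], [0.05], [0.3]])
        C = 10.0 * F[:, 0]
        est = EffectiveVarianceCMB().fit(F, C, conc_unc=0.01 * C)
        np.testing.assert_allclose(est.contributions_, [10.0], atol=1e-10)
        np.testing.assert_allclose(est.residuals_, 0.0, atol=1e-10)
        assert est.r_squared_ == pytest.approx(1.0)

    def test_three_source_zero_noise_matches_linear_solve(self, rng):
        F = rng.uniform(0.01, 0.3, (10, 3))
        S_true = np.array([10.0, 5.0, 2.0])
        C = F @ S_true
        est = EffectiveVarianceCMB().fit(
            F, C, conc_unc=np.full(10, 0.05), frac_unc=0.1 * F
        )
        oracle, *_ = np.linalg.lstsq(F, C, rcond=None)
        np.testing.assert_allclose(est.contributions_, oracle, atol=1e-6)
        np.testing.assert_allclose(est.contributions_, S_true, atol=1e-6)

    def test_equal_uncertainties_equal_ols(self, rng):
        """With equal weights and no profile error the solution is OLS."""
        F = rng.uniform(0.01, 0.3, (12, 4))
        C = F @ rng.uniform(1, 20, 4) + rng.normal(0, 0.1, 12)
        C = np.abs(C)
        est = EffectiveVarianceCMB().fit(F, C, conc_unc=np.full(12, 0.7))
        ols, *_ = np.linalg.lstsq(F, C, rcond=None)
        np.testing.assert_allclose(est.contributions_, ols, atol=1e-8)

    def test_scale_equivariance(self, rng):
        F = rng.uniform(0.01, 0.3, (10, 3))
        C = F @ np.array([10.0, 5.0, 2.0]) * rng.uniform(0.95, 1.05, 10)
        sC = 0.1 * C
        sF = 0.1 * F
        a = EffectiveVarianceCMB().fit(F, C, conc_unc=sC, frac_unc=sF)
        b = EffectiveVarianceCMB().fit(F, 7.0 * C, conc_unc=7.0 * sC, frac_unc=sF)
        np.testing.assert_allclose(b.contributions_, 7.0 * a.contributions_, rtol=1e-6)

    def test_effective_variance_fixed_point(self, rng):
        F = rng.uniform(0.01, 0.3, (10, 3))
        C = F @ np.array([10.0, 5.0, 2.0]) * rng.uniform(0.9, 1.1, 10)
        sC, sF = 0.1 * C, 0.15 * F
        est = EffectiveVarianceCMB(tol=1e-10).fit(F, C, conc_unc=sC, frac_unc=sF)
        S = est.contributions_
        # one more hand iteration from the converged S
        V = sC**2 + (sF**2) @ (S**2)
        w = 1.0 / V
        S_next = np.linalg.solve(F.T @ (F * w[:, None]), F.T @ (C * w))
        np.testing.assert_allclose(S_next, S, rtol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_zero_noise_recovery_any_conditioned_profiles(self, seed):
        """Property: exact mixtures are recovered for any well-conditioned F."""
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 6)
        F = rng.uniform(0.005, 0.3, (3 * k, k))
        if np.linalg.cond(F / np.linalg.norm(F, axis=0)) > 100:
            return
        S_true = rng.uniform(0.5, 30, k)
        C = F @ S_true
        est = EffectiveVarianceCMB().fit(
            F, C, conc_unc=np.maximum(0.05 * C, 1e-6), frac_unc=0.2 * F
        )
        np.testing.assert_allclose(est.contributions_, S_true, atol=1e-6)

    def test_collinear_profiles_rejected(self):
        F = np.column_stack([np.ones(6), np.ones(6) * 2.0])
        with pytest.raises(ValueError, match="collinear"):
            EffectiveVarianceCMB().fit(F, np.ones(6), conc_unc=np.full(6, 0.1))

    def test_more_sources_than_elements_rejected(self):
        with pytest.raises(ValueError, match="at least as many"):
            EffectiveVarianceCMB().fit(
                np.ones((2, 3)), np.ones(2), conc_unc=np.full(2, 0.1)
            )

    def test_negative_contribution_warns_and_refit_drops(self, rng):
        F = rng.uniform(0.01, 0.3, (12, 2))
        C = F[:, 0] * 10.0 - F[:, 1] * 0.5  # second source genuinely negative
        C = np.abs(C)
        with pytest.warns(UserWarning, match="negative"):
            EffectiveVarianceCMB().fit(F, C + 1e-3, conc_unc=np.full(12, 1e-3))
        est = EffectiveVarianceCMB(drop_negative=True).fit(
            F, C + 1e-3, conc_unc=np.full(12, 1e-3)
        )
        assert np.all(est.contributions_ >= 0)

    def test_monte_carlo_bias_and_coverage_small(self, profiles7):
        """10% noise, 50 replicates: unbiased recovery, near-nominal coverage."""
        S_true = np.array([10.0, 5.0, 8.0, 3.0, 6.0, 2.0, 1.0])
        hits = np.zeros(7)
        means = np.zeros(7)
        n_rep = 50
        for r in range(n_rep):
            panel, _ = gen_samples(profiles7, S_true[None, :], 0.10, seed=5000 + r)
            res = fit_cmb(panel, profiles7)
            means += res.S[0] / n_rep
            hits += (np.abs(res.S[0] - S_true) <= 1.96 * res.S_unc[0]) / n_rep
        np.testing.assert_allclose(means, S_true, rtol=0.10)
        assert hits.mean() >= 0.85


class TestMineralMass:
    def test_fully_apportioned_equals_total(self, profiles7):
        S_true = np.array([[20.0, 5.0, 8.0, 3.0, 6.0, 2.0, 1.0]])
        panel, _ = gen_samples(profiles7, S_true, 0.0, seed=1)
        res = fit_cmb(panel, profiles7)
        out = reconstruct_mineral_mass(res, panel, res.source_names)
        np.testing.assert_allclose(out["apportioned"], res.S.sum(axis=1))

    def test_empty_source_list_zero(self, profiles7):
        S_true = np.array([[20.0, 5.0, 8.0, 3.0, 6.0, 2.0, 1.0]])
        panel, _ = gen_samples(profiles7, S_true, 0.0, seed=1)
        res = fit_cmb(panel, profiles7)
        out = reconstruct_mineral_mass(res, panel, [])
        np.testing.assert_allclose(out["apportioned"], 0.0)

    def test_crustal_only_sample_rmmm_within_15pct(self, profiles7):
        """Oxide reconstruction of a pure-crust sample tracks the dust mass."""
        S_true = np.zeros((1, 7))
        S_true[0, 0] = 40.0  # African dust only
        panel, _ = gen_samples(profiles7, S_true, 0.0, seed=2)
        res = fit_cmb(panel, profiles7)
        out = reconstruct_mineral_mass(res, panel, ["African dust"])
        assert out["rmmm"][0] == pytest.approx(out["apportioned"][0], rel=0.15)

    def test_unknown_source_rejected(self, profiles7):
        S_true = np.array([[20.0, 5.0, 8.0, 3.0, 6.0, 2.0, 1.0]])
        panel, _ = gen_samples(profiles7, S_true, 0.0, seed=1)
        res = fit_cmb(panel, profiles7)
        with pytest.raises(KeyError):
            reconstruct_mineral_mass(res, panel, ["volcano"])


class TestRatios:
    def test_equal_la_ce_gives_unit_ratio(self):
        conc = np.column_stack([np.full(4, 2.0), np.full(4, 2.0), np.full(4, 8.0)])
        panel = ElementPanel(
            ["a", "b", "c", "d"], ["La", "Ce", "V"], conc, 0.1 * conc
        )
        out = ratio_diagnostics(panel)
        assert out["mean_la_ce"] == pytest.approx(1.0)

    def test_zero_denominator_flagged_and_excluded(self):
        conc = np.array([[1.0, 2.0], [1.0, 0.0]])
        unc = np.full_like(conc, 0.1)
        panel = ElementPanel(["a", "b"], ["La", "Ce"], conc, unc)
        with pytest.warns(UserWarning, match="denominator"):
            out = ratio_diagnostics(panel)
        assert np.isnan(out["la_ce"][1])
        assert out["mean_la_ce"] == pytest.approx(0.5)


class TestDustDays:
    @pytest.mark.parametrize(
        "dust,label", [(65.7, "peak"), (14.0, "medium"), (2.0, "low")]
    )
    def test_printed_examples(self, dust, label):
        assert classify_dust_days([dust]) == [label]

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            classify_dust_days([5.0], thresholds=(30.0, 10.0))


class TestSummaries:
    def test_single_sample_sd_zero(self):
        out = summarize_contributions([10.0], [50.0])
        assert out["sd"] == 0.0
        assert out["mean"] == pytest.approx(20.0)

    def test_all_zero_contributions(self):
        out = summarize_contributions([0.0, 0.0], [50.0, 60.0])
        assert out["mean"] == 0.0

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_contributions([1.0], [50.0], sample_ids=["S1"], subset=[])

    def test_fully_apportioned_unapportioned_zero(self):
        res = _result([[30.0, 20.0]], [50.0])
        out = unapportioned_fraction(res)
        assert out["pct"][0] == pytest.approx(0.0)

    def test_known_secondary_fraction(self, profiles7):
        S_true = np.array([[20.0, 5.0, 8.0, 3.0, 6.0, 2.0, 1.0]])
        panel, _ = gen_samples(
            profiles7, S_true, 0.0, seed=3, secondary_fraction=0.20
        )
        res = fit_cmb(panel, profiles7)
        out = unapportioned_fraction(res)
        assert out["mean"] == pytest.approx(20.0, abs=0.5)

    def test_over_apportionment_negative_with_warning(self):
        res = _result([[40.0, 20.0]], [50.0])
        with pytest.warns(UserWarning, match="exceeds"):
            out = unapportioned_fraction(res)
        assert out["pct"][0] == pytest.approx(-20.0)
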