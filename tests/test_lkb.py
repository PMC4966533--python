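"""gEUD identities, LKB likelihood machinery, partial models, fixed params."""

import itertools

import numpy as np
import pytest
from scipy.stats import norm

from ntcp_rectox import (
    QUANTEC_LATE_RECTAL,
    CohortSpec,
    ConfigurationError,
    DegenerateDataError,
    DoseSample,
    FractionationScheme,
    LKBParams,
    apply_fixed_lkb,
    eqd2_convert,
    fit_lkb,
    fit_lkb_partial,
    generate_cohort,
    geud,
    lkb_ntcp,
)
from ntcp_rectox.lkb import cohort_dose_matrix, lkb_loglik
from ntcp_rectox.synthetic_cohort import default_lkb_truth


def sample(doses, vols=None):
    return DoseSample("p", np.asarray(doses, float),
                      None if vols is None else np.asarray(vols, float))


class TestGEUD:
    def test_n_one_is_mean_dose(self, rng):
        doses = rng.uniform(0, 80, 300)
        assert geud(sample(doses), 1.0) == pytest.approx(doses.mean(), rel=1e-12)

    def test_uniform_dose_any_exponent(self):
        for n in (0.05, 0.131, 1.0, 3.0):
            assert geud(sample([60.0] * 10), n) == pytest.approx(60.0, rel=1e-9)

    def test_two_voxel_closed_form(self):
        # (0.5 * 20**(1/0.131) + 0.5 * 60**(1/0.131)) ** 0.131
        expected = (0.5 * 20 ** (1 / 0.131) + 0.5 * 60 ** (1 / 0.131)) ** 0.131
        got = geud(sample([20.0, 60.0], [0.5, 0.5]), 0.131)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(54.8, abs=0.05)

    def test_small_n_approaches_max(self, rng):
        # the max-dose limit: with N equally weighted voxels the hottest voxel
        # carries weight 1/N, so gEUD(n) >= max * N**(-n); n = 0.001 puts the
        # 500-voxel case within 1% of the maximum
        doses = rng.uniform(10, 80, 500)
        gs = [geud(sample(doses), n) for n in (0.1, 0.01, 0.001)]
        assert all(g <= doses.max() + 1e-9 for g in gs)
        assert np.all(np.diff(gs) > 0)  # monotone approach to the max
        assert gs[-1] >= 0.99 * doses.max()

    def test_monotone_in_any_voxel(self, rng):
        doses = rng.uniform(10, 70, 50)
        base = geud(sample(doses), 0.3)
        bumped = doses.copy()
        bumped[7] += 5.0
        assert geud(sample(bumped), 0.3) > base

    def test_zero_doses_contribute_nothing(self):
        assert geud(sample([0.0, 0.0]), 0.5) == 0.0
        g = geud(sample([0.0, 60.0], [0.5, 0.5]), 0.5)
        assert 0 < g < 60

    def test_invalid_exponent(self):
        with pytest.raises(ConfigurationError):
            geud(sample([10.0]), 0.0)


class TestNTCP:
    def test_probit_symmetry_at_td50(self):
        params = LKBParams(56.8, 0.093, 0.131)
        assert lkb_ntcp(56.8, params) == pytest.approx(0.5, abs=1e-12)

    def test_one_slope_unit_above(self):
        params = LKBParams(50.0, 0.1, 0.2)
        assert lkb_ntcp(50.0 * 1.1, params) == pytest.approx(norm.cdf(1.0), rel=1e-12)

    def test_strictly_increasing_and_scale_invariant(self):
        params = LKBParams(60.0, 0.09, 0.1)
        g = np.linspace(30, 90, 50)
        p = lkb_ntcp(g, params)
        assert np.all(np.diff(p) > 0)
        scaled = lkb_ntcp(2 * g, LKBParams(120.0, 0.09, 0.1))
        assert np.allclose(p, scaled)


class TestFit:
    def test_grid_search_oracle_on_toy_cohort(self):
        """Nelder-Mead's optimum is at least as good as an exhaustive coarse
        3-D lattice search on a tiny cohort."""
        doses = [sample([40.0, 55.0]), sample([60.0, 75.0]),
                 sample([30.0, 45.0]), sample([65.0, 80.0])]
        y = np.array([0, 1, 0, 1])
        fit = fit_lkb(doses, y, bin_width=None, compute_ci=False)
        centers, weights = cohort_dose_matrix(doses, None)
        lattice = itertools.product(np.linspace(30, 90, 13),
                                    np.linspace(0.05, 0.5, 10),
                                    np.linspace(0.05, 1.0, 10))
        best_lattice = max(
            lkb_loglik(LKBParams(*point), centers, weights, y) for point in lattice
        )
        assert fit.loglik >= best_lattice - 1e-6

    def test_loglik_not_below_any_init_point(self, study_cohort, scheme):
        eff = [eqd2_convert(s, scheme) for s in study_cohort.doses]
        fit = fit_lkb(eff, study_cohort.outcomes, compute_ci=False)
        centers, weights = cohort_dose_matrix(eff, 0.25)
        from ntcp_rectox.lkb import _DEFAULT_INIT_GRID

        for point in _DEFAULT_INIT_GRID:
            assert fit.loglik >= lkb_loglik(LKBParams(*point), centers, weights,
                                            study_cohort.outcomes) - 1e-6

    def test_degenerate_cohort_rejected(self):
        doses = [sample([50.0]), sample([60.0])]
        with pytest.raises(DegenerateDataError):
            fit_lkb(doses, np.array([0, 0]))

    def test_separable_cohort_is_flagged(self):
        rng = np.random.default_rng(0)
        doses = [sample(rng.uniform(10, 40, 50)) for _ in range(10)]
        doses += [sample(rng.uniform(60, 80, 50)) for _ in range(10)]
        y = np.array([0] * 10 + [1] * 10)
        fit = fit_lkb(doses, y, compute_ci=False)
        assert not fit.converged

    def test_parameter_recovery_moderate_n(self):
        """Fitting cohorts simulated from a known LKB truth recovers it."""
        truth = default_lkb_truth()
        spec = CohortSpec(n_patients=1500, seed=42,
                          toxicity_model=truth)
        cohort = generate_cohort(spec)
        scheme = FractionationScheme()
        eff = [eqd2_convert(s, scheme) for s in cohort.doses]
        fit = fit_lkb(eff, cohort.outcomes)
        assert fit.converged
        assert fit.params.td50 == pytest.approx(truth.td50, abs=4.0)
        assert fit.params.m == pytest.approx(truth.m, abs=0.04)
        assert fit.params.n == pytest.approx(truth.n, abs=0.08)
        for name in ("td50", "m", "n"):
            lo, hi = fit.ci95[name]
            est = getattr(fit.params, name)
            assert lo <= est <= hi

    def test_ci_width_shrinks_with_n(self):
        truth = default_lkb_truth()
        scheme = FractionationScheme()
        widths = {}
        for n_pat in (500, 2000):
            cohort = generate_cohort(
                CohortSpec(n_patients=n_pat, seed=7, toxicity_model=truth)
            )
            eff = [eqd2_convert(s, scheme) for s in cohort.doses]
            fit = fit_lkb(eff, cohort.outcomes,
                          init_grid=[(50.0, 0.08, 0.1), (65.0, 0.12, 0.2)])
            widths[n_pat] = fit.ci95["td50"][1] - fit.ci95["td50"][0]
        assert widths[2000] < widths[500]


class TestPartial:
    def test_constant_covariate_falls_back(self, study_cohort, scheme):
        eff = [eqd2_convert(s, scheme) for s in study_cohort.doses]
        res = fit_lkb_partial(eff, study_cohort.outcomes,
                              np.zeros(len(eff)), "constant")
        assert res.degenerate_covariate
        assert res.delta == 0.0

    def test_dose_modifying_recovery(self):
        """A true TD50 modifier on a binary covariate is recovered."""
        rng = np.random.default_rng(3)
        truth = default_lkb_truth()
        delta_true = -0.05
        n_pat = 2000
        cohort = generate_cohort(CohortSpec(n_patients=n_pat, seed=15))
        scheme = FractionationScheme()
        eff = [eqd2_convert(s, scheme) for s in cohort.doses]
        x = cohort.patients["statins"].to_numpy(float)
        g = np.array([geud(s, truth.n) for s in eff])
        td = truth.td50 * np.exp(delta_true * x)
        p = norm.cdf((g - td) / (truth.m * td))
        y = (rng.random(n_pat) < p).astype(int)
        res = fit_lkb_partial(eff, y, x, "statins",
                              init_grid=[(50.0, 0.08, 0.1), (65.0, 0.12, 0.2)])
        assert res.converged
        assert res.delta == pytest.approx(delta_true, abs=0.03)
        assert res.delta_ci[0] <= res.delta <= res.delta_ci[1]


class TestApplyFixed:
    def test_huge_td50_gives_negligible_ntcp(self, study_cohort):
        max_dose = max(s.max_dose for s in study_cohort.doses)
        params = LKBParams(10 * max_dose, 0.13, 0.09)
        ntcp, mean = apply_fixed_lkb(study_cohort.doses, params)
        assert np.all(ntcp < 0.01)
        assert mean < 0.01

    def test_deterministic(self, study_cohort):
        a = apply_fixed_lkb(study_cohort.doses, QUANTEC_LATE_RECTAL)
        b = apply_fixed_lkb(study_cohort.doses, QUANTEC_LATE_RECTAL)
        assert np.array_equal(a[0], b[0])

    def test_late_model_underpredicts_acute_incidence(self, study_cohort, scheme):
        """The late-toxicity threshold (TD50 = 76.9 Gy) predicts far fewer
        events than the acute generating process produces."""
        eff = [eqd2_convert(s, scheme) for s in study_cohort.doses]
        _, mean_pred = apply_fixed_lkb(eff, QUANTEC_LATE_RECTAL)
        observed = study_cohort.outcomes.mean()
        assert mean_pred < 0.5 * observed
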