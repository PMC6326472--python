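"""Penalized-spline conditional logit: basis, likelihood, fitting, EDF,
fallback and ranking — checked against independent oracles."""

import numpy as np
import pytest

from conftest import make_synthetic_sets
from riverchoice.choice_sets import CandidateModel
from riverchoice.dcgam import (
    conditional_loglik,
    effective_df,
    fit_dcgam,
    linear_fallback,
    rank_from_aic,
    rank_models,
    spline_basis,
)
from riverchoice.errors import DomainError, FitError

LINEAR = CandidateModel("UOCW", ("uocw",), (False,))
SMOOTH = CandidateModel("UOCW", ("uocw",))


# ---------------------------------------------------------------------------
# spline basis


class TestSplineBasis:
    def test_raw_basis_partition_of_unity(self):
        x = np.linspace(-3.0, 7.0, 257)
        basis = spline_basis(x, basis_dim=4)
        assert np.allclose(basis.raw_design.sum(axis=1), 1.0, atol=1e-12)
        basis8 = spline_basis(x, basis_dim=8)
        assert np.allclose(basis8.raw_design.sum(axis=1), 1.0, atol=1e-12)

    def test_second_difference_penalty_rank(self):
        basis = spline_basis(np.linspace(0, 1, 50), basis_dim=4)
        assert np.linalg.matrix_rank(basis.raw_penalty) == 2

    def test_centered_columns_mean_zero(self):
        x = np.random.default_rng(0).uniform(0, 10, 300)
        basis = spline_basis(x, basis_dim=4)
        assert np.allclose(basis.design.mean(axis=0), 0.0, atol=1e-12)

    def test_quadratic_reproduced_unpenalized(self):
        # cubic Bernstein basis spans quadratics exactly
        x = np.linspace(0, 1, 41)
        y = 3.0 * x**2 - 2.0 * x + 0.5
        basis = spline_basis(x, basis_dim=4)
        coef, *_ = np.linalg.lstsq(basis.raw_design, y, rcond=None)
        assert np.allclose(basis.raw_design @ coef, y, atol=1e-6)

    def test_out_of_range_fit_time_raises(self):
        basis = spline_basis(np.linspace(0, 1, 10))
        with pytest.raises(DomainError):
            basis.evaluate(np.array([1.5]))

    def test_out_of_range_prediction_clamps_with_warning(self):
        basis = spline_basis(np.linspace(0, 1, 10))
        with pytest.warns(UserWarning, match="clamped"):
            inside = basis.evaluate(np.array([1.0]), clamp=True)
            outside = basis.evaluate(np.array([1.5]), clamp=True)
        assert np.allclose(inside, outside)

    def test_degenerate_range_raises(self):
        with pytest.raises(DomainError):
            spline_basis(np.ones(10))


# ---------------------------------------------------------------------------
# conditional likelihood


class TestConditionalLoglik:
    def test_identical_alternatives_give_log_21(self):
        sets = make_synthetic_sets(7, n_alts=21, covariate_draw=lambda rng, n: np.full(n, 3.3))
        ll = conditional_loglik(np.array([0.7]), sets, LINEAR)
        assert ll == pytest.approx(-7 * np.log(21), abs=1e-10)

    def test_two_alternative_arithmetic(self):
        sets = make_synthetic_sets(1, n_alts=2, covariate_draw=lambda rng, n: np.array([0.0, 1.0]))
        # force alternative with x=1 to be the used one
        for a in sets[0].alternatives:
            a.used = a.uocw == 1.0
        ll = conditional_loglik(np.array([np.log(3.0)]), sets, LINEAR)
        assert ll == pytest.approx(np.log(3.0 / 4.0), abs=1e-12)

    def test_matches_high_precision_oracle(self):
        import mpmath

        mpmath.mp.dps = 50
        rng = np.random.default_rng(17)
        for trial in range(30):
            n_sets = int(rng.integers(2, 6))
            sets = make_synthetic_sets(n_sets, n_alts=int(rng.integers(2, 7)), seed=trial)
            beta = rng.normal(size=2)
            model = CandidateModel("UOCW+NF", ("uocw", "nf"), (False, False))
            got = conditional_loglik(beta, sets, model)
            want = mpmath.mpf(0)
            for cs in sets:
                ws = [
                    mpmath.exp(beta[0] * a.uocw + beta[1] * a.nf)
                    for a in cs.alternatives
                ]
                w_used = ws[[a.used for a in cs.alternatives].index(True)]
                want += mpmath.log(w_used / mpmath.fsum(ws))
            assert abs(got - float(want)) < 1e-10

    def test_wrong_param_length_raises(self):
        sets = make_synthetic_sets(3, n_alts=3)
        with pytest.raises(DomainError):
            conditional_loglik(np.zeros(5), sets, LINEAR)

    def test_nonfinite_covariate_names_set(self):
        sets = make_synthetic_sets(3, n_alts=3)
        sets[1].alternatives[0].uocw = np.nan
        with pytest.raises(DomainError, match="set 1"):
            conditional_loglik(np.zeros(1), sets, LINEAR)


# ---------------------------------------------------------------------------
# fitting


def statsmodels_clogit(sets, covariates):
    """Independent conditional-logit oracle."""
    import pandas as pd
    from statsmodels.discrete.conditional_models import ConditionalLogit

    rows = [
        {
            "used": int(a.used),
            "set_id": cs.set_id,
            **{c: a.covariate(c) for c in covariates},
        }
        for cs in sets
        for a in cs.alternatives
    ]
    df = pd.DataFrame(rows)
    model = ConditionalLogit(df["used"], df[list(covariates)], groups=df["set_id"])
    return model.fit(method="newton", tol=1e-12, disp=False).params.to_numpy()


class TestFitDCGAM:
    def test_linear_fit_matches_statsmodels(self):
        sets = make_synthetic_sets(80, n_alts=6, beta={"uocw": 0.8, "nf": -0.5}, seed=2)
        model = CandidateModel("UOCW+NF", ("uocw", "nf"), (False, False))
        fit = fit_dcgam(sets, model)
        want = statsmodels_clogit(sets, ("uocw", "nf"))
        assert fit.converged
        assert np.allclose(fit.beta, want, atol=1e-6)

    def test_null_model_loglik_and_aic(self):
        sets = make_synthetic_sets(40, n_alts=21)
        fit = fit_dcgam(sets, CandidateModel("NULL", ()))
        assert fit.loglik == pytest.approx(-40 * np.log(21), abs=1e-12)
        assert fit.aic == pytest.approx(-2 * fit.loglik, abs=1e-12)
        assert fit.total_edf == 0.0

    def test_linear_truth_smooth_edf_near_one(self):
        sets = make_synthetic_sets(500, n_alts=8, beta={"uocw": 1.0}, seed=5)
        fit = fit_dcgam(sets, SMOOTH)
        assert fit.edf_per_term["uocw"] < 1.3
        # shape close to a straight line: compare to secant over the range
        design = fit.design.terms[0]
        x = np.linspace(design.basis.lo, design.basis.hi, 50)
        eta = design.columns_for(x) @ fit.beta
        secant = eta[0] + (eta[-1] - eta[0]) * (x - x[0]) / (x[-1] - x[0])
        assert np.max(np.abs(eta - secant)) < 0.02 * (eta.max() - eta.min())

    def test_likelihood_invariant_to_constant_covariate_shift(self):
        sets = make_synthetic_sets(60, n_alts=5, beta={"uocw": 0.9}, seed=6)
        model = CandidateModel("UOCW", ("uocw",), (False,))
        base = fit_dcgam(sets, model)
        for cs in sets:
            for a in cs.alternatives:
                a.uocw += 123.0
        shifted = fit_dcgam(sets, model)
        assert shifted.loglik == pytest.approx(base.loglik, abs=1e-8)

    def test_fixed_lambdas_skip_search(self):
        sets = make_synthetic_sets(50, n_alts=6, beta={"uocw": 1.0}, seed=7)
        fit = fit_dcgam(sets, SMOOTH, lambdas={"uocw": 3.0})
        assert fit.lambdas == {"uocw": 3.0}

    def test_deterministic(self):
        sets = make_synthetic_sets(60, n_alts=6, beta={"uocw": 1.0}, seed=8)
        a = fit_dcgam(sets, SMOOTH)
        b = fit_dcgam(sets, SMOOTH)
        assert np.array_equal(a.beta, b.beta)
        assert a.lambdas == b.lambdas

    def test_complete_separation_flagged(self):
        # deterministic choice of the largest covariate: likelihood unbounded
        rng = np.random.default_rng(9)
        sets = make_synthetic_sets(30, n_alts=4, seed=9)
        for cs in sets:
            best = max(cs.alternatives, key=lambda a: a.uocw)
            for a in cs.alternatives:
                a.used = a is best
        fit = fit_dcgam(sets, CandidateModel("UOCW", ("uocw",), (False,)))
        assert not fit.converged
        assert "separation" in fit.note or "convergence" in fit.note

    def test_empty_sets_raise(self):
        with pytest.raises(FitError):
            fit_dcgam([], SMOOTH)


# ---------------------------------------------------------------------------
# effective degrees of freedom


class TestEffectiveDF:
    @pytest.fixture(scope="class")
    def wiggly_sets(self):
        # strongly non-linear truth so the unpenalized fit uses full freedom
        def draw(rng, n):
            return rng.uniform(0, 1, n)

        sets = make_synthetic_sets(300, n_alts=8, seed=11, covariate_draw=draw)
        rng = np.random.default_rng(12)
        for cs in sets:
            x = np.array([a.uocw for a in cs.alternatives])
            eta = 3 * np.sin(6 * x)
            p = np.exp(eta - eta.max())
            p /= p.sum()
            used = int(rng.choice(len(x), p=p))
            for j, a in enumerate(cs.alternatives):
                a.used = j == used
        return sets

    def test_edf_is_basis_dim_minus_one_at_zero_lambda(self, wiggly_sets):
        fit = fit_dcgam(wiggly_sets, SMOOTH, lambdas={"uocw": 0.0})
        assert fit.edf_per_term["uocw"] == pytest.approx(3.0, abs=1e-6)

    def test_edf_tends_to_one_at_huge_lambda(self, wiggly_sets):
        fit = fit_dcgam(wiggly_sets, SMOOTH, lambdas={"uocw": 1e12})
        assert fit.edf_per_term["uocw"] == pytest.approx(1.0, abs=0.05)

    def test_edf_monotone_decreasing_in_lambda(self, wiggly_sets):
        edfs = [
            fit_dcgam(wiggly_sets, SMOOTH, lambdas={"uocw": lam}).edf_per_term["uocw"]
            for lam in (0.0, 0.1, 1.0, 10.0, 100.0, 1e4)
        ]
        assert all(a > b for a, b in zip(edfs, edfs[1:]))

    def test_effective_df_recomputation_matches(self, wiggly_sets):
        fit = fit_dcgam(wiggly_sets, SMOOTH, lambdas={"uocw": 2.0})
        per_term, total = effective_df(fit)
        assert per_term["uocw"] == pytest.approx(fit.edf_per_term["uocw"], abs=1e-10)
        assert total == pytest.approx(fit.total_edf, abs=1e-10)


# ---------------------------------------------------------------------------
# linear fallback


class TestLinearFallback:
    def test_triggers_on_edf_near_one(self):
        sets = make_synthetic_sets(400, n_alts=8, beta={"uocw": 1.0}, seed=13)
        fit = fit_dcgam(sets, SMOOTH)
        if abs(fit.edf_per_term["uocw"] - 1.0) <= 0.05:
            fallback = linear_fallback(fit, sets)
            assert fallback.model.smooth == (False,)
        else:  # force the trigger via a huge smoothing parameter
            fit = fit_dcgam(sets, SMOOTH, lambdas={"uocw": 1e12})
            fallback = linear_fallback(fit, sets)
            assert fallback.model.smooth == (False,)

    def test_unchanged_when_all_edf_above_tolerance(self):
        def draw(rng, n):
            return rng.uniform(0, 1, n)

        sets = make_synthetic_sets(200, n_alts=8, seed=14, covariate_draw=draw)
        rng = np.random.default_rng(15)
        for cs in sets:
            x = np.array([a.uocw for a in cs.alternatives])
            eta = 4 * (x - 0.5) ** 2
            p = np.exp(eta - eta.max())
            p /= p.sum()
            used = int(rng.choice(len(x), p=p))
            for j, a in enumerate(cs.alternatives):
                a.used = j == used
        fit = fit_dcgam(sets, SMOOTH, lambdas={"uocw": 0.01})
        assert fit.edf_per_term["uocw"] > 1.05
        assert linear_fallback(fit, sets) is fit

    def test_fallback_usually_lowers_aic_under_linear_truth(self):
        # tolerance covers the residual flexibility a finite lambda-grid cap
        # leaves in the "straight" smooth
        wins = 0
        n_rep = 40
        for r in range(n_rep):
            sets = make_synthetic_sets(80, n_alts=6, beta={"uocw": 0.8}, seed=100 + r)
            smooth_fit = fit_dcgam(sets, SMOOTH)
            fallback_fit = linear_fallback(smooth_fit, sets)
            wins += fallback_fit.aic <= smooth_fit.aic + 1e-3
        assert wins >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# ranking


class TestRanking:
    def test_printed_riverine_table_arithmetic(self):
        aics = [1359.05, 1360.40, 1360.57, 1361.83, 1366.10]
        names = ["UOCW+NF+UD", "UOCW+NF", "UOCW+NF+DIS", "TCW+UOCW+NF", "NF"]
        ncov = [3, 2, 3, 3, 1]
        ranking = rank_from_aic(names, aics, ncov)
        assert ranking["UOCW+NF"].delta_aic == pytest.approx(1.35, abs=1e-9)
        weights = [round(r.weight, 2) for r in ranking.rows]
        assert weights == [0.44, 0.23, 0.21, 0.11, 0.01]
        # parsimony: both ΔAIC ≤ 2 models, the 2-covariate one wins
        assert ranking.selected == "UOCW+NF"

    def test_printed_corridor_table_arithmetic(self):
        aics = [2614.87, 2620.86, 2638.10, 2654.28]
        names = ["UOCW+NF", "UOCW", "NF", "NULL"]
        ranking = rank_from_aic(names, aics, [2, 1, 1, 0])
        assert ranking["NF"].delta_aic == pytest.approx(23.23, abs=1e-9)
        assert round(ranking.rows[0].weight, 2) == 0.95
        assert ranking.selected == "UOCW+NF"

    def test_single_model(self):
        ranking = rank_from_aic(["ONLY"], [123.4], [1])
        assert ranking.rows[0].delta_aic == 0.0
        assert ranking.rows[0].weight == 1.0
        assert ranking.selected == "ONLY"

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(3)
        aics = rng.uniform(100, 200, 9)
        ranking = rank_from_aic([str(i) for i in range(9)], aics, range(9))
        assert sum(r.weight for r in ranking.rows) == pytest.approx(1.0, abs=1e-9)
        assert all(r.delta_aic >= 0 for r in ranking.rows)

    def test_rank_models_rejects_mismatched_data(self):
        fits_a = fit_dcgam(make_synthetic_sets(10, n_alts=3), CandidateModel("NULL", ()))
        fits_b = fit_dcgam(make_synthetic_sets(12, n_alts=3), CandidateModel("NULL", ()))
        with pytest.raises(FitError, match="differing"):
            rank_models([fits_a, fits_b])

    def test_rank_models_on_fits(self):
        sets = make_synthetic_sets(100, n_alts=6, beta={"uocw": 1.0}, seed=30)
        fits = [
            fit_dcgam(sets, CandidateModel("NULL", ())),
            fit_dcgam(sets, LINEAR),
        ]
        ranking = rank_models(fits)
        assert ranking.selected == "UOCW"
        assert ranking["NULL"].delta_aic > 2.0
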