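import numpy as np
import pytest
from scipy.interpolate import CubicSpline
from scipy.special import expit

from cesofa import (
    GeneratorConfig,
    OrdinalPointScheme,
    ScoreDerivation,
    enumerate_extensions,
    generate_cohort,
    ncs_basis,
    ordinalize,
    screen_variables,
    select_best,
    select_df,
    substitution_fit,
)
from cesofa.derivation import NINE_VARIABLES
from cesofa.scoring import BASE_SOFA, score_cohort


def natural_interpolation_basis(x, knots):
    """Independent natural-spline basis: cardinal natural cubic interpolants.

    The space of natural cubic splines with the given knots is spanned by
    the interpolants of the indicator data at the knots under natural
    boundary conditions.
    """
    cols = []
    for j in range(len(knots)):
        e = np.zeros(len(knots))
        e[j] = 1.0
        cs = CubicSpline(knots, e, bc_type="natural", extrapolate=True)
        cols.append(cs(x))
    return np.column_stack(cols)


def span_residual(A, B):
    """Max residual of projecting columns of B onto span([1, A])."""
    design = np.column_stack([np.ones(A.shape[0]), A])
    resid, *_ = np.linalg.lstsq(design, B, rcond=None)
    return np.max(np.abs(B - design @ resid))


class TestNcsBasis:
    def test_df1_is_linear(self):
        x = np.linspace(0, 10, 50)
        basis = ncs_basis(x, df=1)
        assert basis.shape == (50, 1)
        np.testing.assert_allclose(basis[:, 0], x)

    def test_linear_beyond_boundary(self):
        rng = np.random.default_rng(1)
        data = rng.uniform(0, 1, 200)
        # evaluate well outside the boundary knots on an even grid
        grid = np.linspace(1.5, 3.0, 30)
        basis = ncs_basis(grid, df=4, data=data)
        second_diff = np.diff(basis, n=2, axis=0)
        assert np.max(np.abs(second_diff)) < 1e-8

    def test_spans_match_independent_construction(self):
        """df=3 truncated-power basis spans the same space as cardinal
        natural-spline interpolants on the same knots (both directions)."""
        x = np.arange(1.0, 101.0)
        df = 3
        ours = ncs_basis(x, df=df)
        knots = np.quantile(x, np.linspace(0, 1, df + 1))
        ref = natural_interpolation_basis(x, knots)
        assert span_residual(ours, ref) < 1e-7
        assert span_residual(ref, ours) < 1e-7

    def test_insufficient_distinct_values(self):
        with pytest.raises(ValueError):
            ncs_basis(np.array([1.0, 1.0, 2.0]), df=3)


class TestSelectDf:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        y = (rng.random(200) < expit(x)).astype(int)
        res = select_df(x, y, candidates=[3])
        assert res.df == 3

    def test_aic_identity(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(300)
        y = (rng.random(300) < expit(0.5 * x)).astype(int)
        res = select_df(x, y, candidates=[2])
        k = len(res.fit.coefficients)
        assert res.fit.aic == pytest.approx(2 * k - 2 * res.fit.loglik)

    def test_linear_truth_prefers_df1(self):
        """A purely linear log-odds should usually win with df = 1."""
        rng = np.random.default_rng(77)
        wins = 0
        reps = 40
        for _ in range(reps):
            x = rng.standard_normal(400)
            y = (rng.random(400) < expit(-0.5 + 1.0 * x)).astype(int)
            wins += select_df(x, y, candidates=(1, 2, 3, 4, 5)).df == 1
        assert wins > reps / 2

    def test_risk_curve_evaluates(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 300)
        y = (rng.random(300) < expit(x - 5)).astype(int)
        res = select_df(x, y)
        p = res.fitted_risk_curve(np.array([1.0, 9.0]))
        assert 0 <= p[0] < p[1] <= 1


class TestScreenVariables:
    def test_nine_in_nine_out(self, train_cohort):
        results = screen_variables(train_cohort)
        assert [r.variable for r in results] == list(NINE_VARIABLES)
        assert all(r.error is None for r in results)

    def test_signal_ordering(self):
        """Strong log-cTnT effect, null pressures: cTnT must out-discriminate SBP."""
        cfg = GeneratorConfig(n=2000, seed=19)
        cohort = generate_cohort(cfg)
        res = {r.variable: r.auc for r in screen_variables(cohort, ("hs_ctnt", "sbp"))}
        assert res["hs_ctnt"] > res["sbp"]

    def test_null_outcome_aucs_near_half(self, null_config):
        null_config.n = 5000
        cohort = generate_cohort(null_config)
        for r in screen_variables(cohort):
            assert r.auc == pytest.approx(0.5, abs=0.05)

    def test_record_order_invariance(self, train_cohort):
        from cesofa.cohort import Cohort

        rng = np.random.default_rng(3)
        perm = rng.permutation(len(train_cohort))
        shuffled = Cohort([train_cohort[i] for i in perm], label="shuffled")
        a = screen_variables(train_cohort, ("hs_ctnt",))[0]
        b = screen_variables(shuffled, ("hs_ctnt",))[0]
        assert a.auc == pytest.approx(b.auc, abs=1e-9)
        assert a.df == b.df


class TestOrdinalize:
    def test_monotone_risk_gives_monotone_bin_mortality(self):
        rng = np.random.default_rng(4)
        n = 10_000
        x = rng.lognormal(3, 1, n)
        y = (rng.random(n) < expit(-3 + 0.9 * np.log(x))).astype(int)
        scheme = ordinalize(x, y, n_bins=5, transform="log", variable="x")
        bins = np.searchsorted(np.array(scheme.thresholds), x, side="right")
        rates = [y[bins == b].mean() for b in range(5)]
        assert all(a <= b + 0.01 for a, b in zip(rates[:-1], rates[1:]))

    def test_log_linear_risk_gives_geometric_thresholds(self):
        """Risk linear in log(x) makes equal log-odds increments equal
        log-spacing, i.e. roughly constant threshold ratios."""
        rng = np.random.default_rng(14)
        n = 20_000
        x = rng.lognormal(0, 1, n)
        y = (rng.random(n) < expit(1.2 * np.log(x))).astype(int)
        scheme = ordinalize(x, y, n_bins=5, transform="log", variable="x")
        ratios = np.diff(np.log(scheme.thresholds))
        assert np.std(ratios) / np.mean(ratios) < 0.5

    def test_two_bins_separable_toy(self):
        x = np.r_[np.linspace(0, 1, 30), np.linspace(2, 3, 30)]
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        scheme = ordinalize(x, y, n_bins=2, variable="x", min_bin_frac=0.1)
        assert 1.0 < scheme.thresholds[0] <= 2.0 + 1e-9

    def test_thresholds_inside_data_range(self, train_cohort):
        x = train_cohort.field("hs_ctnt")
        scheme = ordinalize(x, train_cohort.outcome, transform="log", variable="hs_ctnt")
        assert x.min() <= scheme.thresholds[0]
        assert scheme.thresholds[-1] <= x.max()
        assert all(np.diff(scheme.thresholds) > 0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            ordinalize(np.ones(100), np.r_[np.ones(50), np.zeros(50)].astype(int))


class TestSubstitutionFit:
    def test_arity_with_replacement(self, train_cohort):
        scheme = OrdinalPointScheme(variable="af", binary=True, binary_points=2)
        fit = substitution_fit(train_cohort, scheme)
        assert len(fit.names) == 7  # intercept + 5 SOFA + replacement
        assert fit.names[-1] == "af_points"

    def test_cardiovascular_term_without_replacement(self, train_cohort):
        fit = substitution_fit(train_cohort, None)
        assert fit.names[-1] == "sofa_cardio"

    def test_age_sex_adjustment(self, train_cohort):
        fit = substitution_fit(train_cohort, None, adjust_age_sex=True)
        assert fit.names[-2:] == ["age", "male"]

    def test_null_effects_cover_unity(self, null_config):
        """With no generative effects most terms' CIs should cover OR 1."""
        null_config.n = 3000
        cohort = generate_cohort(null_config)
        fit = substitution_fit(cohort, None)
        covered = sum(
            lo <= 1.0 <= hi for lo, hi in fit.ci95[1:]  # skip intercept
        )
        assert covered >= 4


class TestEnumerateExtensions:
    @pytest.fixture()
    def schemes(self):
        return {
            "ctnt": OrdinalPointScheme(variable="hs_ctnt", transform="log",
                                       thresholds=(18.0, 37.0, 68.0, 137.0)),
            "bnp": OrdinalPointScheme(variable="nt_probnp", transform="log",
                                      thresholds=(1540.0, 3500.0, 7130.0, 16230.0)),
            "af": OrdinalPointScheme(variable="af", binary=True),
        }

    def test_combinatorics(self, schemes):
        models = enumerate_extensions(schemes, weights=(1, 2, 3))
        assert len(models) == 4**3 - 1

    def test_single_scheme_single_weight(self, schemes):
        models = enumerate_extensions({"ctnt": schemes["ctnt"]}, weights=(1,))
        assert len(models) == 1

    def test_max_score_invariant(self, schemes):
        for m in enumerate_extensions(schemes, weights=(1, 2, 3)):
            expected = 24 + sum(
                (2 if s.binary else len(s.thresholds)) * s.weight for s in m.schemes
            )
            assert m.max_score == expected

    def test_deterministic_ordering(self, schemes):
        a = enumerate_extensions(schemes)
        b = enumerate_extensions(dict(reversed(list(schemes.items()))))
        assert [m.name for m in a] == [m.name for m in b]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            enumerate_extensions({})


class TestSelectBest:
    def test_identical_candidates_null_comparison(self, train_cohort):
        scheme = OrdinalPointScheme(variable="af", binary=True)
        m = enumerate_extensions({"af": scheme}, weights=(1,))[0]
        results, best = select_best(train_cohort, [m, m], k=2)
        assert results[0].auc == pytest.approx(results[1].auc)
        assert results[1].nri_vs_base.nri == pytest.approx(results[0].nri_vs_base.nri)

    def test_k_clamped(self, train_cohort, record_factory):
        scheme = OrdinalPointScheme(variable="af", binary=True)
        models = enumerate_extensions({"af": scheme}, weights=(1, 2))
        results, _ = select_best(train_cohort, models, k=10)
        assert all(r.delong_p_vs_base is not None for r in results)

    def test_true_model_ranked_first(self):
        """A candidate matching the generative truth should usually win
        against a pure-noise extension."""
        wins = 0
        reps = 20
        for seed in range(reps):
            cfg = GeneratorConfig(n=1000, seed=1000 + seed)
            cohort = generate_cohort(cfg)
            truth = enumerate_extensions(
                {
                    "ctnt": cfg.schemes["ctnt_points"],
                    "bnp": cfg.schemes["bnp_points"],
                    "af": OrdinalPointScheme(variable="af", binary=True, weight=2),
                },
                weights=(1,),
                weights_by_name={"af": (2,)},
            )[-1]  # the full three-scheme model
            noise = enumerate_extensions(
                {"hr": cfg.schemes["hr_points"]}, weights=(3,)
            )[0]
            results, best = select_best(cohort, [truth, noise], k=2)
            wins += best.name == truth.name
        assert wins >= 0.95 * reps


class TestScoreDerivationPipeline:
    def test_results_structure(self, train_cohort):
        res = ScoreDerivation(train_cohort, screen=False).fit()
        assert set(res.schemes) == {"hs_ctnt", "nt_probnp", "hr", "af"}
        assert res.schemes["hr"].max_base_points == 2  # HR capped at 0-2 points
        assert len(res.candidates) == 4 * 4 * 3 - 1  # biomarkers x {0,1,2,3}, AF x {0,1,2}
        assert res.final_model.name == res.candidates[0].model.name
        d = res.to_dict()
        assert d["final_model"]["max_score"] == res.final_model.max_score

    def test_selected_beats_base_on_training(self, train_cohort):
        res = ScoreDerivation(train_cohort, screen=False).fit()
        y = train_cohort.outcome
        from cesofa.evalstats import auc

        base_auc = auc(score_cohort(train_cohort, BASE_SOFA), y).auc
        assert res.candidates[0].auc >= base_auc

    def test_summary_renders(self, train_cohort):
        res = ScoreDerivation(train_cohort, screen=False).fit()
        text = res.summary()
        assert "Selected model" in text and "point schemes" in text
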