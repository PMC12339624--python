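import numpy as np
import pandas as pd
import pytest

from metabnet.decompose import (
    apply_exclusions,
    binarize_age,
    build_design,
    extract_diet_lifestyle_part,
    extract_time_part,
    fit_random_intercept_lmm,
    residualize_per_timepoint,
)
from metabnet.io_config import RepeatedMeasuresDataset


class TestBinarizeAge:
    @pytest.mark.parametrize("age,expected", [(49.9, 0), (50.0, 1), (74, 1), (25, 0)])
    def test_threshold_at_fifty(self, age, expected):
        assert binarize_age(age) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            binarize_age(np.nan)


def _cov_row(sid, **kw):
    row = {
        "subject_id": sid, "timepoint": 0, "age": 40.0, "sex": 0,
        "diabetes": 0, "glucose": 5.0, "ffq_complete": 1,
    }
    row.update(kw)
    return row


def _dataset(sids):
    return RepeatedMeasuresDataset(
        pd.DataFrame(
            {"subject_id": sids, "timepoint": [0] * len(sids),
             "m1": np.arange(len(sids), dtype=float)}
        )
    )


class TestExclusions:
    def test_high_glucose_excluded_boundary_retained(self):
        cov = pd.DataFrame([
            _cov_row("a", glucose=10.5),
            _cov_row("b", glucose=10.0),
            _cov_row("c", glucose=3.0, diabetes=1),
            _cov_row("d"),
        ])
        ds, report = apply_exclusions(_dataset(["a", "b", "c", "d"]), cov)
        kept = set(ds.data["subject_id"])
        assert kept == {"b", "d"}  # strict > 10; glucose exactly 10 retained
        assert report["glucose_over_10"] == 1
        assert report["diabetes"] == 1

    def test_clean_set_is_identity(self):
        cov = pd.DataFrame([_cov_row("a"), _cov_row("b")])
        ds0 = _dataset(["a", "b"])
        ds, report = apply_exclusions(ds0, cov)
        pd.testing.assert_frame_equal(ds.data, ds0.data)
        assert report["excluded_subjects"] == 0

    def test_incomplete_information_excluded(self):
        cov = pd.DataFrame([_cov_row("a", ffq_complete=0), _cov_row("b")])
        ds, _ = apply_exclusions(_dataset(["a", "b"]), cov)
        assert set(ds.data["subject_id"]) == {"b"}

    def test_missing_required_column_rejected(self):
        cov = pd.DataFrame([_cov_row("a")]).drop(columns=["glucose"])
        with pytest.raises(ValueError, match="glucose"):
            apply_exclusions(_dataset(["a"]), cov)


class TestDesign:
    def test_m6_gives_41_columns_in_block_order(self, small_study):
        # 16 coefficient blocks of Eq-style model: 11 scalar + 5 factor-wide
        from metabnet.decompose import CovariateBundle

        b = small_study.bundle
        F6 = pd.concat([b.F] * 3, axis=1)
        F6.columns = [f"F{j + 1}" for j in range(6)]
        bundle6 = CovariateBundle(
            subject_id=b.subject_id, age_years=b.age_years, sex=b.sex,
            timepoint=b.timepoint, F=F6, G=b.G,
        )
        with pytest.warns(UserWarning):  # duplicated factors are collinear
            d = build_design(bundle6, "M01")
        assert d.q == 41
        assert sorted(d.blocks) == list(range(16))

    def test_interaction_columns_are_hadamard_products(self, small_study):
        d = build_design(small_study.bundle, "M01")
        X, lab = d.X, d.labels
        age, sex, t = X[:, lab.index("b1:Age")], X[:, lab.index("b2:Sex")], X[:, lab.index("b3:T")]
        g = X[:, lab.index("b5:G")]
        f1 = X[:, lab.index("b4:F1")]
        assert np.array_equal(X[:, lab.index("b6:Age*Sex")], age * sex)
        assert np.array_equal(X[:, lab.index("b13:T*F1")], t * f1)
        assert np.array_equal(X[:, lab.index("b15:F1*G")], f1 * g)
        assert np.array_equal(X[:, lab.index("b14:T*G")], t * g)


def _balanced_sim(n_subj=150, seed=0, sigma_u=1.0, sigma_eps=0.7):
    rng = np.random.default_rng(seed)
    sid = np.repeat([f"s{i}" for i in range(n_subj)], 2)
    X = np.column_stack([np.ones(2 * n_subj), rng.standard_normal((2 * n_subj, 3))])
    beta = np.array([1.0, 0.5, -0.3, 0.2])
    u = sigma_u * rng.standard_normal(n_subj)
    y = X @ beta + np.repeat(u, 2) + sigma_eps * rng.standard_normal(2 * n_subj)
    from metabnet.decompose import DesignMatrix

    design = DesignMatrix(
        X=X, labels=["b0:intercept", "b4:F1", "b4:F2", "b4:F3"],
        blocks={0: [0], 4: [1, 2, 3]},
    )
    return y, design, sid, u


class TestRandomInterceptREML:
    def test_blup_matches_shrinkage_closed_form(self):
        y, design, sid, _ = _balanced_sim()
        fit = fit_random_intercept_lmm(y, design, sid)
        resid = y - design.X @ fit.beta_hat
        shrink = fit.sigma2_u / (fit.sigma2_u + fit.sigma2_eps / 2)
        expected = shrink * pd.Series(resid).groupby(pd.Series(sid)).mean()
        got = fit.u_hat.reindex(expected.index)
        assert np.max(np.abs(got - expected)) < 1e-6

    def test_matches_statsmodels_reml(self):
        import statsmodels.api as sm

        y, design, sid, _ = _balanced_sim(seed=3)
        fit = fit_random_intercept_lmm(y, design, sid)
        ref = sm.MixedLM(y, design.X, groups=sid).fit(reml=True)
        assert fit.sigma2_u == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), rel=1e-4)
        assert fit.sigma2_eps == pytest.approx(float(ref.scale), rel=1e-4)
        assert np.allclose(fit.beta_hat, ref.fe_params, atol=1e-5)
        assert fit.loglik == pytest.approx(float(ref.llf), abs=1e-4)

    def test_zero_between_subject_variance_detected(self):
        y, design, sid, _ = _balanced_sim(seed=5, sigma_u=0.0)
        fit = fit_random_intercept_lmm(y, design, sid)
        assert fit.sigma2_u < 0.02
        assert np.max(np.abs(fit.u_hat)) < 0.1

    def test_singular_design_lists_columns(self):
        y, design, sid, _ = _balanced_sim(n_subj=30)
        from metabnet.decompose import DesignMatrix

        X = np.column_stack([design.X, design.X[:, 1]])
        bad = DesignMatrix(X=X, labels=design.labels + ["b4:F1_copy"],
                           blocks=design.blocks)
        with pytest.raises(ValueError, match="singular design"):
            fit_random_intercept_lmm(y, bad, sid)

    def test_unbalanced_subjects_get_one_intercept_each(self, small_study, small_fits):
        fit = small_fits["M01"]
        assert len(fit.u_hat) == small_study.dataset.data["subject_id"].nunique()

    def test_lifestyle_intercepts_track_truth(self):
        # empirical Bayes intercepts are informative under the
        # random-intercepts model at study-sized conditions (364/211
        # subjects, ICC 2/3): corr(u_hat, u) ~ sqrt(n_i*lam/(1+n_i*lam))
        from metabnet.decompose import fit_metabolome
        from metabnet.simulate import simulate_metabolome, simulate_study

        study = simulate_study(seed=0)
        t = study.truth
        dataset, u_true = simulate_metabolome(
            study.bundle, t.beta_true, t.Theta_true,
            t.sigma_eps_true.to_numpy(), seed=123,
        )
        fits = fit_metabolome(dataset, study.bundle)
        cors = [
            np.corrcoef(fit.u_hat, u_true[met].reindex(fit.u_hat.index))[0, 1]
            for met, fit in fits.items()
        ]
        assert np.median(cors) >= 0.8


class TestExtraction:
    def test_brute_force_term_oracle(self, small_study, small_fits):
        bundle = small_study.bundle
        y_l = extract_diet_lifestyle_part(small_fits, bundle)
        y_t = extract_time_part(small_fits, bundle)
        for met, fit in small_fits.items():
            d = build_design(bundle, met)
            lab = d.labels
            beta = dict(zip(lab, fit.beta_hat))
            # independent recomputation, term by term from raw covariates
            age = bundle.age_binary.astype(float)
            sex = bundle.sex.astype(float)
            t = bundle.timepoint.astype(float)
            F = bundle.F.to_numpy()
            g = bundle.G[met].to_numpy()
            fn = bundle.factor_names
            exp_l = sum(
                beta[f"b4:{f}"] * F[:, j]
                + beta[f"b8:Age*{f}"] * age * F[:, j]
                + beta[f"b11:Sex*{f}"] * sex * F[:, j]
                + beta[f"b13:T*{f}"] * t * F[:, j]
                + beta[f"b15:{f}*G"] * F[:, j] * g
                for j, f in enumerate(fn)
            ) + fit.u_hat.reindex(bundle.subject_id).to_numpy()
            exp_t = (
                beta["b3:T"] * t
                + beta["b7:Age*T"] * age * t
                + beta["b10:Sex*T"] * sex * t
                + beta["b14:T*G"] * t * g
                + sum(beta[f"b13:T*{f}"] * t * F[:, j] for j, f in enumerate(fn))
            )
            assert np.max(np.abs(y_l.frame[met].to_numpy() - exp_l)) < 1e-10
            assert np.max(np.abs(y_t.frame[met].to_numpy() - exp_t)) < 1e-10

    def test_time_part_vanishes_at_baseline(self, small_study, small_fits):
        y_t = extract_time_part(small_fits, small_study.bundle)
        baseline = small_study.bundle.timepoint == 0
        assert np.allclose(y_t.values()[baseline], 0.0)

    def test_zeroed_diet_blocks_leave_only_intercepts(self, small_study, small_fits):
        import copy

        bundle = small_study.bundle
        fits0 = {}
        for met, fit in small_fits.items():
            f0 = copy.deepcopy(fit)
            for b in (4, 8, 11, 13, 15):
                f0.beta_hat[f0.blocks[b]] = 0.0
            fits0[met] = f0
        y_l = extract_diet_lifestyle_part(fits0, bundle)
        for met, fit in fits0.items():
            u_rep = fit.u_hat.reindex(bundle.subject_id).to_numpy()
            assert np.allclose(y_l.frame[met].to_numpy(), u_rep)

    def test_blocks_partition_the_linear_predictor(self, small_study, small_fits):
        # fitted values decompose exactly into the 16 coefficient blocks + u
        bundle = small_study.bundle
        met, fit = next(iter(small_fits.items()))
        d = build_design(bundle, met)
        total = d.X @ fit.beta_hat
        parts = sum(
            d.X[:, cols] @ fit.beta_hat[cols] for cols in fit.blocks.values()
        )
        assert np.max(np.abs(total - parts)) < 1e-10


class TestBenchmarkResidualization:
    def test_residuals_orthogonal_to_design(self, small_study):
        res = residualize_per_timepoint(small_study.dataset, small_study.bundle)
        for t, frame in res.items():
            rows = small_study.bundle.timepoint == t
            age = small_study.bundle.age_binary[rows].astype(float)
            sex = small_study.bundle.sex[rows].astype(float)
            X = np.column_stack([np.ones(rows.sum()), age, sex, age * sex])
            proj = X.T @ frame.to_numpy()
            assert np.max(np.abs(proj)) < 1e-8

    def test_signal_linear_in_age_residualizes_to_zero(self):
        from metabnet.decompose import CovariateBundle

        n = 40
        rng = np.random.default_rng(0)
        sids = [f"s{i}" for i in range(n)]
        age = rng.uniform(25, 74, n)
        ds = RepeatedMeasuresDataset(
            pd.DataFrame(
                {"subject_id": sids, "timepoint": 0,
                 "m1": 2.0 + 3.0 * (age >= 50)}
            )
        )
        bundle = CovariateBundle(
            subject_id=np.array(sids), age_years=age,
            sex=np.zeros(n, int), timepoint=np.zeros(n, int),
            F=pd.DataFrame({"F1": np.zeros(n)}),
            G=pd.DataFrame({"m1": np.zeros(n)}),
        )
        res = residualize_per_timepoint(ds, bundle)
        assert np.max(np.abs(res[0].to_numpy())) < 1e-10

    def test_too_few_observations_rejected(self):
        from metabnet.decompose import CovariateBundle

        ds = _dataset(["a", "b", "c"])
        bundle = CovariateBundle(
            subject_id=np.array(["a", "b", "c"]),
            age_years=np.array([30.0, 40.0, 60.0]),
            sex=np.zeros(3, int), timepoint=np.zeros(3, int),
            F=pd.DataFrame({"F1": np.zeros(3)}),
            G=pd.DataFrame({"m1": np.zeros(3)}),
        )
        with pytest.raises(ValueError, match=">= 5"):
            residualize_per_timepoint(ds, bundle)
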