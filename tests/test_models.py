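"""Mixed-model machinery: design building, ML fits, autocorrelation term,
likelihood-ratio inference."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from routescape.models import (ModelSpec, autocorr_term, build_design,
                               drop1_tests, fit_mixed, lrt, optimize_D)


def logistic_data(seed, n=2000, G=5, beta=(0.2, 1.0, -0.5), u_sd=0.4):
    rg = np.random.default_rng(seed)
    g = np.repeat(np.arange(G), n // G)
    u = rg.normal(0, u_sd, G)
    x1, x2 = rg.normal(size=n), rg.normal(size=n)
    eta = beta[0] + beta[1] * x1 + beta[2] * x2 + u[g]
    y = (rg.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(dict(y=y, x1=x1, x2=x2, g=g))


class TestDesign:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main effects"):
            ModelSpec("y", ("a", "a:b"), "g")

    def test_missing_column_named(self):
        spec = ModelSpec("y", ("nope",), "g")
        df = pd.DataFrame(dict(y=[0, 1], g=["a", "b"]))
        with pytest.raises(KeyError, match="nope"):
            build_design(spec, df)

    def test_standardization_skips_binaries(self, rng):
        df = pd.DataFrame(dict(y=rng.normal(size=50),
                               cont=rng.normal(10, 3, 50),
                               flag=rng.integers(0, 2, 50),
                               g=rng.integers(0, 2, 50)))
        spec = ModelSpec("y", ("cont", "flag"), "g", standardize=True)
        _, X, names, *_ = build_design(spec, df)
        cont = X[:, names.index("cont")]
        flag = X[:, names.index("flag")]
        assert abs(cont.mean()) < 1e-9 and cont.std() == pytest.approx(1.0)
        assert set(np.unique(flag)) <= {0.0, 1.0}

    def test_sqrt_transform_applied(self, rng):
        df = pd.DataFrame(dict(y=rng.normal(size=30),
                               s=rng.uniform(0, 40, 30),
                               g=rng.integers(0, 2, 30)))
        spec = ModelSpec("y", ("sqrt(s)",), "g", standardize=False)
        _, X, names, *_ = build_design(spec, df)
        assert np.allclose(X[:, names.index("sqrt(s)")], np.sqrt(df.s))


class TestGaussian:
    def test_zero_group_variance_matches_ols(self, rng):
        import statsmodels.api as sm
        n = 400
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = 1.0 + 0.5 * x1 - 0.3 * x2 + rng.normal(0, 1, n)
        df = pd.DataFrame(dict(y=y, x1=x1, x2=x2,
                               g=np.repeat(np.arange(5), n // 5)))
        fit = fit_mixed(ModelSpec("y", ("x1", "x2"), "g", random_slopes=(),
                                  standardize=False), df)
        ols = sm.OLS(y, sm.add_constant(np.column_stack([x1, x2]))).fit()
        assert np.allclose(fit.params.estimate.to_numpy(),
                           np.asarray(ols.params), rtol=1e-3, atol=1e-3)

    def test_buffer_count_model_shape_runs(self):
        # 4 groups x 4 buffers x 2 location types (32 rows)
        rows = []
        rg = np.random.default_rng(0)
        for g in range(4):
            for b in (5, 10, 15, 20):
                real = 20 + 2.0 * b + rg.normal(0, 3)
                rows.append(dict(g=g, buffer_m=b, type_real=1, n=real + 8))
                rows.append(dict(g=g, buffer_m=b, type_real=0, n=real))
        df = pd.DataFrame(rows)
        fit = fit_mixed(ModelSpec("n", ("type_real", "buffer_m"), "g",
                                  standardize=False), df)
        assert np.isfinite(fit.loglik)
        assert fit.coef("type_real") > 0


class TestBinomial:
    def test_recovers_known_coefficients(self):
        fits = [fit_mixed(ModelSpec("y", ("x1", "x2"), "g", random_slopes=(),
                                    family="binomial", standardize=False),
                          logistic_data(seed)) for seed in range(6)]
        b1 = np.mean([f.coef("x1") for f in fits])
        b2 = np.mean([f.coef("x2") for f in fits])
        assert b1 == pytest.approx(1.0, abs=0.1)
        assert b2 == pytest.approx(-0.5, abs=0.1)

    def test_agrees_with_lme4_glmer(self, tmp_path):
        """Independent oracle: the same model fitted by lme4's Laplace ML."""
        df = logistic_data(7, n=600, G=4)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'library(lme4)\n'
            f'd <- read.csv("{csv}")\n'
            'm <- glmer(y ~ x1 + x2 + (1|g), data=d, family=binomial)\n'
            'cat(paste(c(fixef(m), as.numeric(logLik(m))), collapse=","))\n'
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        fit = fit_mixed(ModelSpec("y", ("x1", "x2"), "g", random_slopes=(),
                                  family="binomial", standardize=False), df)
        assert np.allclose(fit.params.estimate.to_numpy(), ref[:3], atol=0.02)
        assert fit.loglik == pytest.approx(ref[3], abs=0.05)

    def test_non_binary_response_rejected(self):
        df = logistic_data(0, n=100)
        df["y"] = df["y"] + 0.5
        with pytest.raises(ValueError, match="0/1"):
            fit_mixed(ModelSpec("y", ("x1",), "g", family="binomial"), df)


class TestAutocorr:
    def test_constant_residuals_give_constant(self, rng):
        e = np.full(20, 3.14)
        xy = rng.uniform(0, 50, (20, 2))
        ac = autocorr_term(e, xy, np.zeros(20), D=5.0)
        assert np.allclose(ac, 3.14)

    def test_large_D_limit_is_leave_one_out_mean(self, rng):
        e = rng.normal(size=15)
        xy = rng.uniform(0, 30, (15, 2))
        ac = autocorr_term(e, xy, np.zeros(15), D=1e6)
        loo = (e.sum() - e) / (len(e) - 1)
        assert np.allclose(ac, loo, atol=1e-6)

    def test_two_point_exchange(self):
        ac = autocorr_term(np.array([1.0, -1.0]),
                           np.array([[0.0, 0.0], [3.0, 0.0]]),
                           ["a", "a"], D=5.0)
        assert np.allclose(ac, [-1.0, 1.0])

    def test_singleton_group_gets_zero(self):
        ac = autocorr_term(np.array([2.0, 1.0, -1.0]),
                           np.array([[0, 0], [1, 1], [2, 0]], dtype=float),
                           ["solo", "pair", "pair"], D=4.0)
        assert ac[0] == 0.0

    def test_rigid_motion_invariance(self, rng):
        e = rng.normal(size=25)
        xy = rng.uniform(0, 40, (25, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = xy @ R.T + [123.0, -77.0]
        a = autocorr_term(e, xy, np.zeros(25), D=6.0)
        b = autocorr_term(e, moved, np.zeros(25), D=6.0)
        assert np.allclose(a, b)

    def test_single_point_grid_returns_it(self, rng):
        df = pd.DataFrame(dict(y=rng.normal(size=60),
                               x=rng.uniform(0, 50, 60),
                               yy=rng.uniform(0, 50, 60),
                               g=np.repeat([0, 1], 30)))
        spec = ModelSpec("y", (), "g", random_slopes=(), standardize=False)
        D, fit, prof = optimize_D(spec, df, D_grid=[4.0], coord_cols=("x", "yy"))
        assert D == 4.0 and len(prof) == 1


class TestInference:
    def test_identical_fits_give_null_result(self):
        df = logistic_data(1, n=500)
        spec = ModelSpec("y", ("x1",), "g", random_slopes=(),
                         family="binomial", standardize=False)
        fit = fit_mixed(spec, df)
        chi2, dof, p = lrt(fit, fit)
        assert chi2 == 0.0 and p == 1.0

    def test_planted_strong_effect_detected(self):
        hits = 0
        for seed in range(5):
            df = logistic_data(seed + 20, n=1500, beta=(0.0, 1.2, 0.0))
            full = fit_mixed(ModelSpec("y", ("x1",), "g", random_slopes=(),
                                       family="binomial", standardize=False), df)
            null = fit_mixed(ModelSpec("y", (), "g", random_slopes=(),
                                       family="binomial", standardize=False), df)
            _, _, p = lrt(full, null)
            hits += p < 0.001
        assert hits == 5

    def test_drop1_respects_marginality(self, rng):
        n = 600
        df = pd.DataFrame(dict(
            a=rng.normal(size=n), b=rng.normal(size=n),
            c=rng.normal(size=n), g=np.repeat(np.arange(3), n // 3)))
        df["y"] = (rng.random(n) < 0.5).astype(int)
        spec = ModelSpec("y", ("a", "b", "c", "a:b"), "g", random_slopes=(),
                         family="binomial", standardize=False)
        out = drop1_tests(spec, df)
        tested = set(out.term)
        assert "a:b" in tested and "c" in tested
        assert "a" not in tested and "b" not in tested  # shielded mains
        assert out.term.iloc[0] == "a:b"  # interaction first
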