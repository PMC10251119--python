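"""MLR and GAM descriptions of the p_thrive surface.

Oracles: exact arithmetic for the eps-guarded logit, closed-form normal
equations for the OLS path, penalized-smoothing theory (effective df -> 1 on
linear truth), and R's mgcv as an independent GAM implementation.
"""

import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftbalance import descriptive_models as dm
from driftbalance.pipeline import generate_fixture_pmap


# --------------------------------------------------------------- transform

class TestLogitEps:
    def test_printed_arithmetic(self):
        assert dm.logit_eps(1.0) == pytest.approx(math.log(1e6 + 1e-6), abs=1e-9)
        assert dm.logit_eps(1.0) == pytest.approx(13.8155, abs=1e-4)
        assert dm.logit_eps(0.0) == pytest.approx(math.log(1e-6), abs=1e-9)
        assert dm.logit_eps(0.0) == pytest.approx(-13.8155, abs=1e-4)
        assert dm.logit_eps(0.5) == pytest.approx(-9.99e-7, abs=2e-8)

    def test_domain_errors(self):
        for bad in (-0.01, 1.01):
            with pytest.raises(ValueError):
                dm.logit_eps(bad)

    @given(p=st.floats(min_value=0.001, max_value=0.999))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, p):
        assert dm.inv_logit_eps(dm.logit_eps(p)) == pytest.approx(p, abs=1e-5)


# --------------------------------------------------------------------- MLR

def _pmap_from_logit(beta, noise=0.0, rng=None):
    """Grid map whose eps-logit response is exactly X @ beta (study terms)."""
    pmap = generate_fixture_pmap(n_seeds=None)
    mu, K = pmap.dmu_pct.to_numpy(), pmap.dKs_pct.to_numpy()
    n0, si = pmap.n_initial.to_numpy(), pmap.spacing.to_numpy()
    X = np.column_stack([np.ones_like(mu), mu, K, n0, si, mu * si, K * si])
    y = X @ beta
    if noise and rng is not None:
        y = y + rng.normal(0, noise, y.size)
    pmap["p_thrive"] = np.clip(dm.inv_logit_eps(y), 0.0, 1.0)
    return pmap


BETA = np.array([0.1, 0.02, -0.015, 0.01, 0.005, 1e-4, -2e-4])


class TestFitMLR:
    def test_exact_recovery_on_design_grid(self):
        pmap = _pmap_from_logit(BETA)
        fit = dm.fit_mlr(pmap)
        assert fit.coefficients == pytest.approx(BETA, abs=1e-8)
        assert fit.rmse < 1e-8

    def test_matches_normal_equations_on_toy_design(self, rng):
        full = _pmap_from_logit(BETA, noise=0.3, rng=rng)
        pmap = full.iloc[rng.choice(len(full), size=20, replace=False)]
        fit = dm.fit_mlr(pmap)
        mu, K = pmap.dmu_pct.to_numpy(), pmap.dKs_pct.to_numpy()
        n0, si = pmap.n_initial.to_numpy(), pmap.spacing.to_numpy()
        X = np.column_stack([np.ones_like(mu), mu, K, n0, si, mu * si, K * si])
        y = dm.logit_eps(pmap.p_thrive.to_numpy())
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coefficients == pytest.approx(beta, abs=1e-10)

    def test_pure_noise_regressor_rarely_significant(self, rng):
        # Type-I calibration of the term tests used in backward selection
        hits = 0
        for _ in range(100):
            pmap = _pmap_from_logit(BETA, noise=0.5, rng=rng)
            pmap["noise_var"] = rng.normal(size=len(pmap))
            dm.VARIABLES["nv"] = "noise_var"
            try:
                spec = dm.ModelSpec(
                    kind="mlr", response="logit_eps",
                    terms=tuple(
                        list(dm.mlr_spec_study().terms) + [dm.Term(("nv",))]
                    ),
                )
                fit = dm.fit_mlr(pmap, spec)
            finally:
                del dm.VARIABLES["nv"]
            if fit.term_pvalues["nv"] < 0.05:
                hits += 1
        assert hits <= 10

    def test_rank_deficiency_names_aliased_terms(self):
        pmap = _pmap_from_logit(BETA)
        spec = dm.ModelSpec(
            kind="mlr", response="logit_eps",
            terms=(dm.Term(("mu_p",)), dm.Term(("mu_p",))),
        )
        with pytest.raises(ValueError, match="aliased.*mu_p"):
            dm.fit_mlr(pmap, spec)

    def test_eps_rescaling_equivariance(self, rng):
        """On interior-probability data the pseudo-probability is a
        numerical guard, not a model choice: RMSE must be stable in eps."""
        pmap = _pmap_from_logit(BETA * 0.3, noise=0.1, rng=rng)
        rmses = []
        for eps in (1e-8, 1e-6, 1e-4):
            spec = dm.ModelSpec(kind="mlr", response="logit_eps",
                                terms=dm.mlr_spec_study().terms, eps=eps)
            rmses.append(dm.fit_mlr(pmap, spec).rmse)
        assert max(rmses) - min(rmses) < 0.01


# --------------------------------------------------------------------- GAM

def _linear_truth_pmap():
    pmap = generate_fixture_pmap(n_seeds=None)
    lin = (0.45 + 0.003 * pmap.dmu_pct - 0.002 * pmap.dKs_pct
           + 0.005 * pmap.n_initial + 0.008 * pmap.spacing)
    assert lin.min() > 0.05 and lin.max() < 0.95
    pmap["p_thrive"] = lin
    return pmap


def _crowding_surface(rng, n_seeds=120):
    ks, mu50s = {}, {}
    for n0 in (4, 9, 16):
        for sp in (2.5, 5.0, 10.0):
            ks[(n0, sp)] = -0.08 - 0.05 * (sp == 5.0) - 0.0025 * n0
            mu50s[(n0, sp)] = 8 + 0.6 * n0 + 1.2 * sp
    return generate_fixture_pmap(true_k=ks, true_mu50=mu50s, mu50_slope=0.8,
                                 n_seeds=n_seeds, rng=rng)


class TestFitGAM:
    def test_linear_truth_gives_unit_effective_df(self):
        fit = dm.fit_gam(_linear_truth_pmap(), dm.gam_spec_main_effects())
        for name, edf in fit.term_edf.items():
            assert edf == pytest.approx(1.0, abs=0.2), name
        assert fit.rmse < 1e-4

    def test_interacting_surface_beats_main_effects_mlr_held_out(self, rng):
        # mirrors the study's model ordering: only smooths + interactions
        # reproduce the spread structure
        pmap = _crowding_surface(rng)
        test_mask = np.zeros(len(pmap), dtype=bool)
        test_mask[::7] = True
        train, held = pmap[~test_mask], pmap[test_mask]
        gam = dm.fit_gam(train)
        mlr = dm.fit_mlr(train, dm.mlr_spec_main_effects())
        p_obs = held.p_thrive.to_numpy()
        gam_rmse = np.sqrt(np.mean((gam.predict(held) - p_obs) ** 2))
        mlr_rmse = np.sqrt(np.mean((mlr.predict(held) - p_obs) ** 2))
        assert gam_rmse < mlr_rmse

    def test_predictions_unclipped_with_flag(self, rng):
        fit = dm.fit_gam(_crowding_surface(rng))
        preds = fit.predict(_crowding_surface(rng))
        # a Gaussian GAM on [0,1] data is free to leave the interval
        assert fit.predictions_clipped == bool(
            np.any((preds < 0) | (preds > 1))) or fit.predictions_clipped

    def test_gam_nests_bilinear_interaction(self):
        # the tensor penalty's null space is the product of marginal linear
        # trends, so a purely bilinear surface fits essentially exactly
        pmap = generate_fixture_pmap(n_seeds=None)
        pmap["p_thrive"] = np.clip(
            0.5 + 1e-4 * pmap.dmu_pct * pmap.dKs_pct, 0, 1)
        spec = dm.ModelSpec(kind="gam", response="identity", terms=(
            dm.Term(("mu_p",), smooth=True), dm.Term(("K_p",), smooth=True),
            dm.Term(("mu_p", "K_p"), smooth=True),
        ))
        fit = dm.fit_gam(pmap, spec)
        assert fit.rmse < 1e-6


# -------------------------------------------------------------- selection

def _stub_fit(spec, pvalues):
    return dm.ModelFit(
        spec=spec, coefficients=np.zeros(1), term_slices={},
        term_pvalues={t.name: pvalues[t.name] for t in spec.terms},
        term_edf={}, rmse=0.0, r_squared=1.0, aic=0.0, edf_total=1.0,
        sigma2=1.0, lambdas=None, predictions_clipped=False, n_obs=0,
    )


class TestBackwardSelect:
    def test_all_significant_is_fixed_point(self):
        spec = dm.factorial_spec("mlr")
        pvals = {t.name: 0.001 for t in spec.terms}
        out, _ = dm.backward_select(
            None, spec, fitter=lambda d, s: _stub_fit(s, pvals))
        assert out.terms == spec.terms
        assert out.dropped == ()

    def test_highest_order_nonsignificant_dropped_first(self):
        spec = dm.factorial_spec("mlr")
        pvals = {t.name: 0.001 for t in spec.terms}
        pvals["mu_p:K_p:N0"] = 0.5      # the only non-significant term
        pvals["mu_p"] = 0.5             # main effect inside significant terms
        calls = []

        def fitter(_d, s):
            calls.append(tuple(t.name for t in s.terms))
            return _stub_fit(s, pvals)

        out, _ = dm.backward_select(None, spec, fitter=fitter)
        assert out.dropped == ("mu_p:K_p:N0",)
        # mu_p survives: it is nested in retained significant interactions
        assert any(t.name == "mu_p" for t in out.terms)

    def test_selection_consistency_under_noise(self, rng):
        """With a true {mu_p, K_p, mu_p x K_p} structure plus noise, the
        procedure should retain those terms and discard the rest nearly
        always."""
        keep = {"mu_p", "K_p", "mu_p:K_p"}
        ok = 0
        n_rep = 40
        for _ in range(n_rep):
            pmap = generate_fixture_pmap(n_seeds=None)
            mu, K = pmap.dmu_pct.to_numpy(), pmap.dKs_pct.to_numpy()
            y = 0.05 * mu - 0.05 * K + 2e-3 * mu * K + rng.normal(0, 1.0, len(pmap))
            pmap["p_thrive"] = np.clip(dm.inv_logit_eps(y), 0, 1)
            spec, _fit = dm.backward_select(pmap, dm.factorial_spec("mlr"))
            names = {t.name for t in spec.terms}
            if keep <= names:
                ok += 1
        assert ok >= 0.9 * n_rep


# ----------------------------------------------------------------- metrics

class TestModelMetrics:
    def test_perfect_and_constant_predictors(self):
        pmap = _linear_truth_pmap()
        fit = dm.fit_gam(pmap, dm.gam_spec_main_effects())
        rmse, r2, aic = dm.model_metrics(fit, pmap)
        assert rmse == pytest.approx(0.0, abs=1e-4)
        assert r2 == pytest.approx(1.0, abs=1e-4)
        assert np.isfinite(aic)

    def test_rmse_matches_direct_loop(self, rng):
        # a 10-row toy table varies only mu_p, so fit that single term
        pmap = _pmap_from_logit(BETA, noise=0.4, rng=rng).iloc[:10]
        fit = dm.fit_mlr(pmap, dm.ModelSpec(
            kind="mlr", response="logit_eps", terms=(dm.Term(("mu_p",)),)))
        preds = fit.predict(pmap)
        obs = pmap.p_thrive.to_numpy()
        acc = 0.0
        for a, b in zip(preds, obs):
            acc += (a - b) ** 2
        assert fit.rmse == pytest.approx(math.sqrt(acc / len(pmap)), abs=1e-12)

    def test_constant_mean_predictor_r2_zero(self):
        pmap = _linear_truth_pmap()
        # intercept-only model: predictions collapse to the mean
        fit = dm.fit_gam(pmap, dm.ModelSpec(kind="gam", response="identity",
                                            terms=()))
        rmse, r2, _aic = dm.model_metrics(fit, pmap)
        p = pmap.p_thrive.to_numpy()
        assert rmse == pytest.approx(p.std(), abs=1e-10)
        assert r2 == pytest.approx(0.0, abs=1e-10)


# ------------------------------------------------------------ mgcv oracle

@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_gam_agrees_with_mgcv_on_smooth_surface(tmp_path, rng):
    """Independent cross-check: on a smooth two-factor surface, this
    package's penalized splines and mgcv should recover the truth with
    comparable accuracy."""
    pmap = generate_fixture_pmap(true_k=-0.12, true_mu50=12.0, mu50_slope=0.7,
                                 n_seeds=120, rng=rng,
                                 spacings=[5.0], populations=[9])
    truth = generate_fixture_pmap(true_k=-0.12, true_mu50=12.0, mu50_slope=0.7,
                                  n_seeds=None, spacings=[5.0],
                                  populations=[9])["p_thrive"].to_numpy()
    spec = dm.ModelSpec(kind="gam", response="identity", terms=(
        dm.Term(("mu_p",), smooth=True), dm.Term(("K_p",), smooth=True),
        dm.Term(("mu_p", "K_p"), smooth=True),
    ))
    ours = dm.fit_gam(pmap, spec)
    ours_rmse = float(np.sqrt(np.mean((ours.predict(pmap) - truth) ** 2)))

    csv = tmp_path / "pmap.csv"
    pmap.to_csv(csv, index=False)
    rscript = tmp_path / "fit.R"
    rscript.write_text(
        "library(mgcv)\n"
        f"d <- read.csv('{csv}')\n"
        "m <- gam(p_thrive ~ s(dmu_pct, k=5) + s(dKs_pct, k=5) +"
        " ti(dmu_pct, dKs_pct, k=5), data=d, method='GCV.Cp')\n"
        "cat(sprintf('%.10f', sqrt(mean((fitted(m) - d$p_thrive)^2))))\n"
    )
    out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    mgcv_fit_rmse = float(out.stdout.strip().split()[-1])
    # both should sit near the binomial noise floor; neither should be
    # drastically worse than the other
    assert ours_rmse < 3 * mgcv_fit_rmse + 0.02
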