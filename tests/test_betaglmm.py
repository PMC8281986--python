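"""Beta mixed-model likelihood and fitting: oracles and recovery."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import betaln, expit, logsumexp

from reachkin.betaglmm import (
    ModelSpec,
    _FitData,
    _marginal_loglik,
    beta_glmm_loglik,
    fit_ladder,
    fit_model,
    model_ladder,
)
from reachkin.session import BetaGlmmParams, gen_tpv_dataset


@pytest.fixture(scope="module")
def toy_table():
    rng = np.random.default_rng(1)
    return pd.DataFrame(dict(
        participant=["a"] * 3 + ["b"] * 3,
        condition=["dominant", "non-dominant", "dominant"] * 2,
        srt_ms=rng.uniform(0, 2000, 6),
        tpv=rng.uniform(0.2, 0.7, 6),
    ))


def _grid_loglik(beta, sigma, phi, data, half_width=8.0, n_grid=40001):
    """Independent dense-grid integration of the random intercept."""
    total = 0.0
    bgrid = np.linspace(-half_width * sigma, half_width * sigma, n_grid)
    db = bgrid[1] - bgrid[0]
    for g in range(data.n_groups):
        m = data.group_idx == g
        eta = data.X[m] @ beta
        mu = expit(eta[:, None] + bgrid[None, :])
        a1, a2 = mu * phi, (1 - mu) * phi
        ll = ((a1 - 1) * np.log(data.y[m])[:, None]
              + (a2 - 1) * np.log1p(-data.y[m])[:, None]
              - betaln(a1, a2)).sum(axis=0)
        lp = -0.5 * (bgrid / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        total += logsumexp(ll + lp) + np.log(db)
    return total


class TestMarginalLikelihood:
    def test_quadrature_matches_dense_grid(self, toy_table):
        beta = np.array([-0.3, 0.2])
        sigma, phi = 0.35, 9.0
        data = _FitData(toy_table, ModelSpec("mb1"))
        ll_q, _ = _marginal_loglik(beta, sigma, phi, data, order=15)
        ll_g = _grid_loglik(beta, sigma, phi, data)
        assert ll_q == pytest.approx(ll_g, abs=1e-6)

    def test_zero_random_effect_equals_plain_beta_regression(self, toy_table):
        from scipy.stats import beta as beta_dist
        beta = np.array([-0.3, 0.2])
        phi = 9.0
        ll0 = beta_glmm_loglik(beta, 0.0, phi, toy_table, "mb1")
        data = _FitData(toy_table, ModelSpec("mb1"))
        mu = expit(data.X @ beta)
        ref = beta_dist.logpdf(data.y, mu * phi, (1 - mu) * phi).sum()
        assert ll0 == pytest.approx(ref, abs=1e-10)

    def test_small_sigma_limit_is_continuous(self, toy_table):
        beta = np.array([-0.3, 0.2])
        ll0 = beta_glmm_loglik(beta, 0.0, 9.0, toy_table, "mb1")
        ll_eps = beta_glmm_loglik(beta, 1e-4, 9.0, toy_table, "mb1")
        assert ll_eps == pytest.approx(ll0, abs=1e-3)

    def test_per_observation_loglik_near_generating_entropy(self):
        """At the generating parameters, the average per-trial log-likelihood
        of two independent simulated studies agrees within Monte-Carlo error."""
        glmm = BetaGlmmParams()
        spec = ModelSpec("mb1")
        beta = np.array([glmm.intercept, glmm.beta_condition])
        vals = []
        for seed in (21, 22):
            tab = gen_tpv_dataset(glmm, 19, 150, seed=seed)
            data = _FitData(tab, spec, srt_center=glmm.srt_center_ms,
                            srt_scale=glmm.srt_scale_ms)
            ll, _ = _marginal_loglik(beta, glmm.sigma_b, glmm.phi, data, order=15)
            vals.append(ll / data.y.size)
        assert abs(vals[0] - vals[1]) < 0.05

    def test_rejects_boundary_responses(self, toy_table):
        bad = toy_table.copy()
        bad.loc[0, "tpv"] = 1.0
        with pytest.raises(ValueError):
            beta_glmm_loglik(np.array([-0.3, 0.2]), 0.2, 9.0, bad, "mb1")


class TestModelLadder:
    def test_parameter_counts(self):
        assert [s.k for s in model_ladder()] == [3, 4, 5, 6]

    def test_fit_reports_ladder_k(self, toy_table):
        tab = gen_tpv_dataset(BetaGlmmParams(), 6, 40, seed=2)
        fits = fit_ladder(tab, order=9, extra_starts=False)
        assert [f.k for f in fits] == [3, 4, 5, 6]
        assert all(f.n == len(tab) for f in fits)

    def test_nesting_logliks_are_monotone(self):
        tab = gen_tpv_dataset(BetaGlmmParams(beta_srt=0.05), 8, 60, seed=3)
        fits = fit_ladder(tab, order=9, extra_starts=False)
        lls = [f.loglik for f in fits]
        for lo, hi in zip(lls[:-1], lls[1:]):
            assert hi >= lo - 1e-4


class TestFitRecovery:
    def test_single_study_recovers_generating_parameters(self):
        glmm = BetaGlmmParams()
        tab = gen_tpv_dataset(glmm, 19, 150, seed=3)
        f = fit_model("mb1", tab, compute_cov=True)
        assert f.converged
        assert f.beta[0] == pytest.approx(glmm.intercept, abs=3 * f.beta_se[0])
        assert f.beta[1] == pytest.approx(glmm.beta_condition, abs=3 * f.beta_se[1])
        assert f.sigma_b == pytest.approx(glmm.sigma_b, abs=0.12)
        assert f.phi == pytest.approx(glmm.phi, rel=0.15)

    def test_wald_table_shape(self):
        tab = gen_tpv_dataset(BetaGlmmParams(), 6, 40, seed=4)
        f = fit_model("mb2", tab, order=9, compute_cov=True, extra_starts=False)
        wt = f.wald_table()
        assert list(wt["term"]) == ["intercept", "condition", "srt_z"]
        assert ((wt["p"] >= 0) & (wt["p"] <= 1)).all()


def test_model_selection_prefers_generating_model():
    """On data simulated from the additive model (condition + foreperiod)
    with moderate effects at 19 participants × 150 trials, mb2 takes the
    largest Akaike weight in the majority of 100 seeds."""
    from reachkin.compare import akaike_weights

    glmm = BetaGlmmParams(beta_srt=0.08)
    wins = 0
    for seed in range(100):
        tab = gen_tpv_dataset(glmm, 19, 150, seed=40_000 + seed)
        fits = fit_ladder(tab, order=7, compute_cov=False, extra_starts=False)
        w = akaike_weights([f.aicc for f in fits])
        wins += int(np.argmax(w)) == 2
    assert wins > 50


def test_matches_glmmtmb_reference():
    """Independent cross-check: glmmTMB (R) on the same simulated table."""
    tab = gen_tpv_dataset(BetaGlmmParams(), 10, 40, seed=11)
    f = fit_model("mb1", tab, order=15)

    import tempfile, os
    with tempfile.TemporaryDirectory() as d:
        csv = os.path.join(d, "tab.csv")
        tab.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv("{csv}")
            d$condition <- relevel(factor(d$condition), ref="dominant")
            m <- glmmTMB(tpv ~ condition + (1|participant),
                         family=beta_family(), data=d)
            cat(as.numeric(logLik(m)), fixef(m)$cond, sigma(m), "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", rscript], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ll_r, b0_r, b1_r, phi_r = map(float, out.stdout.split())

    # glmmTMB uses the Laplace approximation; tolerances reflect that
    assert f.loglik == pytest.approx(ll_r, abs=0.1)
    assert f.beta[0] == pytest.approx(b0_r, abs=0.01)
    assert f.beta[1] == pytest.approx(b1_r, abs=0.01)
    assert f.phi == pytest.approx(phi_r, rel=0.02)
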