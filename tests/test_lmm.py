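"""The REML/ML engine: closed-form reductions, oracle and library checks."""

import numpy as np
import pandas as pd
import pytest

from titplayback import fit_lmm_arrays
from titplayback.lmm import ConvergenceError

from oracles import brute_force_reml, reml_loglik_direct


def _simulate(seed, n=60, n_male=12, n_play=4, beta=(1.0, 0.5, -0.3),
              sd_male=0.7, sd_play=0.5, sd_resid=0.6):
    rng = np.random.default_rng(seed)
    male = rng.integers(0, n_male, n)
    play = rng.integers(0, n_play, n)
    X = np.column_stack([np.ones(n), rng.normal(size=n), rng.integers(0, 2, n)])
    y = (
        X @ np.asarray(beta)
        + sd_male * rng.standard_normal(n_male)[male]
        + sd_play * rng.standard_normal(n_play)[play]
        + sd_resid * rng.standard_normal(n)
    )
    return y, X, male, play


def test_no_random_terms_reduces_to_ols():
    y, X, *_ = _simulate(0)
    fit = fit_lmm_arrays(y, X, ["b0", "b1", "b2"], {})
    ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    np.testing.assert_allclose(fit.params.to_numpy(), ols, rtol=1e-10)
    resid = y - X @ ols
    np.testing.assert_allclose(fit.sigma2, resid @ resid / (len(y) - 3), rtol=1e-10)


def test_zero_variance_truth_estimated_at_boundary():
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits may warn as singular
        ests = []
        for seed in (1, 21, 31):
            y, X, male, play = _simulate(seed, n=200, sd_male=0.0)
            fit = fit_lmm_arrays(y, X, ["b0", "b1", "b2"],
                                 {"male": male, "play": play})
            ests.append(fit.varcomps["male"])
    assert np.median(ests) < 0.02
    assert min(ests) < 1e-4


def test_matches_statsmodels_mixedlm():
    """Independent library cross-check on a crossed-intercepts fixture."""
    import statsmodels.api as sm

    y, X, male, play = _simulate(2, n=120)
    fit = fit_lmm_arrays(y, X, ["b0", "b1", "b2"], {"male": male, "play": play})
    df = pd.DataFrame(
        {"y": y, "x1": X[:, 1], "x2": X[:, 2], "male": male, "play": play, "g": 1}
    )
    md = sm.MixedLM.from_formula(
        "y ~ x1 + x2", groups="g",
        vc_formula={"male": "0 + C(male)", "play": "0 + C(play)"}, data=df,
    )
    ref = md.fit(reml=True)
    np.testing.assert_allclose(fit.params.to_numpy(), ref.fe_params.values, rtol=1e-5)
    np.testing.assert_allclose(
        sorted(fit.varcomps.values()), sorted(ref.vcomp), rtol=1e-3, atol=1e-5
    )
    np.testing.assert_allclose(fit.sigma2, ref.scale, rtol=1e-5)
    np.testing.assert_allclose(fit.loglik, ref.llf, rtol=1e-8)


@pytest.mark.parametrize("seed", [3, 4, 5, 6, 7])
@pytest.mark.parametrize("method", ["reml", "ml"])
def test_matches_brute_force_maximizer(seed, method):
    """Profiled fit equals direct maximization of the unprofiled criterion."""
    y, X, male, play = _simulate(seed)
    fit = fit_lmm_arrays(y, X, ["b0", "b1", "b2"], {"male": male, "play": play},
                         method=method)
    beta, sigma2, comps, ll = brute_force_reml(y, X, [male, play], method=method)
    tol = 1e-4
    assert np.all(
        np.abs(fit.params.to_numpy() - beta) <= tol * np.maximum(np.abs(beta), 1.0)
    )
    impl = [fit.sigma2, fit.varcomps["male"], fit.varcomps["play"]]
    orac = [sigma2] + comps
    assert np.all(np.abs(np.array(impl) - orac) <= tol * np.maximum(np.abs(orac), 1.0))
    assert fit.loglik == pytest.approx(ll, abs=1e-6)


def test_loglik_at_optimum_consistent_with_direct_formula():
    y, X, male, play = _simulate(8)
    fit = fit_lmm_arrays(y, X, ["b0", "b1", "b2"], {"male": male, "play": play})
    Zs = []
    for codes in (male, play):
        Z = np.zeros((len(codes), codes.max() + 1))
        Z[np.arange(len(codes)), codes] = 1.0
        Zs.append(Z)
    direct = reml_loglik_direct(
        [fit.sigma2, fit.varcomps["male"], fit.varcomps["play"]], y, X, Zs
    )
    assert fit.loglik == pytest.approx(direct, abs=1e-8)


def test_extra_df_inflates_se_only():
    y, X, male, play = _simulate(9)
    base = fit_lmm_arrays(y, X, ["b0", "b1", "b2"], {"male": male, "play": play})
    adj = fit_lmm_arrays(y, X, ["b0", "b1", "b2"], {"male": male, "play": play},
                         extra_df=20)
    np.testing.assert_allclose(base.params, adj.params, rtol=1e-12)
    n, p = X.shape
    factor = np.sqrt((n - p) / (n - p - 20))
    np.testing.assert_allclose(adj.se, base.se * factor, rtol=1e-10)
    assert adj.df_resid == base.df_resid - 20
    assert adj.loglik == pytest.approx(base.loglik)


def test_input_validation():
    y, X, male, play = _simulate(10)
    with pytest.raises(ValueError, match="2 levels"):
        fit_lmm_arrays(y, X, ["b0", "b1", "b2"], {"male": np.zeros(len(y), int)})
    Xbad = np.column_stack([X, X[:, 1]])
    with pytest.raises(ValueError, match="rank deficient"):
        fit_lmm_arrays(y, Xbad, list("abcd"), {"male": male})
    with pytest.raises(ValueError, match="method"):
        fit_lmm_arrays(y, X, ["b0", "b1", "b2"], {"male": male}, method="pql")
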