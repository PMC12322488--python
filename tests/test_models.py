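"""Model battery: LRTs, estimated-marginal-means contrasts, FDR families."""

import warnings

import numpy as np
import pandas as pd
import pytest

from titplayback import (
    ModelSpec,
    emm_contrasts,
    fit_global_model,
    fit_lmm,
    lrt,
    refit_ml,
    run_paper_models,
)
from titplayback.models import (
    GLOBAL_FIXED,
    GLOBAL_FIXED_ADDITIVE,
    SPECIES_FIXED,
    _prepare,
    standardize_covariates,
)


@pytest.fixture(scope="module")
def prepared(paper_experiment):
    return _prepare(paper_experiment["index"])


@pytest.fixture(scope="module")
def global_fit(prepared):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fit_global_model(prepared)


def test_global_model_shape(global_fit):
    assert global_fit.n_obs == 333
    assert set(global_fit.varcomps) == {"species", "male_id", "playback_species"}
    assert all(v >= 0 for v in global_fit.varcomps.values())
    assert 0 <= global_fit.marginal_r2 <= 1


def test_standardized_covariates_have_unit_scale(prepared):
    assert prepared["z_trial_seq"].mean() == pytest.approx(0, abs=1e-12)
    assert prepared["z_trial_seq"].std(ddof=0) == pytest.approx(1, rel=1e-12)


def test_lrt_identical_models_is_null(global_fit):
    full = refit_ml(global_fit)
    chi2, df, p = lrt(full, full)
    assert chi2 == 0.0
    assert df == 0
    assert p == 1.0


def test_interaction_lrt_has_two_df(global_fit):
    full = refit_ml(global_fit)
    reduced = refit_ml(global_fit, GLOBAL_FIXED_ADDITIVE)
    chi2, df, p = lrt(full, reduced)
    assert df == 2
    assert chi2 >= 0
    assert 0 <= p <= 1


def test_lrt_rejects_reml_and_misordered_models(global_fit):
    full = refit_ml(global_fit)
    reduced = refit_ml(global_fit, GLOBAL_FIXED_ADDITIVE)
    with pytest.raises(ValueError, match="ML"):
        lrt(global_fit, global_fit)
    with pytest.raises(ValueError, match="more parameters"):
        lrt(reduced, full)


def test_contrasts_cyclic_consistency(global_fit):
    """(A-B) + (B-C) equals (A-C) exactly for every contrast family."""
    c = emm_contrasts(global_fit, by="habitat_group")
    for _, fam in c.groupby("by"):
        fam = fam.set_index("contrast")
        ab = fam.loc["conspecific - intra_habitat", "estimate"]
        bc = fam.loc["intra_habitat - extra_habitat", "estimate"]
        ac = fam.loc["conspecific - extra_habitat", "estimate"]
        assert ab + bc == pytest.approx(ac, abs=1e-10)


def test_contrast_table_shape_and_fdr_monotonicity(global_fit):
    c = emm_contrasts(global_fit, by="habitat_group")
    assert len(c) == 6  # 3 contrasts x 2 habitat groups
    assert (c["p_adjusted"] >= c["p_value"] - 1e-15).all()
    # Benjamini-Hochberg recomputed by hand within each 3-contrast family
    for _, fam in c.groupby("by"):
        p = fam["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        bh = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            bh[i] = running
        np.testing.assert_allclose(fam["p_adjusted"].to_numpy(), bh, rtol=1e-12)


def test_no_treatment_effect_gives_zero_contrasts():
    """Balanced data built with equal treatment means: all contrasts ~0."""
    rows = []
    rng = np.random.default_rng(0)
    for m in range(12):
        noise = rng.normal(0, 1e-12)
        order = rng.permutation(["conspecific", "intra_habitat", "extra_habitat"])
        for seq, t in enumerate(order, start=1):
            rows.append(
                {"male_id": f"m{m}", "species": "great tit",
                 "playback_species": "great tit", "treatment": t,
                 "aggression_index": noise, "already_singing": m % 2,
                 "trial_seq": seq,
                 "minutes_after_sunrise": float(rng.uniform(0, 200))}
            )
    df = standardize_covariates(pd.DataFrame(rows))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_lmm(df, ModelSpec("aggression_index", SPECIES_FIXED, ("male_id",)))
    c = emm_contrasts(fit)
    assert np.allclose(c["estimate"], 0.0, atol=1e-9)


def test_response_shift_moves_only_intercept(prepared):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = fit_global_model(prepared)
        shifted = prepared.copy()
        shifted["aggression_index"] = shifted["aggression_index"] + 5.0
        b = fit_global_model(shifted)
    pa, pb = a.params, b.params
    assert pb["Intercept"] - pa["Intercept"] == pytest.approx(5.0, abs=1e-6)
    others = [n for n in pa.index if n != "Intercept"]
    np.testing.assert_allclose(pa[others], pb[others], atol=1e-6)


def test_covariate_rescaling_leaves_standardized_coefficient(prepared):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = fit_global_model(prepared)
        rescaled = prepared.copy()
        rescaled["minutes_after_sunrise"] = rescaled["minutes_after_sunrise"] * 60.0
        b = fit_global_model(_prepare(rescaled))
    assert a.params["z_minutes"] == pytest.approx(b.params["z_minutes"], abs=1e-6)


def test_run_paper_models_report_structure(paper_experiment):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        report = run_paper_models(paper_experiment["index"])
    assert report["global"]["fit"]["n_obs"] == 333
    assert set(report["per_species"]) == {
        "great tit", "blue tit", "marsh tit", "crested tit", "coal tit"
    }
    for block in report["per_species"].values():
        assert len(block["contrasts"]) == 3
        assert "treatment" in block["lrt"]
    assert set(report["per_variable"]) == {
        "centered_min_distance", "centered_mean_distance_singing",
        "centered_total_singing", "centered_latency",
    }
    assert report["global"]["lrt"]["treatment:habitat_group"]["df"] == 2


def test_run_paper_models_unknown_species_error(paper_experiment):
    with pytest.raises(ValueError, match="willow tit"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_paper_models(paper_experiment["index"], species=["willow tit"])


def test_emm_requires_fitted_factor(prepared):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = fit_lmm(
            prepared,
            ModelSpec("aggression_index", "already_singing", ("male_id",)),
        )
    with pytest.raises(KeyError, match="treatment"):
        emm_contrasts(fit)
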