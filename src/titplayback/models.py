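"""Model battery for the aggression index: global, per-species and
per-variable linear mixed models, likelihood-ratio tests and estimated
marginal means contrasts with FDR correction.

The global model regresses the within-male-centered aggression index on
playback treatment (conspecific / intra-habitat / extra-habitat) in
interaction with habitat group (broadleaf / conifer), controlling for
whether the male was already singing, the trial sequence number and the time
of day (both standardized), with random intercepts for species, for male
(nested in species through globally unique male labels) and, crossed with
these, for playback species.  Per-species models drop the habitat factor and
the species intercept; per-variable models use each within-male-centered raw
variable as the response.

Coefficients and contrasts are reported from REML fits; likelihood-ratio
tests compare ML refits of nested fixed-effect structures.  Post hoc
pairwise treatment contrasts are estimated-marginal-means differences on a
reference grid (standardized covariates at 0, the already-singing factor
averaged over its two levels), with t tests on residual degrees of freedom
and Benjamini-Hochberg adjustment within each three-contrast family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices, dmatrix
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmm import LMMFit, fit_lmm_arrays
from .species import TREATMENT_LEVELS, habitat_group_map

_TREAT = f"C(treatment, levels={list(TREATMENT_LEVELS)!r})"

GLOBAL_FIXED = (
    f"{_TREAT} * C(habitat_group) + already_singing + z_trial_seq + z_minutes"
)
GLOBAL_FIXED_ADDITIVE = (
    f"{_TREAT} + C(habitat_group) + already_singing + z_trial_seq + z_minutes"
)
SPECIES_FIXED = f"{_TREAT} + already_singing + z_trial_seq + z_minutes"
VARIABLE_FIXED = f"{_TREAT} + already_singing + z_minutes"

CENTERED_RESPONSES = (
    "centered_min_distance",
    "centered_mean_distance_singing",
    "centered_total_singing",
    "centered_latency",
)


@dataclass
class ModelSpec:
    """One LMM: response column, patsy fixed-effect formula, random
    intercept grouping columns, and the estimation criterion.

    ``centered_within`` names the grouping column the response was centered
    within before modelling (the aggression index is centered within male).
    The centering estimates one mean per group outside the model, which
    deflates the apparent residual variance; the fitter charges those
    degrees of freedom against the residual so that contrast SEs refer to
    the pre-centering error scale.  Set to None to reproduce a naive fit on
    centered data.
    """

    response: str
    fixed: str
    random: tuple[str, ...]
    method: str = "reml"
    centered_within: str | None = None


@dataclass
class MixedModelFit:
    """A fitted LMM plus everything needed for contrasts and refits."""

    spec: ModelSpec
    fit: LMMFit
    design_info: object = field(repr=False)
    data: pd.DataFrame = field(repr=False)
    marginal_r2: float = np.nan

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def se(self) -> pd.Series:
        return self.fit.se

    @property
    def varcomps(self) -> dict[str, float]:
        return self.fit.varcomps

    @property
    def loglik(self) -> float:
        return self.fit.loglik

    @property
    def n_obs(self) -> int:
        return self.fit.n_obs

    def to_dict(self) -> dict:
        return {
            "response": self.spec.response,
            "fixed": self.spec.fixed,
            "random": list(self.spec.random),
            "method": self.spec.method,
            "n_obs": self.n_obs,
            "loglik": self.loglik,
            "sigma2": self.fit.sigma2,
            "marginal_r2": self.marginal_r2,
            "varcomps": self.varcomps,
            "converged": self.fit.converged,
            "singular": self.fit.singular,
            "coefficients": {
                name: {"estimate": float(self.params[name]), "se": float(self.se[name])}
                for name in self.params.index
            },
        }


def standardize_covariates(df: pd.DataFrame) -> pd.DataFrame:
    """Add z-scored trial_seq / minutes_after_sunrise columns (mean 0, SD 1)."""
    out = df.copy()
    for raw, z in (("trial_seq", "z_trial_seq"), ("minutes_after_sunrise", "z_minutes")):
        v = out[raw].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        out[z] = (v - v.mean()) / sd if sd > 0 else 0.0
    return out


def fit_lmm(data: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """Fit one LMM described by a ModelSpec on a scored index table."""
    if spec.response not in data.columns:
        raise KeyError(f"response column {spec.response!r} not in data")
    for col in spec.random:
        if col not in data.columns:
            raise KeyError(f"random grouping column {col!r} not in data")
    data = data.reset_index(drop=True)
    X = dmatrix(spec.fixed, data, return_type="dataframe")
    if len(X) != len(data):
        raise ValueError("rows were dropped while building the design (missing values?)")
    codes = {col: pd.factorize(data[col])[0] for col in spec.random}
    extra_df = 0
    if spec.centered_within is not None:
        if spec.centered_within not in data.columns:
            raise KeyError(f"centering column {spec.centered_within!r} not in data")
        extra_df = data[spec.centered_within].nunique() - 1
    fit = fit_lmm_arrays(
        data[spec.response].to_numpy(float),
        X.to_numpy(),
        list(X.columns),
        codes,
        method=spec.method,
        extra_df=extra_df,
    )
    mm = MixedModelFit(spec=spec, fit=fit, design_info=X.design_info, data=data)
    mm.marginal_r2 = _marginal_r2(mm, X.to_numpy())
    return mm


def _marginal_r2(mm: MixedModelFit, X: np.ndarray) -> float:
    """Fixed-effect variance over total (fixed + random + residual) variance."""
    yhat = X @ mm.fit.params.to_numpy()
    var_fixed = float(np.var(yhat, ddof=0))
    total = var_fixed + sum(mm.fit.varcomps.values()) + mm.fit.sigma2
    return var_fixed / total if total > 0 else np.nan


def refit_ml(mm: MixedModelFit, fixed: str | None = None) -> MixedModelFit:
    """ML refit of a model, optionally with a different fixed structure."""
    spec = ModelSpec(
        response=mm.spec.response,
        fixed=mm.spec.fixed if fixed is None else fixed,
        random=mm.spec.random,
        method="ml",
        centered_within=mm.spec.centered_within,
    )
    return fit_lmm(mm.data, spec)


def lrt(full: MixedModelFit, reduced: MixedModelFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed-effect structures (ML fits)."""
    if full.spec.method != "ml" or reduced.spec.method != "ml":
        raise ValueError("likelihood-ratio tests require ML fits (method='ml')")
    if tuple(full.spec.random) != tuple(reduced.spec.random):
        raise ValueError("models differ in random structure; LRT compares fixed effects")
    df = full.fit.n_fixed - reduced.fit.n_fixed
    if df < 0:
        raise ValueError("'reduced' model has more parameters than 'full'")
    if df == 0 and full.spec.fixed != reduced.spec.fixed:
        raise ValueError("models are not nested (same size, different terms)")
    chi2 = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


def _reference_grid(
    mm: MixedModelFit, overrides: dict[str, object]
) -> np.ndarray:
    """Mean design row at the reference grid with the given factor settings.

    Continuous standardized covariates sit at 0; ``already_singing`` is
    averaged over {0, 1}; any categorical in the model not overridden is
    averaged over its observed levels with equal weights.
    """
    grid_axes: dict[str, list] = {}
    cols = mm.data.columns
    for var in ("treatment", "habitat_group"):
        if var in overrides:
            grid_axes[var] = [overrides[var]]
        elif var in cols and var in mm.spec.fixed:
            grid_axes[var] = sorted(mm.data[var].unique())
    if "already_singing" in mm.spec.fixed:
        grid_axes["already_singing"] = [0, 1]
    for z in ("z_trial_seq", "z_minutes"):
        if z in mm.spec.fixed:
            grid_axes[z] = [0.0]
    keys = list(grid_axes)
    rows = [dict(zip(keys, combo)) for combo in itertools.product(*grid_axes.values())]
    grid = pd.DataFrame(rows)
    (mat,) = build_design_matrices([mm.design_info], grid)
    return np.asarray(mat).mean(axis=0)


def emm_contrasts(
    mm: MixedModelFit,
    factor: str = "treatment",
    by: str | None = None,
    df_method: str = "residual",
    p_adjust: str = "fdr_bh",
) -> pd.DataFrame:
    """Pairwise estimated-marginal-means contrasts for the treatment factor.

    Returns one row per level pair (per ``by`` level when given) with the
    contrast estimate, SE, t, df, raw and FDR-adjusted p-values.  Adjustment
    is applied within each ``by`` family.
    """
    if factor not in mm.data.columns or factor not in mm.spec.fixed:
        raise KeyError(f"factor {factor!r} not in the fitted model")
    if df_method not in ("residual",):
        raise ValueError(f"unknown df_method {df_method!r}")
    levels = [l for l in TREATMENT_LEVELS if l in set(mm.data[factor])] or sorted(
        mm.data[factor].unique()
    )
    by_levels = sorted(mm.data[by].unique()) if by else [None]

    beta = mm.fit.params.to_numpy()
    vcov = mm.fit.vcov.to_numpy()
    df_resid = mm.fit.df_resid

    rows = []
    for b in by_levels:
        emm_rows = {}
        for lev in levels:
            over = {factor: lev}
            if by:
                over[by] = b
            emm_rows[lev] = _reference_grid(mm, over)
        for la, lb in itertools.combinations(levels, 2):
            L = emm_rows[la] - emm_rows[lb]
            est = float(L @ beta)
            se = float(np.sqrt(L @ vcov @ L))
            t = est / se if se > 0 else np.nan
            p = float(2.0 * stats.t.sf(abs(t), df_resid))
            rows.append(
                {
                    "by": b,
                    "contrast": f"{la} - {lb}",
                    "estimate": est,
                    "se": se,
                    "df": df_resid,
                    "t": t,
                    "p_value": p,
                }
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    for b in by_levels:
        mask = out["by"].isna() if b is None else (out["by"] == b)
        out.loc[mask, "p_adjusted"] = multipletests(
            out.loc[mask, "p_value"], method=p_adjust
        )[1]
    if by is None:
        out = out.drop(columns="by")
    return out


def _drop_term_lrts(
    mm: MixedModelFit, terms: dict[str, tuple[str, str]]
) -> dict[str, dict]:
    """LRTs for named terms given (full formula, reduced formula) pairs."""
    cache: dict[str, MixedModelFit] = {}

    def ml(fixed: str) -> MixedModelFit:
        if fixed not in cache:
            cache[fixed] = refit_ml(mm, fixed)
        return cache[fixed]

    out = {}
    for term, (full_f, reduced_f) in terms.items():
        chi2, df, p = lrt(ml(full_f), ml(reduced_f))
        out[term] = {"chi2": chi2, "df": df, "p_value": p}
    return out


def _strip(formula: str, piece: str) -> str:
    out = formula.replace(f" + {piece}", "").replace(f"{piece} + ", "")
    if out == formula:
        raise ValueError(f"term {piece!r} not found in {formula!r}")
    return out


def fit_global_model(index_table: pd.DataFrame, species_vc: bool = True) -> MixedModelFit:
    """REML fit of the all-species treatment x habitat-group model."""
    data = _prepare(index_table)
    random = ("species", "male_id", "playback_species") if species_vc else (
        "male_id", "playback_species"
    )
    return fit_lmm(
        data,
        ModelSpec("aggression_index", GLOBAL_FIXED, random, centered_within="male_id"),
    )


def _prepare(index_table: pd.DataFrame) -> pd.DataFrame:
    data = index_table.copy()
    if "habitat_group" not in data.columns:
        groups = habitat_group_map()
        data["habitat_group"] = data["species"].map(groups)
        if data["habitat_group"].isna().any():
            bad = sorted(data.loc[data["habitat_group"].isna(), "species"].unique())
            raise KeyError(f"species without a habitat group: {bad}")
    return standardize_covariates(data)


def run_paper_models(
    index_table: pd.DataFrame,
    species_vc: bool = True,
    df_method: str = "residual",
    species: list[str] | None = None,
) -> dict:
    """Run the full model battery on a scored index table.

    Returns a JSON-able report with (a) the global treatment x habitat-group
    model, its term LRTs and by-group treatment contrasts; (b) one model per
    focal species with term LRTs and treatment contrasts; (c) one model per
    within-male-centered behavioural variable.
    """
    data = _prepare(index_table)

    report: dict = {}

    # (a) global model
    gfit = fit_global_model(data, species_vc=species_vc)
    g_terms = {
        "treatment:habitat_group": (GLOBAL_FIXED, GLOBAL_FIXED_ADDITIVE),
        "treatment": (GLOBAL_FIXED_ADDITIVE, _strip(GLOBAL_FIXED_ADDITIVE, _TREAT)),
        "habitat_group": (
            GLOBAL_FIXED_ADDITIVE,
            _strip(GLOBAL_FIXED_ADDITIVE, "C(habitat_group)"),
        ),
        "already_singing": (GLOBAL_FIXED, _strip(GLOBAL_FIXED, "already_singing")),
        "trial_seq": (GLOBAL_FIXED, _strip(GLOBAL_FIXED, "z_trial_seq")),
        "minutes_after_sunrise": (GLOBAL_FIXED, _strip(GLOBAL_FIXED, "z_minutes")),
    }
    report["global"] = {
        "fit": gfit.to_dict(),
        "lrt": _drop_term_lrts(gfit, g_terms),
        "contrasts": emm_contrasts(
            gfit, by="habitat_group", df_method=df_method
        ).to_dict(orient="records"),
    }

    # (b) per-species models
    report["per_species"] = {}
    species_list = sorted(data["species"].unique()) if species is None else list(species)
    for sp in species_list:
        sub = data[data["species"] == sp].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no trials for species {sp!r}")
        sfit = fit_lmm(
            sub,
            ModelSpec(
                "aggression_index",
                SPECIES_FIXED,
                ("male_id", "playback_species"),
                centered_within="male_id",
            ),
        )
        s_terms = {
            "treatment": (SPECIES_FIXED, _strip(SPECIES_FIXED, _TREAT)),
            "already_singing": (SPECIES_FIXED, _strip(SPECIES_FIXED, "already_singing")),
            "trial_seq": (SPECIES_FIXED, _strip(SPECIES_FIXED, "z_trial_seq")),
            "minutes_after_sunrise": (SPECIES_FIXED, _strip(SPECIES_FIXED, "z_minutes")),
        }
        report["per_species"][sp] = {
            "fit": sfit.to_dict(),
            "lrt": _drop_term_lrts(sfit, s_terms),
            "contrasts": emm_contrasts(sfit, df_method=df_method).to_dict(
                orient="records"
            ),
        }

    # (c) per-variable models
    report["per_variable"] = {}
    for resp in CENTERED_RESPONSES:
        vfit = fit_lmm(
            data,
            ModelSpec(
                resp,
                VARIABLE_FIXED,
                ("male_id", "playback_species"),
                centered_within="male_id",
            ),
        )
        v_terms = {
            "treatment": (VARIABLE_FIXED, _strip(VARIABLE_FIXED, _TREAT)),
            "already_singing": (VARIABLE_FIXED, _strip(VARIABLE_FIXED, "already_singing")),
            "minutes_after_sunrise": (VARIABLE_FIXED, _strip(VARIABLE_FIXED, "z_minutes")),
        }
        report["per_variable"][resp] = {
            "fit": vfit.to_dict(),
            "lrt": _drop_term_lrts(vfit, v_terms),
            "contrasts": emm_contrasts(vfit, df_method=df_method).to_dict(
                orient="records"
            ),
        }
    return report
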