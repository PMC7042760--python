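"""Mixed-effects models for gradient analyses of network metrics.

Walk-level network metrics are regressed on site-level predictors
(elevation, land-use intensity, temperature) with a random study-site
intercept to absorb repeated measurements per site.  Inference uses
containment-style denominator degrees of freedom: a predictor that is
constant within sites is tested against the between-site stratum
(G - 1 - p_between df), predictors varying within sites and the intercept
against the within-site stratum (N - G - p_within df).  t = estimate / SE
throughout; the variance explained by a single fixed effect is reported as
the marginal R2 share attributable to that term (Nakagawa & Schielzeth
style decomposition).

Model comparison uses AICc (second-order small-sample correction) on
maximum-likelihood refits; reported estimates come from REML fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class TermFit:
    name: str
    estimate: float
    se: float
    t: float
    df: float
    p: float
    r2: float | None = None

    def ci(self, alpha: float = 0.05) -> tuple[float, float]:
        half = sps.t.ppf(1 - alpha / 2, self.df) * self.se
        return (self.estimate - half, self.estimate + half)


@dataclass(frozen=True)
class LmmFit:
    response: str
    terms: tuple[TermFit, ...]
    random_sd: dict[str, float]
    resid_sd: float
    n_obs: int
    n_groups: int
    aicc: float | None
    converged: bool
    flags: tuple[str, ...] = field(default_factory=tuple)

    def term(self, name: str) -> TermFit:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    @property
    def r2_fixed(self) -> float:
        vals = [t.r2 for t in self.terms if t.name != "Intercept" and t.r2 is not None]
        return float(np.sum(vals)) if vals else 0.0


def aicc_from_loglike(llf: float, k: int, n: int) -> float:
    """AICc = AIC + 2k(k+1)/(n-k-1); undefined for n <= k + 1."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} too small for k={k} parameters")
    return -2.0 * llf + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _containment_df(X: pd.DataFrame, groups: np.ndarray) -> dict[str, float]:
    """Denominator df per design column, containment style.

    Columns constant within every group are between-group terms and share
    the between stratum; the rest (and the intercept) use the within
    stratum.  Mimics the df pattern of nested-stratum mixed-model software.
    """
    g = pd.Series(np.asarray(groups))
    n, G = len(X), g.nunique()
    between_cols = []
    within_cols = []
    for col in X.columns:
        if col == "Intercept":
            continue
        nun = X[col].groupby(g.values).nunique()
        (between_cols if (nun <= 1).all() else within_cols).append(col)
    df_between = max(G - 1 - len(between_cols), 1)
    df_within = max(n - G - len(within_cols), 1)
    out = {"Intercept": float(df_within)}
    out.update({c: float(df_between) for c in between_cols})
    out.update({c: float(df_within) for c in within_cols})
    return out


def _best_fit(model, reml: bool):
    """Fit with two optimizers and keep the higher (restricted) likelihood.

    The default optimizer can stall ~1e-4 short of the optimum on
    variance components; conjugate gradients usually polishes it off.
    """
    best = None
    for method in (None, "cg"):
        try:
            kwargs = {"method": method, "maxiter": 500} if method else {}
            res = model.fit(reml=reml, **kwargs)
        except Exception:
            continue
        if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
            best = res
    if best is None:
        raise RuntimeError("mixed-model fit failed with every optimizer")
    return best


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    group: str,
    reml: bool = True,
    compute_aicc: bool = True,
) -> LmmFit:
    """REML linear mixed model with a random group intercept.

    Returns estimates, containment df, t and p per fixed term, the fixed
    effects' marginal R2 shares, and (optionally) the model's AICc from an
    ML refit.  A random-effect variance estimated at (or near) zero is
    retained but flagged as singular.
    """
    cols = [response, group] + fixed
    df = data[cols].dropna().reset_index(drop=True)
    n = len(df)
    G = df[group].nunique()
    if G < 2 or n < 3:
        raise ValueError("need at least 2 groups and 3 observations")
    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"Q('{response}') ~ {rhs}"
    flags: list[str] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df[group])
        result = _best_fit(model, reml)
        llf_ml = None
        if compute_aicc:
            res_ml = result if not reml else _best_fit(smf.mixedlm(formula, df, groups=df[group]), False)
            llf_ml = float(res_ml.llf)
    var_re = float(result.cov_re.iloc[0, 0])
    var_resid = float(result.scale)
    if var_re < 1e-10:
        flags.append("singular_random_effect")
    if not result.converged:
        flags.append("not_converged")

    X = pd.DataFrame(model.exog, columns=model.exog_names)
    dfs = _containment_df(X, df[group].to_numpy())
    beta = result.fe_params
    # total variance for the marginal-R2 denominator
    fixed_part = X.drop(columns="Intercept", errors="ignore").to_numpy() @ beta.drop(
        "Intercept", errors="ignore"
    ).to_numpy() if len(beta) > 1 else np.zeros(n)
    var_fixed_all = float(np.var(fixed_part))
    var_total = var_fixed_all + var_re + var_resid
    terms = []
    for name in model.exog_names:
        est = float(beta[name])
        se = float(result.bse_fe[name])
        tval = est / se if se > 0 else np.nan
        ddf = dfs[name]
        p = float(2 * sps.t.sf(abs(tval), ddf)) if np.isfinite(tval) else np.nan
        r2 = None
        if name != "Intercept" and var_total > 0:
            r2 = float(np.var(X[name].to_numpy() * est) / var_total)
        terms.append(TermFit(name, est, se, tval, ddf, p, r2))
    k = len(beta) + 2  # fixed effects + random-intercept variance + residual variance
    aicc = aicc_from_loglike(llf_ml, k, n) if llf_ml is not None else None
    return LmmFit(
        response=response,
        terms=tuple(terms),
        random_sd={group: float(np.sqrt(max(var_re, 0.0)))},
        resid_sd=float(np.sqrt(var_resid)),
        n_obs=n,
        n_groups=G,
        aicc=aicc,
        converged=result.converged if result.converged is not None else True,
        flags=tuple(flags),
    )


def fit_metric_vs_elevation(
    data: pd.DataFrame,
    metric: str,
    elevation: str = "elevation",
    site: str = "site_id",
) -> LmmFit:
    """Walk-level metric vs elevation with a random site intercept."""
    return fit_lmm(data, metric, [elevation], site)


@dataclass(frozen=True)
class AiccComparison:
    metric: str
    aicc_elevation: float
    aicc_lui: float
    delta: float  # AICc(LUI) - AICc(elevation); negative -> LUI better
    similarly_supported: bool


def compare_elevation_vs_lui(
    data: pd.DataFrame,
    metric: str,
    elevation: str = "elevation",
    lui: str = "LUI",
    site: str = "site_id",
) -> AiccComparison:
    """AICc contest between elevation-only and LUI-only mixed models.

    Both models are refit by ML on the identical set of complete cases;
    |delta| <= 2 is flagged as similar support for both predictors.
    """
    df = data[[metric, elevation, lui, site]].dropna().reset_index(drop=True)
    fit_e = fit_lmm(df, metric, [elevation], site)
    fit_l = fit_lmm(df, metric, [lui], site)
    if fit_e.n_obs != fit_l.n_obs:
        raise ValueError("elevation and LUI models were fit on different n")
    assert fit_e.aicc is not None and fit_l.aicc is not None
    delta = fit_l.aicc - fit_e.aicc
    return AiccComparison(metric, fit_e.aicc, fit_l.aicc, delta, abs(delta) <= 2.0)


def intraspecific_dprime_model(
    scores: pd.DataFrame,
    mat_col: str = "MAT",
    dprime_col: str = "d_prime",
    species_col: str = "species",
    site_col: str = "site_id",
    min_sites: int = 3,
) -> LmmFit:
    """Within-species specialization vs mean annual temperature.

    Gaussian mixed model with MAT as single fixed effect and crossed
    random intercepts for species and site; restricted to species observed
    on at least ``min_sites`` distinct sites.
    """
    df = scores[[species_col, site_col, mat_col, dprime_col]].dropna().copy()
    site_counts = df.groupby(species_col)[site_col].nunique()
    keep = site_counts[site_counts >= min_sites].index
    df = df[df[species_col].isin(keep)].reset_index(drop=True)
    if df[species_col].nunique() < 2:
        raise ValueError("fewer than 2 species remain after the min_sites filter")
    if df[mat_col].nunique() < 2:
        raise ValueError("MAT is constant; slope undefined")
    n = len(df)
    vc = {"species": f"0 + C({species_col})", "site": f"0 + C({site_col})"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            f"Q('{dprime_col}') ~ {mat_col}", df, groups=np.ones(n), vc_formula=vc
        )
        result = model.fit(reml=True)
    n_sp = df[species_col].nunique()
    n_si = df[site_col].nunique()
    ddf = float(max(n - n_sp - n_si, 3))
    est = float(result.fe_params[mat_col])
    se = float(result.bse_fe[mat_col])
    tval = est / se if se > 0 else np.nan
    p = float(2 * sps.t.sf(abs(tval), ddf))
    x = df[mat_col].to_numpy()
    var_fixed = float(np.var(x * est))
    var_re = float(result.vcomp.sum())
    var_total = var_fixed + var_re + float(result.scale)
    r2 = var_fixed / var_total if var_total > 0 else 0.0
    terms = (
        TermFit("Intercept", float(result.fe_params["Intercept"]), float(result.bse_fe["Intercept"]),
                np.nan, ddf, np.nan),
        TermFit(mat_col, est, se, tval, ddf, p, r2),
    )
    sds = {name: float(np.sqrt(max(v, 0.0))) for name, v in zip(["species", "site"], result.vcomp)}
    return LmmFit(dprime_col, terms, sds, float(np.sqrt(result.scale)), n,
                  n_sp, None, bool(result.converged))


def trait_and_taxon_models(
    species_table: pd.DataFrame,
    min_obs: int = 3,
) -> dict[str, LmmFit]:
    """Species mean d' vs taxonomic group and functional traits.

    Expects one row per pollinator species with columns ``mean_dprime``,
    ``n_obs``, ``group`` (bee/wasp/syrphid), ``order``, ``family``,
    ``genus``, ``proboscis_length``, ``head_width``, ``elev_range``.
    Fits: (A) Hymenoptera-vs-Diptera contrast with a random genus
    intercept; (B) proboscis length, (C) head width and (D) elevational
    range, each with nested order/family/genus random terms.
    """
    df = species_table[species_table["n_obs"] >= min_obs].copy()
    taxo = ["order", "family", "genus"]
    unresolved = df.loc[df[taxo].isna().any(axis=1), "species"].tolist() if "species" in df else []
    if unresolved:
        raise ValueError(f"unresolvable taxonomy for species: {', '.join(map(str, unresolved))}")
    df["is_hymenoptera"] = (df["order"] == "Hymenoptera").astype(float)
    out: dict[str, LmmFit] = {}
    out["group"] = fit_lmm(df, "mean_dprime", ["is_hymenoptera"], "genus", compute_aicc=False)

    def nested_fit(predictor: str) -> LmmFit:
        sub = df[["mean_dprime", predictor] + taxo].dropna().reset_index(drop=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                f"mean_dprime ~ {predictor}",
                sub,
                groups=sub["order"],
                re_formula="1",
                vc_formula={"family": "0 + C(family)", "genus": "0 + C(genus)"},
            )
            result = model.fit(reml=True)
        n = len(sub)
        ddf = float(max(n - sub["genus"].nunique() - 1, 3))
        est = float(result.fe_params[predictor])
        se = float(result.bse_fe[predictor])
        tval = est / se if se > 0 else np.nan
        p = float(2 * sps.t.sf(abs(tval), ddf))
        var_fixed = float(np.var(sub[predictor].to_numpy() * est))
        var_cov_re = float(result.cov_re.iloc[0, 0]) if result.cov_re.size else 0.0
        var_re = var_cov_re + float(result.vcomp.sum())
        var_total = var_fixed + var_re + float(result.scale)
        terms = (
            TermFit("Intercept", float(result.fe_params["Intercept"]),
                    float(result.bse_fe["Intercept"]), np.nan, ddf, np.nan),
            TermFit(predictor, est, se, tval, ddf, p,
                    var_fixed / var_total if var_total > 0 else 0.0),
        )
        return LmmFit("mean_dprime", terms, {"taxonomy": float(np.sqrt(max(var_re, 0)))},
                      float(np.sqrt(result.scale)), n, sub["order"].nunique(), None,
                      bool(result.converged))

    out["proboscis_length"] = nested_fit("proboscis_length")
    out["head_width"] = nested_fit("head_width")
    out["elev_range"] = nested_fit("elev_range")
    return out


def robustness_predictor_model(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    site: str = "site_id",
    alpha: float = 0.05,
) -> tuple[LmmFit, list[dict[str, float | str]]]:
    """Backward elimination of robustness predictors.

    Starting from the additive model, the least significant term is
    removed while any p exceeds ``alpha``; returns the final fit plus the
    elimination trace.  If every predictor is eliminated the intercept-only
    model is returned (flagged via the empty term list).
    """
    remaining = list(predictors)
    df = data[[response, site] + predictors].dropna().reset_index(drop=True)
    trace: list[dict[str, float | str]] = []
    while True:
        fit = fit_lmm(df, response, remaining, site, compute_aicc=False)
        slopes = [t for t in fit.terms if t.name != "Intercept"]
        if not slopes:
            return fit, trace
        worst = max(slopes, key=lambda t: (t.p if np.isfinite(t.p) else np.inf))
        if worst.p > alpha:
            remaining.remove(worst.name)
            trace.append({"dropped": worst.name, "p": worst.p})
            if not remaining:
                return fit_lmm(df, response, [], site, compute_aicc=False), trace
        else:
            return fit, trace


def fit_ols(data: pd.DataFrame, response: str, predictor: str) -> TermFit:
    """Ordinary least squares slope for site-level sensitivity analyses."""
    df = data[[response, predictor]].dropna()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.ols(f"Q('{response}') ~ Q('{predictor}')", df).fit()
    name = res.params.index[1]
    return TermFit(
        predictor,
        float(res.params.iloc[1]),
        float(res.bse.iloc[1]),
        float(res.tvalues.iloc[1]),
        float(res.df_resid),
        float(res.pvalues.iloc[1]),
        float(res.rsquared),
    )


def sensitivity_suite(
    walk_metrics: pd.DataFrame,
    metrics: list[str],
    elevation: str = "elevation",
    lui: str = "LUI",
    site: str = "site_id",
    canopy: str = "canopy_cover",
    pooled_h2: pd.DataFrame | None = None,
    low_elevation_cutoff: float = 2000.0,
) -> dict[str, pd.DataFrame]:
    """Five stability checks of the gradient results.

    (a) site-mean OLS per metric; (b) elevation-vs-LUI AICc contest;
    (c) mixed models restricted to sites below ``low_elevation_cutoff``;
    (d) OLS of pooled-network H2' vs elevation (table supplied by the
    caller, built from :func:`pollinet.assembly.pool_site_networks`);
    (e) mixed models restricted to open habitats (canopy cover at or below
    the median).  Empty subsets skip the analysis with a warning row.
    """
    out: dict[str, pd.DataFrame] = {}

    site_cols = [site, elevation] + ([lui] if lui in walk_metrics else []) \
        + ([canopy] if canopy in walk_metrics else [])
    site_means = walk_metrics.groupby(site, as_index=False).agg(
        {**{m: "mean" for m in metrics}, **{c: "first" for c in site_cols if c != site}}
    )
    rows = []
    for m in metrics:
        t = fit_ols(site_means, m, elevation)
        rows.append({"metric": m, "slope": t.estimate, "t": t.t, "p": t.p, "n": len(site_means)})
    out["site_mean_ols"] = pd.DataFrame(rows)

    if lui in walk_metrics.columns:
        rows = []
        for m in metrics:
            c = compare_elevation_vs_lui(walk_metrics, m, elevation, lui, site)
            rows.append(
                {"metric": m, "aicc_elevation": c.aicc_elevation, "aicc_lui": c.aicc_lui,
                 "delta_aicc": c.delta, "similar": c.similarly_supported}
            )
        out["elevation_vs_lui_aicc"] = pd.DataFrame(rows)

    def lmm_rows(df: pd.DataFrame, label: str) -> pd.DataFrame:
        rows = []
        for m in metrics:
            sub = df[[m, elevation, site]].dropna()
            if sub.empty or sub[site].nunique() < 2:
                rows.append({"metric": m, "slope": np.nan, "t": np.nan, "p": np.nan,
                             "n": len(sub), "note": "subset too small; skipped"})
                continue
            fit = fit_metric_vs_elevation(sub, m, elevation, site)
            t = fit.term(elevation)
            rows.append({"metric": m, "slope": t.estimate, "t": t.t, "p": t.p,
                         "n": fit.n_obs, "note": ""})
        return pd.DataFrame(rows)

    out["below_cutoff_lmm"] = lmm_rows(
        walk_metrics[walk_metrics[elevation] < low_elevation_cutoff], "below_cutoff"
    )

    if pooled_h2 is not None and not pooled_h2.empty:
        t = fit_ols(pooled_h2, "h2_prime", elevation)
        out["pooled_network_ols"] = pd.DataFrame(
            [{"metric": "h2_prime", "slope": t.estimate, "t": t.t, "p": t.p, "n": len(pooled_h2)}]
        )

    if canopy in walk_metrics.columns:
        med = walk_metrics.drop_duplicates(site)[canopy].median()
        out["open_habitat_lmm"] = lmm_rows(walk_metrics[walk_metrics[canopy] <= med], "open")
    return out
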