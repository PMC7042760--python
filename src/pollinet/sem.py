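"""Piecewise structural equation models over a DAG of mixed regressions.

Each endogenous variable is fit with its graph parents as fixed effects
and (when a grouping column is supplied and varies) a random site
intercept.  Global goodness of fit uses the d-separation test: every
non-adjacent ordered pair yields one independence claim, tested by
regressing the topologically later variable on the earlier one plus the
later variable's parents; Fisher's C = -2 * sum(ln p) is chi-square with
2k degrees of freedom when the causal structure is compatible with the
data.  Models are ranked by AICc = C + 2K n / (n - K - 1), with K the
total number of estimated parameters across component models.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class SemModel:
    """A DAG over observed, z-transformed variables."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    group: str | None = None  # random-intercept grouping column

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("path model graph has a cycle")
        return g

    def parents(self, node: str) -> list[str]:
        return sorted(p for p, c in self.edges if c == node)

    @property
    def endogenous(self) -> list[str]:
        return sorted({c for _, c in self.edges})


@dataclass(frozen=True)
class IndependenceClaim:
    x: str  # earlier variable
    y: str  # later variable (regression response)
    conditioning: tuple[str, ...]
    p: float | None = None


@dataclass(frozen=True)
class PathCoefficient:
    source: str
    target: str
    estimate: float
    se: float
    p: float


@dataclass(frozen=True)
class SemResult:
    model: SemModel
    coefficients: tuple[PathCoefficient, ...]
    basis: tuple[IndependenceClaim, ...]
    C: float
    df: int
    p_C: float
    K: int
    n: int
    aicc: float
    r2: dict[str, tuple[float, float]] = field(default_factory=dict)  # node -> (marginal, conditional)
    delta_aicc: float | None = None

    def has_edge(self, source: str, target: str) -> bool:
        return (source, target) in self.model.edges


def basis_set(model: SemModel) -> list[IndependenceClaim]:
    """d-separation basis set: one claim per non-adjacent ordered pair.

    Variables are taken in a deterministic (lexicographic-tie-break)
    topological order; the later variable of each pair is regressed on the
    earlier one plus the later variable's own parents.
    """
    g = model.graph()
    order = list(nx.lexicographical_topological_sort(g))
    claims = []
    for i, u in enumerate(order):
        for v in order[i + 1:]:
            if g.has_edge(u, v) or g.has_edge(v, u):
                continue
            conditioning = tuple(sorted(set(model.parents(v)) - {u}))
            claims.append(IndependenceClaim(u, v, conditioning))
    return claims


def fishers_c(p_values: list[float] | np.ndarray) -> tuple[float, int, float]:
    """Fisher's C over independence-claim p-values: (C, df, p_C)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return 0.0, 0, 1.0
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("claim p-values must lie in (0, 1]")
    C = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return C, df, float(sps.chi2.sf(C, df))


def _component_fit(
    df: pd.DataFrame, response: str, predictors: list[str], group: str | None,
    cache: dict | None = None,
):
    """One component regression: mixed model with random group intercept,
    or OLS when no grouping is available / the response is group-constant.

    ``cache`` (keyed by response and predictor set) lets the exhaustive
    model search skip regressions shared between candidate structures.
    """
    if cache is not None:
        key = (response, tuple(sorted(predictors)))
        if key in cache:
            return cache[key]
    rhs = " + ".join(f"Q('{p}')" for p in predictors) if predictors else "1"
    formula = f"Q('{response}') ~ {rhs}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if group is not None and df[group].nunique() > 1:
            model = smf.mixedlm(formula, df, groups=df[group])
            res = model.fit(reml=True)
            var_re = float(res.cov_re.iloc[0, 0])
            k = len(res.fe_params) + 2
        else:
            res = smf.ols(formula, df).fit()
            var_re = 0.0
            k = len(res.params) + 1
    out = (res, var_re, k)
    if cache is not None:
        cache[key] = out
    return out


def _slope_p(df: pd.DataFrame, response: str, predictors: list[str], focal: str,
             group: str | None, cache: dict | None = None) -> tuple[float, float, float]:
    """(estimate, se, p) of ``focal`` in response ~ predictors."""
    res, _, _ = _component_fit(df, response, predictors, group, cache)
    name = f"Q('{focal}')"
    params = res.fe_params if hasattr(res, "fe_params") else res.params
    bse = res.bse_fe if hasattr(res, "bse_fe") else res.bse
    est, se = float(params[name]), float(bse[name])
    tval = est / se if se > 0 else 0.0
    ddf = max(len(df) - len(params) - (df[group].nunique() if group else 0), 3)
    return est, se, float(2 * sps.t.sf(abs(tval), ddf))


def zscore_frame(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    out = data.copy()
    for c in columns:
        sd = out[c].std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"variable {c!r} is constant; cannot z-transform")
        out[c] = (out[c] - out[c].mean()) / sd
    return out


def sem_fit(
    model: SemModel,
    data: pd.DataFrame,
    standardize: bool = True,
    cache: dict | None = None,
) -> SemResult:
    """Fit all component models and the d-separation test for one DAG."""
    cols = list(model.nodes) + ([model.group] if model.group else [])
    df = data[cols].dropna().reset_index(drop=True)
    n = len(df)
    if standardize:
        df = zscore_frame(df, list(model.nodes))
    coefficients: list[PathCoefficient] = []
    K = 0
    r2: dict[str, tuple[float, float]] = {}
    for node in model.endogenous:
        parents = model.parents(node)
        res, var_re, k = _component_fit(df, node, parents, model.group, cache)
        K += k
        params = res.fe_params if hasattr(res, "fe_params") else res.params
        bse = res.bse_fe if hasattr(res, "bse_fe") else res.bse
        scale = float(res.scale) if hasattr(res, "fe_params") else float(res.mse_resid)
        X = df[parents].to_numpy()
        beta = np.array([float(params[f"Q('{p}')"]) for p in parents])
        var_fixed = float(np.var(X @ beta)) if parents else 0.0
        var_total = var_fixed + var_re + scale
        r2[node] = (
            var_fixed / var_total if var_total > 0 else 0.0,
            (var_fixed + var_re) / var_total if var_total > 0 else 0.0,
        )
        ddf = max(n - len(params) - (df[model.group].nunique() if model.group else 0), 3)
        for p_name in parents:
            est = float(params[f"Q('{p_name}')"])
            se = float(bse[f"Q('{p_name}')"])
            tval = est / se if se > 0 else 0.0
            coefficients.append(
                PathCoefficient(p_name, node, est, se, float(2 * sps.t.sf(abs(tval), ddf)))
            )
    # exogenous-only models contribute no parameters beyond their marginal
    # distributions, which cancel across candidate structures.
    if n <= K + 1:
        raise ValueError(f"AICc undefined: n={n}, K={K}")
    claims = []
    pvals = []
    for claim in basis_set(model):
        predictors = [claim.x] + list(claim.conditioning)
        _, _, p = _slope_p(df, claim.y, predictors, claim.x, model.group, cache)
        p = min(max(p, 1e-300), 1.0)
        claims.append(IndependenceClaim(claim.x, claim.y, claim.conditioning, p))
        pvals.append(p)
    C, dof, p_C = fishers_c(pvals)
    aicc = C + 2.0 * K * n / (n - K - 1)
    return SemResult(model, tuple(coefficients), tuple(claims), C, dof, p_C, K, n, aicc, r2)


MAX_OPTIONAL_EDGES = 12


def exhaustive_path_search(
    nodes: list[str],
    mandatory_edges: list[tuple[str, str]],
    optional_edges: list[tuple[str, str]],
    data: pd.DataFrame,
    group: str | None = None,
    tie_tolerance: float = 0.01,
) -> list[SemResult]:
    """Fit every subset of optional edges and rank by AICc.

    Returns results sorted by AICc (stable in subset enumeration order, so
    ranking is invariant to how the optional edges are listed); each
    carries its delta AICc to the best model.  Ties within
    ``tie_tolerance`` share rank by having near-zero deltas.
    """
    optional_edges = sorted(set(optional_edges))
    if len(optional_edges) > MAX_OPTIONAL_EDGES:
        raise ValueError(
            f"{len(optional_edges)} optional edges exceed the 2^{MAX_OPTIONAL_EDGES} cap; "
            "preselect variables first"
        )
    results = []
    cache: dict = {}  # shared regressions across candidate structures
    for r in range(len(optional_edges) + 1):
        for combo in itertools.combinations(optional_edges, r):
            model = SemModel(tuple(nodes), tuple(sorted(set(mandatory_edges) | set(combo))), group)
            model.graph()  # cycle check
            results.append(sem_fit(model, data, cache=cache))
    results.sort(key=lambda res: res.aicc)
    best = results[0].aicc
    return [
        SemResult(
            r.model, r.coefficients, r.basis, r.C, r.df, r.p_C, r.K, r.n, r.aicc, r.r2,
            delta_aicc=r.aicc - best,
        )
        for r in results
    ]


def preselect_variables(
    blocks: dict[str, list[str]],
    response: str,
    data: pd.DataFrame,
    group: str | None = None,
) -> dict[str, list[str]]:
    """AICc-based variable preselection within and across hypothesis blocks.

    Within each block, every subset of the block's variables is fit
    against the response (random group intercept when available) and the
    subset with the lowest AICc advances; a second pass repeats the
    exhaustive search on the union of the block winners.  Returns the
    per-block winners plus the final cross-block selection under the key
    ``"selected"``.
    """
    from .gradient import aicc_from_loglike

    def subset_aicc(predictors: list[str]) -> float:
        cols = [response] + predictors + ([group] if group else [])
        df = data[cols].dropna().reset_index(drop=True)
        rhs = " + ".join(f"Q('{p}')" for p in predictors) if predictors else "1"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if group is not None and df[group].nunique() > 1:
                res = smf.mixedlm(f"Q('{response}') ~ {rhs}", df, groups=df[group]).fit(reml=False)
                k = len(res.fe_params) + 2
            else:
                res = smf.ols(f"Q('{response}') ~ {rhs}", df).fit()
                k = len(res.params) + 1
        return aicc_from_loglike(float(res.llf), k, len(df))

    def best_subset(variables: list[str]) -> list[str]:
        best_vars: list[str] = []
        best_score = subset_aicc([])
        for r in range(1, len(variables) + 1):
            for combo in itertools.combinations(variables, r):
                score = subset_aicc(list(combo))
                if score < best_score - 1e-9:
                    best_score, best_vars = score, list(combo)
        return best_vars

    winners: dict[str, list[str]] = {}
    pool: list[str] = []
    for name, variables in blocks.items():
        if not variables:
            continue
        winners[name] = best_subset(variables)
        pool.extend(winners[name])
    winners["selected"] = best_subset(pool)
    return winners
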