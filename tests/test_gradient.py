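"""Mixed-effects gradient stage: estimates, df, AICc, elimination, sensitivity."""

import warnings

import numpy as np
import pandas as pd
import pytest

import pollinet as pn
from pollinet import (
    aicc_from_loglike,
    compare_elevation_vs_lui,
    fit_lmm,
    fit_metric_vs_elevation,
    intraspecific_dprime_model,
    robustness_predictor_model,
    sensitivity_suite,
    trait_and_taxon_models,
)

warnings.filterwarnings("ignore")


def simulate_site_data(rng, n_sites=18, per_site=4, beta=0.5, site_sd=0.7, resid_sd=1.0,
                       predictor="x"):
    x_site = rng.normal(size=n_sites)
    u = rng.normal(0, site_sd, n_sites)
    rows = []
    for i in range(n_sites):
        for _ in range(per_site):
            rows.append(
                {
                    "site_id": f"s{i:02d}",
                    predictor: x_site[i],
                    "y": 1.0 + beta * x_site[i] + u[i] + rng.normal(0, resid_sd),
                }
            )
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_t_equals_estimate_over_se(self):
        df = simulate_site_data(np.random.default_rng(0))
        fit = fit_lmm(df, "y", ["x"], "site_id")
        for term in fit.terms:
            assert term.t == pytest.approx(term.estimate / term.se)

    def test_containment_df_pattern(self):
        # between-site predictor: G - 2; intercept: N - G
        df = simulate_site_data(np.random.default_rng(1), n_sites=18, per_site=4)
        fit = fit_lmm(df, "y", ["x"], "site_id")
        assert fit.term("x").df == 16
        assert fit.term("Intercept").df == 72 - 18

    def test_constant_response_has_no_slope(self):
        df = simulate_site_data(np.random.default_rng(2))
        df["y"] = 3.0
        fit = fit_lmm(df, "y", ["x"], "site_id")
        assert abs(fit.term("x").estimate) < 1e-6
        assert fit.r2_fixed == pytest.approx(0.0, abs=1e-4)

    def test_balanced_reml_matches_anova_variance_components(self):
        # balanced one-way design: REML equals the closed-form moment
        # estimators sigma_b^2 = (MSB - MSW)/k, sigma_e^2 = MSW
        rng = np.random.default_rng(3)
        n_sites, k = 12, 5
        u = rng.normal(0, 1.2, n_sites)
        rows = [
            {"site_id": f"s{i}", "y": u[i] + rng.normal(0, 0.8)}
            for i in range(n_sites)
            for _ in range(k)
        ]
        df = pd.DataFrame(rows)
        fit = fit_lmm(df, "y", [], "site_id", compute_aicc=False)
        means = df.groupby("site_id")["y"].mean()
        msw = df.groupby("site_id")["y"].var(ddof=1).mean()
        msb = k * means.var(ddof=1)
        assert fit.resid_sd**2 == pytest.approx(msw, abs=1e-5)
        assert fit.random_sd["site_id"] ** 2 == pytest.approx((msb - msw) / k, abs=1e-5)

    def test_slope_recovery_and_coverage_smoke(self):
        rng = np.random.default_rng(4)
        est, cover = [], 0
        for _ in range(40):
            df = simulate_site_data(rng, n_sites=15, per_site=4)
            term = fit_lmm(df, "y", ["x"], "site_id", compute_aicc=False).term("x")
            est.append(term.estimate)
            lo, hi = term.ci()
            cover += lo <= 0.5 <= hi
        assert np.mean(est) == pytest.approx(0.5, abs=0.08)
        assert 0.80 <= cover / 40 <= 1.0


class TestAiccComparison:
    def test_formula(self):
        # AIC 10 vs 14 at equal k and n: corrections cancel, delta stays 4
        a = aicc_from_loglike((2 * 3 - 10) / 2, 3, 62)
        b = aicc_from_loglike((2 * 3 - 14) / 2, 3, 62)
        assert b - a == pytest.approx(4.0)
        with pytest.raises(ValueError):
            aicc_from_loglike(0.0, 10, 11)

    def test_identical_predictors_tie(self):
        df = simulate_site_data(np.random.default_rng(5))
        df["elevation"] = df["x"]
        df["LUI"] = df["x"]
        cmp = compare_elevation_vs_lui(df, "y")
        assert cmp.delta == pytest.approx(0.0, abs=1e-6)
        assert cmp.similarly_supported

    def test_elevation_driven_metric_prefers_elevation(self):
        rng = np.random.default_rng(6)
        wins = 0
        for _ in range(12):
            df = simulate_site_data(rng, beta=0.8, predictor="elevation")
            site_elev = df.groupby("site_id")["elevation"].first()
            lui = pd.Series(rng.normal(size=len(site_elev)), index=site_elev.index)
            df["LUI"] = df["site_id"].map(lui)
            if compare_elevation_vs_lui(df, "y").delta > 0:
                wins += 1
        assert wins >= 9


class TestIntraspecificModel:
    @staticmethod
    def simulate_scores(rng, slope=0.02, n_species=30, n_sites=15):
        mats = np.linspace(3, 24, n_sites)
        sp_eff = rng.normal(0, 0.08, n_species)
        site_eff = rng.normal(0, 0.04, n_sites)
        rows = []
        for s in range(n_species):
            sites = rng.choice(n_sites, size=rng.integers(3, 8), replace=False)
            for i in sites:
                rows.append(
                    {
                        "species": f"sp{s}",
                        "site_id": f"s{i}",
                        "MAT": mats[i],
                        "d_prime": np.clip(
                            0.3 + slope * mats[i] + sp_eff[s] + site_eff[i]
                            + rng.normal(0, 0.08),
                            0,
                            1,
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def test_positive_temperature_slope_detected(self):
        rng = np.random.default_rng(7)
        detected = 0
        for _ in range(10):
            fit = intraspecific_dprime_model(self.simulate_scores(rng))
            term = fit.term("MAT")
            detected += term.estimate > 0 and term.p < 0.05
        assert detected >= 9

    def test_constant_mat_errors(self):
        rng = np.random.default_rng(8)
        df = self.simulate_scores(rng)
        df["MAT"] = 10.0
        with pytest.raises(ValueError, match="constant"):
            intraspecific_dprime_model(df)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        df = self.simulate_scores(rng)
        f1 = intraspecific_dprime_model(df)
        f2 = intraspecific_dprime_model(df.sample(frac=1, random_state=1))
        assert f1.term("MAT").estimate == pytest.approx(f2.term("MAT").estimate, abs=1e-8)

    def test_min_sites_filter_enforced(self):
        df = pd.DataFrame(
            {
                "species": ["a"] * 2 + ["b"] * 2,
                "site_id": ["s1", "s2"] * 2,
                "MAT": [5.0, 10.0] * 2,
                "d_prime": [0.1, 0.2, 0.3, 0.4],
            }
        )
        with pytest.raises(ValueError):
            intraspecific_dprime_model(df, min_sites=3)


def simulate_species_table(rng, n_species=90, group_offset=0.15, trait_effect=0.0):
    groups = rng.choice(["bee", "wasp", "syrphid"], n_species, p=[0.6, 0.15, 0.25])
    order = np.where(groups == "syrphid", "Diptera", "Hymenoptera")
    family = [
        {"bee": "Apidae", "wasp": "Vespidae", "syrphid": "Syrphidae"}[g] for g in groups
    ]
    genus = [f"{f[:3]}g{rng.integers(8)}" for f in family]
    probo = np.exp(rng.normal(0.8, 0.4, n_species))
    d = np.clip(
        0.35
        + group_offset * (order == "Hymenoptera")
        + trait_effect * probo
        + rng.normal(0, 0.12, n_species),
        0,
        1,
    )
    return pd.DataFrame(
        {
            "species": [f"sp{i}" for i in range(n_species)],
            "group": groups,
            "order": order,
            "family": family,
            "genus": genus,
            "proboscis_length": probo,
            "head_width": np.exp(rng.normal(0.9, 0.3, n_species)),
            "elev_range": rng.uniform(0, 3000, n_species),
            "mean_dprime": d,
            "n_obs": rng.integers(3, 12, n_species),
        }
    )


class TestTraitModels:
    def test_group_contrast_recovered(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(8):
            fits = trait_and_taxon_models(simulate_species_table(rng))
            term = fits["group"].term("is_hymenoptera")
            lo, hi = term.ci()
            hits += lo <= 0.15 <= hi
        assert hits >= 6

    def test_null_trait_rarely_significant(self):
        rng = np.random.default_rng(11)
        false_pos = 0
        for _ in range(20):
            fits = trait_and_taxon_models(simulate_species_table(rng, group_offset=0.0))
            false_pos += fits["proboscis_length"].term("proboscis_length").p < 0.05
        assert false_pos <= 4  # ~5% nominal rate

    def test_unresolved_taxonomy_errors_with_names(self):
        rng = np.random.default_rng(12)
        df = simulate_species_table(rng)
        df.loc[0, "genus"] = np.nan
        with pytest.raises(ValueError, match="sp0"):
            trait_and_taxon_models(df)


class TestRobustnessPredictors:
    @staticmethod
    def simulate(rng, h2_effect=-0.5, noise=0.3, n_sites=16, per_site=4):
        rows = []
        for i in range(n_sites):
            u = rng.normal(0, 0.15)
            for _ in range(per_site):
                h2 = rng.uniform(0, 1)
                rows.append(
                    {
                        "site_id": f"s{i}",
                        "h2_prime": h2,
                        "std_nestedness": rng.normal(),
                        "MAT": rng.uniform(3, 24),
                        "LUI": rng.normal(),
                        "R": 0.7 + h2_effect * h2 + u + rng.normal(0, noise),
                    }
                )
        return pd.DataFrame(rows)

    PREDICTORS = ["h2_prime", "std_nestedness", "MAT", "LUI"]

    def test_true_predictor_retained(self):
        rng = np.random.default_rng(13)
        kept = 0
        for _ in range(10):
            fit, trace = robustness_predictor_model(self.simulate(rng), "R", self.PREDICTORS)
            names = {t.name for t in fit.terms} - {"Intercept"}
            kept += names == {"h2_prime"}
            assert len(trace) <= 4
        assert kept >= 8

    def test_pure_noise_usually_empties(self):
        rng = np.random.default_rng(14)
        empty = 0
        for _ in range(10):
            fit, _ = robustness_predictor_model(
                self.simulate(rng, h2_effect=0.0), "R", self.PREDICTORS
            )
            empty += len(fit.terms) == 1  # intercept only
        assert empty >= 6  # ~(1-alpha)^4 = 81% expectation


class TestSensitivitySuite:
    def test_consistency_and_subsets(self, strong_study):
        table = pn.walk_metric_table(strong_study)
        metrics = ["mean_dprime_pollinator", "h2_prime"]
        from pollinet import build_networks, filter_networks, pool_site_networks
        from pollinet.indices import H2Result, h2prime

        nets = filter_networks(build_networks(strong_study.records), 5)
        site_map = dict(zip(strong_study.walks["walk_id"], strong_study.walks["site_id"]))
        pooled = pool_site_networks(nets, site_map, min_walks=5)
        elev = dict(zip(strong_study.sites["site_id"], strong_study.sites["elevation"]))
        pooled_rows = []
        for p in pooled:
            res = h2prime(p)
            if isinstance(res, H2Result):
                pooled_rows.append({"site_id": p.walk_id, "h2_prime": res.h2_prime,
                                    "elevation": elev[p.walk_id]})
        pooled_h2 = pd.DataFrame(pooled_rows)
        report = sensitivity_suite(
            table, metrics, pooled_h2=pooled_h2, low_elevation_cutoff=10000.0
        )
        # (a) site-mean OLS slope signs match the walk-level mixed models
        for m in metrics:
            lmm = fit_metric_vs_elevation(table.dropna(subset=[m]), m)
            ols_row = report["site_mean_ols"].set_index("metric").loc[m]
            assert np.sign(ols_row["slope"]) == np.sign(lmm.term("elevation").estimate)
        # (c) cutoff above the gradient top = no subsetting at all
        for m in metrics:
            full = fit_metric_vs_elevation(table.dropna(subset=[m]), m)
            sub = report["below_cutoff_lmm"].set_index("metric").loc[m]
            assert sub["slope"] == pytest.approx(full.term("elevation").estimate, rel=1e-6)
        # (d) pooled analysis covers exactly the >=5-walk sites
        assert report["pooled_network_ols"].iloc[0]["n"] == len(pooled_h2)
        from collections import Counter

        walk_counts = Counter(site_map[n.walk_id] for n in nets)
        assert len(pooled) == sum(1 for c in walk_counts.values() if c >= 5)
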