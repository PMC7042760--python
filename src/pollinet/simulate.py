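"""Synthetic elevational-gradient studies with known ground truth.

The generator emulates a transect-walk study of plant-pollinator networks
on a tropical mountain: sites evenly spaced along an elevational gradient,
mean annual temperature declining linearly with elevation, species pools
thinning towards the summit, an unbalanced number of walks per site, and a
composite land-use index negatively correlated with elevation.

The causal knob of interest is the temperature-specialization link: each
pollinator at a site draws its flower preference vector from a Dirichlet
distribution whose concentration is alpha(MAT) = exp(a0 - a1 * MAT) times
local flower availability.  With a1 > 0, warm sites get small
concentrations, i.e. sticky, specialized preferences; a1 = 0 switches the
link off.  Every generated study carries its ground truth so recovery can
be scored exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import InteractionRecord, write_interactions

HABITAT_BANDS = (
    (1300.0, "savanna", 0.15),
    (2000.0, "lower_montane", 0.55),
    (2800.0, "ocotea_forest", 0.85),
    (3500.0, "podocarpus_forest", 0.75),
    (4000.0, "erica_forest", 0.45),
    (float("inf"), "alpine", 0.05),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters; defaults mirror the emulated design."""

    n_sites: int = 18
    elevation_min: float = 993.0
    elevation_max: float = 4390.0
    mat_warm: float = 24.0  # deg C at elevation_min
    mat_cold: float = 3.1   # deg C at elevation_max
    walks_min: int = 1
    walks_max: int = 8
    plant_pool_size: int = 60
    pollinator_pool_size: int = 120
    plant_richness_low: float = 22.0      # site plant richness at the bottom
    plant_richness_decay: float = 0.45    # per km of elevation
    pollinator_richness_low: float = 35.0
    pollinator_richness_decay: float = 0.50
    a0: float = 3.0   # log baseline Dirichlet concentration
    a1: float = 0.20  # temperature -> specialization effect (per deg C)
    mean_interactions: float = 65.0  # per-walk event count, NB-distributed
    dispersion: float = 3.0          # NB size parameter (overdispersion)
    interaction_temp_effect: float = 0.03  # activity increase per deg C of ACT
    flower_abund_meanlog: float = math.log(500.0)
    flower_abund_trend: float = -0.25  # per km, on the log scale
    flower_abund_sdlog: float = 0.6
    act_offset: float = 2.0  # walks happen in the warm hours of the day
    act_sd: float = 1.5
    other_group_rate: float = 0.05  # excluded visitors (e.g. butterflies)
    lui_elev_corr: float = -0.57
    seed: int = 0

    @classmethod
    def null(cls, seed: int = 0) -> "GeneratorConfig":
        """A study with no elevational structure at all.

        Switches off the temperature-specialization link *and* every other
        elevational dependence (richness decay, abundance trend, and the
        temperature-activity link that would otherwise make event counts -
        and with them the residual small-sample bias of d' - trend with
        elevation).  This makes the community-level specialization slope
        against elevation exactly null: the honest reference for type-I
        error calibration of the gradient stage.
        """
        return cls(
            a1=0.0,
            plant_richness_decay=0.0,
            pollinator_richness_decay=0.0,
            flower_abund_trend=0.0,
            interaction_temp_effect=0.0,
            seed=seed,
        )


@dataclass(frozen=True)
class GroundTruth:
    a1: float
    site_richness: dict[str, tuple[int, int]]           # site -> (plants, pollinators)
    preferences: dict[str, dict[str, dict[str, float]]]  # site -> pollinator -> plant -> pref
    lui_ranks: dict[str, int]
    expected_slope_signs: dict[str, int]
    walk_truth: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticStudy:
    config: GeneratorConfig
    records: list[InteractionRecord]
    sites: pd.DataFrame
    walks: pd.DataFrame
    traits: pd.DataFrame
    ground_truth: GroundTruth


def _habitat(elev: float) -> tuple[str, float]:
    for upper, name, canopy in HABITAT_BANDS:
        if elev < upper:
            return name, canopy
    raise AssertionError


def _exact_corr_vector(z_anchor: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance vector with exactly sample correlation rho to z_anchor."""
    if abs(rho) > 1:
        raise ValueError(f"correlation target {rho} outside [-1, 1]")
    n = len(z_anchor)
    eps = rng.normal(size=n)
    eps -= eps.mean()
    eps -= z_anchor * (eps @ z_anchor) / (z_anchor @ z_anchor)
    sd = eps.std(ddof=0)
    if sd == 0:  # pragma: no cover - measure-zero event
        raise RuntimeError("degenerate noise vector")
    eps /= sd
    return rho * z_anchor + math.sqrt(1 - rho**2) * eps


def generate_study(config: GeneratorConfig | None = None) -> SyntheticStudy:
    """Draw one complete synthetic study from a single seed.

    All randomness flows from ``config.seed`` through named substreams
    (sites, species, walks, lui), so output is reproducible bit for bit.
    """
    cfg = config or GeneratorConfig()
    root = np.random.SeedSequence(cfg.seed)
    rng_species, rng_sites, rng_walks, rng_lui = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    elevations = np.linspace(cfg.elevation_min, cfg.elevation_max, cfg.n_sites)
    lapse = (cfg.mat_cold - cfg.mat_warm) / (cfg.elevation_max - cfg.elevation_min)
    site_ids = [f"S{i:02d}" for i in range(cfg.n_sites)]

    # --- global species pools with elevational windows -------------------
    def pool(prefix: str, size: int, rng: np.random.Generator) -> pd.DataFrame:
        centers = rng.uniform(cfg.elevation_min, cfg.elevation_max, size)
        half = rng.uniform(500.0, 2000.0, size)
        return pd.DataFrame(
            {"species": [f"{prefix}{k:03d}" for k in range(size)], "center": centers, "half": half}
        )

    plants = pool("P", cfg.plant_pool_size, rng_species)
    pollinators = pool("A", cfg.pollinator_pool_size, rng_species)
    groups = rng_species.choice(["bee", "wasp", "syrphid"], size=cfg.pollinator_pool_size,
                                p=[0.78, 0.07, 0.15])
    pollinators["group"] = groups
    pollinators["order"] = np.where(groups == "syrphid", "Diptera", "Hymenoptera")
    family_map = {"bee": ["Apidae", "Halictidae", "Megachilidae"],
                  "wasp": ["Vespidae", "Crabronidae"], "syrphid": ["Syrphidae"]}
    pollinators["family"] = [
        family_map[g][rng_species.integers(len(family_map[g]))] for g in groups
    ]
    pollinators["genus"] = [
        f"{fam[:4]}_g{rng_species.integers(6)}" for fam in pollinators["family"]
    ]
    # traits: bees carry longer proboscides on average; head width ~ body size
    base_probo = {"bee": 1.3, "wasp": 0.7, "syrphid": 0.9}
    pollinators["proboscis_length"] = [
        float(np.exp(rng_species.normal(base_probo[g], 0.35))) for g in groups
    ]
    pollinators["head_width"] = np.exp(rng_species.normal(0.9, 0.3, cfg.pollinator_pool_size))

    # --- sites ------------------------------------------------------------
    habitats = [_habitat(e) for e in elevations]
    canopy = np.clip(
        [h[1] + rng_sites.normal(0, 0.05) for h in habitats], 0.0, 1.0
    )
    mat = cfg.mat_warm + (elevations - cfg.elevation_min) * lapse
    mapr = 590.0 + (2740.0 - 590.0) * np.exp(-(((elevations - 2200.0) / 1200.0) ** 2))
    area = 50.0 * np.exp(-0.0006 * (elevations - cfg.elevation_min)) * np.exp(
        rng_sites.normal(0, 0.1, cfg.n_sites)
    )
    z_elev = (elevations - elevations.mean()) / elevations.std(ddof=0)
    lui = _exact_corr_vector(z_elev, cfg.lui_elev_corr, rng_lui)

    def local_pool(df: pd.DataFrame, elev: float, richness: float) -> pd.DataFrame:
        covering = df[(df["center"] - df["half"] <= elev) & (elev <= df["center"] + df["half"])]
        n = max(2, int(round(richness)))
        return covering.reindex(
            (covering["center"] - elev).abs().sort_values(kind="stable").index
        ).head(n)

    km = (elevations - cfg.elevation_min) / 1000.0
    site_plants: dict[str, pd.DataFrame] = {}
    site_pollinators: dict[str, pd.DataFrame] = {}
    availability: dict[str, np.ndarray] = {}
    activity: dict[str, np.ndarray] = {}
    preferences: dict[str, dict[str, dict[str, float]]] = {}
    pref_vectors: dict[str, np.ndarray] = {}
    site_richness: dict[str, tuple[int, int]] = {}
    alpha_site = np.exp(cfg.a0 - cfg.a1 * mat)
    for i, sid in enumerate(site_ids):
        sp = local_pool(plants, elevations[i], cfg.plant_richness_low
                        * math.exp(-cfg.plant_richness_decay * km[i]))
        sa = local_pool(pollinators, elevations[i], cfg.pollinator_richness_low
                        * math.exp(-cfg.pollinator_richness_decay * km[i]))
        site_plants[sid], site_pollinators[sid] = sp, sa
        site_richness[sid] = (len(sp), len(sa))
        avail = rng_sites.dirichlet(np.full(len(sp), 1.2))
        availability[sid] = avail
        activity[sid] = np.exp(rng_sites.normal(0.0, 0.7, len(sa)))
        prefs_here: dict[str, dict[str, float]] = {}
        for j, species in enumerate(sa["species"]):
            alpha = np.maximum(alpha_site[i] * avail, 1e-4)
            gamma = rng_sites.gamma(alpha)
            if gamma.sum() <= 0:  # extreme concentration underflow
                gamma = np.zeros(len(sp))
                gamma[int(rng_sites.choice(len(sp), p=avail))] = 1.0
            pref = gamma / gamma.sum()
            pref_vectors[f"{sid}:{species}"] = pref
            prefs_here[species] = {p: float(v) for p, v in zip(sp["species"], pref)}
        preferences[sid] = prefs_here

    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "elevation": elevations,
            "MAT": mat,
            "MAP": mapr,
            "LUI": lui,
            "area": area,
            "canopy_cover": canopy,
            "habitat": [h[0] for h in habitats],
        }
    )

    # --- walks and interaction events ------------------------------------
    records: list[InteractionRecord] = []
    walk_rows = []
    walk_truth: dict[str, dict[str, float]] = {}
    for i, sid in enumerate(site_ids):
        n_walks = int(rng_walks.integers(cfg.walks_min, cfg.walks_max + 1))
        sp = site_plants[sid]["species"].to_numpy()
        sa = site_pollinators[sid]["species"].to_numpy()
        sa_groups = site_pollinators[sid]["group"].to_numpy()
        avail = availability[sid]
        act_w = activity[sid]
        for w in range(n_walks):
            walk_id = f"{sid}-w{w:02d}"
            meanlog = cfg.flower_abund_meanlog + cfg.flower_abund_trend * km[i]
            flower_abundance = max(1, int(round(rng_walks.lognormal(meanlog, cfg.flower_abund_sdlog))))
            present = rng_walks.random(len(sp)) < 0.8
            if not present.any():
                present[int(np.argmax(avail))] = True
            walk_avail = avail * present
            walk_avail = walk_avail / walk_avail.sum()
            flower_richness = int(present.sum())
            act = float(mat[i] + rng_walks.normal(cfg.act_offset, cfg.act_sd))
            mu = cfg.mean_interactions * (flower_abundance / 500.0) ** 0.3 * math.exp(
                cfg.interaction_temp_effect * (act - 15.0)
            )
            mu = float(np.clip(mu, 1.0, 400.0))
            p_nb = cfg.dispersion / (cfg.dispersion + mu)
            n_events = int(rng_walks.negative_binomial(cfg.dispersion, p_nb))
            active = rng_walks.random(len(sa)) < 0.6
            if not active.any():
                active[int(np.argmax(act_w))] = True
            weights = act_w * active
            weights = weights / weights.sum()
            cells: dict[tuple[str, str, str], int] = {}
            if n_events > 0:
                per_poll = rng_walks.multinomial(n_events, weights)
                for j, count in enumerate(per_poll):
                    if count == 0:
                        continue
                    pref = pref_vectors[f"{sid}:{sa[j]}"] * present
                    if pref.sum() <= 0:
                        pref = walk_avail
                    pref = pref / pref.sum()
                    plants_hit = rng_walks.multinomial(count, pref)
                    for k, c in enumerate(plants_hit):
                        if c:
                            key = (sp[k], sa[j], sa_groups[j])
                            cells[key] = cells.get(key, 0) + int(c)
            for (plant, poll, grp), c in sorted(cells.items()):
                records.append(InteractionRecord(sid, walk_id, plant, poll, grp, c))
            # excluded visitor groups (butterflies etc.) observed but dropped later
            n_other = int(rng_walks.poisson(cfg.other_group_rate * max(n_events, 1)))
            for k in range(n_other):
                plant = sp[int(rng_walks.choice(len(sp), p=walk_avail))]
                records.append(
                    InteractionRecord(sid, walk_id, plant, f"X{k:02d}", "other", 1)
                )
            walk_rows.append(
                {
                    "walk_id": walk_id,
                    "site_id": sid,
                    "ACT": act,
                    "flower_abundance": flower_abundance,
                    "flower_richness": flower_richness,
                    "n_interactions": n_events,
                    "visitation_rate": n_events / flower_abundance,
                }
            )
            walk_truth[walk_id] = {
                "n_events": float(n_events),
                "flower_abundance": float(flower_abundance),
                "visitation_rate": n_events / flower_abundance,
            }

    walks = pd.DataFrame(walk_rows)
    traits = site_pollinators_traits(pollinators)
    sign = -1 if cfg.a1 > 0 else 0
    truth = GroundTruth(
        a1=cfg.a1,
        site_richness=site_richness,
        preferences=preferences,
        lui_ranks={sid: int(r) for sid, r in zip(site_ids, pd.Series(lui).rank().astype(int))},
        expected_slope_signs={
            "mean_dprime_pollinator": sign,
            "mean_dprime_plant": sign,
            "h2_prime": sign,
        },
        walk_truth=walk_truth,
    )
    return SyntheticStudy(cfg, records, sites, walks, traits, truth)


def site_pollinators_traits(pollinators: pd.DataFrame) -> pd.DataFrame:
    cols = ["species", "group", "order", "family", "genus", "proboscis_length", "head_width"]
    return pollinators[cols].copy()


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the study as delimited text + ground-truth JSON (round-trips)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_interactions(study.records, out / "interactions.csv")
    study.sites.to_csv(out / "sites.csv", index=False)
    study.walks.to_csv(out / "walks.csv", index=False)
    study.traits.to_csv(out / "traits.csv", index=False)
    gt = asdict(study.ground_truth)
    gt["config"] = asdict(study.config)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=1, sort_keys=True)


@dataclass(frozen=True)
class RecoveryReport:
    slopes: pd.DataFrame           # metric, estimate, t, p, expected_sign, sign_ok
    sem_best_has_mat_edge: bool
    sem_delta_without_mat_edge: float
    robustness_h2_estimate: float
    robustness_h2_p: float
    n_networks: int


def walk_metric_table(study: SyntheticStudy, min_interactions: int = 5) -> pd.DataFrame:
    """Run assembly + indices on a study; one row per retained network."""
    from .assembly import build_networks, filter_networks
    from .indices import network_index_table

    nets = filter_networks(build_networks(study.records), min_interactions)
    table = network_index_table(nets)
    table = table.merge(study.walks, on="walk_id", how="left")
    table = table.merge(study.sites, on="site_id", how="left")
    table["log_matrix_size"] = np.log(table["matrix_size"])
    table["log_flower_abundance"] = np.log(table["flower_abundance"])
    return table


def recover_parameters(
    study: SyntheticStudy,
    n_orders: int = 50,
    include_robustness: bool = True,
    seed: int = 0,
) -> RecoveryReport:
    """Full-pipeline recovery check against the study's ground truth.

    Reports the elevation slopes of community pollinator d', plant d' and
    H2' (sign-scored against the generator), whether the best path model by
    AICc keeps the direct MAT -> specialization edge, and the
    robustness-vs-H2' relationship.
    """
    from .assembly import build_networks, filter_networks
    from .gradient import fit_lmm, fit_metric_vs_elevation
    from .robustness import robustness
    from .sem import exhaustive_path_search

    table = walk_metric_table(study)
    truth = study.ground_truth
    rows = []
    for metric in ("mean_dprime_pollinator", "mean_dprime_plant", "h2_prime"):
        sub = table[[metric, "elevation", "site_id"]].dropna()
        fit = fit_metric_vs_elevation(sub, metric)
        term = fit.term("elevation")
        expected = truth.expected_slope_signs[metric]
        sign_ok = (
            (np.sign(term.estimate) == expected and term.p < 0.05)
            if expected != 0
            else term.p >= 0.05
        )
        rows.append(
            {
                "metric": metric,
                "estimate": term.estimate,
                "t": term.t,
                "p": term.p,
                "expected_sign": expected,
                "sign_ok": bool(sign_ok),
            }
        )
    slopes = pd.DataFrame(rows)

    sem_data = table[
        ["MAT", "log_flower_abundance", "flower_richness", "mean_dprime_pollinator", "site_id"]
    ].dropna()
    ranked = exhaustive_path_search(
        nodes=["MAT", "log_flower_abundance", "flower_richness", "mean_dprime_pollinator"],
        mandatory_edges=[
            ("MAT", "flower_richness"),
            ("log_flower_abundance", "flower_richness"),
        ],
        optional_edges=[
            ("MAT", "mean_dprime_pollinator"),
            ("flower_richness", "mean_dprime_pollinator"),
        ],
        data=sem_data,
        group="site_id",
    )
    best = ranked[0]
    has_edge = best.has_edge("MAT", "mean_dprime_pollinator")
    without = [r for r in ranked if not r.has_edge("MAT", "mean_dprime_pollinator")]
    delta_without = min(r.aicc for r in without) - best.aicc if without else float("nan")

    rob_est = rob_p = float("nan")
    if include_robustness:
        nets = filter_networks(build_networks(study.records), 5)
        rob_rows = []
        for net in nets:
            h2_val = table.loc[table["walk_id"] == net.walk_id, "h2_prime"]
            if h2_val.empty or not np.isfinite(h2_val.iloc[0]):
                continue
            res = robustness(net, "pollinator", n_orders=n_orders, seed=seed)
            rob_rows.append(
                {
                    "walk_id": net.walk_id,
                    "R": res.R,
                    "h2_prime": float(h2_val.iloc[0]),
                    "site_id": table.loc[table["walk_id"] == net.walk_id, "site_id"].iloc[0],
                }
            )
        rob = pd.DataFrame(rob_rows)
        if len(rob) >= 5 and rob["site_id"].nunique() >= 2:
            fit = fit_lmm(rob, "R", ["h2_prime"], "site_id", compute_aicc=False)
            term = fit.term("h2_prime")
            rob_est, rob_p = term.estimate, term.p
    return RecoveryReport(
        slopes=slopes,
        sem_best_has_mat_edge=has_edge,
        sem_delta_without_mat_edge=float(delta_without),
        robustness_h2_estimate=float(rob_est),
        robustness_h2_p=float(rob_p),
        n_networks=int(len(table)),
    )


def generate_lui_components(n_sites: int = 18, seed: int = 0) -> tuple[pd.DataFrame, pd.Series]:
    """Site-level LUI component table with known intensity ranks.

    Components are strictly monotone transforms of a latent land-use
    intensity, so the composite index must recover the latent ranking
    exactly (Spearman correlation 1).  Returns (components, latent).
    """
    rng = np.random.default_rng(seed)
    latent = rng.uniform(0, 1, n_sites)
    df = pd.DataFrame(
        {
            "site_id": [f"S{i:02d}" for i in range(n_sites)],
            "biomass_removal": latent**1.5,
            "agri_inputs": 10.0 * np.sqrt(latent),
            "veg_dissimilarity": 2.0 * latent,
            "landscape_agri_prop": latent**2,
        }
    )
    return df, pd.Series(latent, index=df.index, name="latent_intensity")
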