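"""Build quantitative plant-pollinator networks from transect-walk records.

The sampling unit is a single transect walk: every flower visit observed
during one walk contributes to exactly one interaction matrix.  Species
(including morphospecies) are therefore identified by their taxon label
*within* a walk; networks from different walks are never merged implicitly.
Pooling walks into one joint network per site is an explicit, documented
approximation (`pool_site_networks`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Pollinator groups that enter networks.  Flower visitors outside these
#: groups (butterflies, non-syrphid Diptera, unknowns) are mapped to
#: "other" and always excluded.
POLLINATOR_GROUPS = ("bee", "wasp", "syrphid", "other")
DEFAULT_GROUPS_KEPT = frozenset({"bee", "wasp", "syrphid"})

INTERACTION_COLUMNS = (
    "site_id",
    "walk_id",
    "plant_taxon",
    "pollinator_taxon",
    "pollinator_group",
    "count",
)


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """An input row violates a domain invariant."""


class UndefinedRateError(ZeroDivisionError):
    """Visitation rate requested for a walk without any flowers."""


@dataclass(frozen=True)
class InteractionRecord:
    """One observed visit event (possibly aggregated into a count)."""

    site_id: str
    walk_id: str
    plant_taxon: str
    pollinator_taxon: str
    pollinator_group: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValidationError(f"count must be >= 1, got {self.count}")
        if self.pollinator_group not in POLLINATOR_GROUPS:
            object.__setattr__(self, "pollinator_group", "other")


@dataclass(frozen=True)
class QuantNetwork:
    """Integer plant x pollinator interaction matrix for one sampling unit.

    Rows are plants (the lower trophic level), columns pollinators (the
    higher level).  ``a[i, j]`` counts interactions between plant ``i`` and
    pollinator ``j``.  Marginal totals are exact integer sums; networks
    never carry all-zero rows or columns.
    """

    walk_id: str
    plants: tuple[str, ...]
    pollinators: tuple[str, ...]
    a: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape != (len(self.plants), len(self.pollinators)):
            raise ValidationError("matrix shape does not match labels")
        if not np.issubdtype(a.dtype, np.integer):
            if not np.allclose(a, np.round(a)):
                raise ValidationError("interaction matrix must be integer-valued")
            a = np.round(a).astype(np.int64)
        if (a < 0).any():
            raise ValidationError("interaction counts must be nonnegative")
        if (a.sum(axis=1) == 0).any() or (a.sum(axis=0) == 0).any():
            raise ValidationError("network has an all-zero row or column")
        object.__setattr__(self, "a", a.astype(np.int64))

    @property
    def row_totals(self) -> np.ndarray:
        return self.a.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.a.sum(axis=0)

    @property
    def m(self) -> int:
        return int(self.a.sum())

    @property
    def n_plants(self) -> int:
        return len(self.plants)

    @property
    def n_pollinators(self) -> int:
        return len(self.pollinators)

    def transpose(self) -> "QuantNetwork":
        """Swap trophic levels (plants become columns)."""
        return QuantNetwork(self.walk_id, self.pollinators, self.plants, self.a.T)


def read_interactions(path: str | Path, delimiter: str | None = None) -> list[InteractionRecord]:
    """Read a long-format interaction table (CSV by default, TSV accepted).

    Raises :class:`SchemaError` if a required column is missing and
    :class:`ValidationError` (naming the offending row) for nonpositive
    counts.  Unknown pollinator groups are mapped to ``"other"``.
    Record order follows file order.
    """
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python")
    else:
        df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"interaction table is missing column(s): {', '.join(missing)}")
    records: list[InteractionRecord] = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        count = int(getattr(row, "count"))
        if count < 1:
            raise ValidationError(f"row {pos}: count must be >= 1, got {count}")
        records.append(
            InteractionRecord(
                site_id=str(row.site_id),
                walk_id=str(row.walk_id),
                plant_taxon=str(row.plant_taxon),
                pollinator_taxon=str(row.pollinator_taxon),
                pollinator_group=str(row.pollinator_group),
                count=count,
            )
        )
    return records


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    """Write records back to CSV with the canonical six-column schema."""
    df = pd.DataFrame([r.__dict__ for r in records], columns=list(INTERACTION_COLUMNS))
    df.to_csv(path, index=False)


def build_networks(
    records: Iterable[InteractionRecord],
    groups_kept: frozenset[str] | set[str] = DEFAULT_GROUPS_KEPT,
) -> list[QuantNetwork]:
    """Assemble one quantitative network per transect walk.

    Only records whose pollinator group is in ``groups_kept`` enter a
    network; ``"other"`` is always dropped.  Counts for repeated
    (plant, pollinator) pairs within a walk are summed.  Rows and columns
    are sorted lexicographically so the result is independent of record
    order.
    """
    kept = frozenset(groups_kept) & (frozenset(POLLINATOR_GROUPS) - {"other"})
    by_walk: dict[str, dict[tuple[str, str], int]] = {}
    for rec in records:
        if rec.pollinator_group not in kept:
            continue
        cells = by_walk.setdefault(rec.walk_id, {})
        key = (rec.plant_taxon, rec.pollinator_taxon)
        cells[key] = cells.get(key, 0) + rec.count
    networks = []
    for walk_id in sorted(by_walk):
        cells = by_walk[walk_id]
        plants = tuple(sorted({p for p, _ in cells}))
        pollinators = tuple(sorted({q for _, q in cells}))
        a = np.zeros((len(plants), len(pollinators)), dtype=np.int64)
        p_ix = {p: i for i, p in enumerate(plants)}
        q_ix = {q: j for j, q in enumerate(pollinators)}
        for (p, q), c in cells.items():
            a[p_ix[p], q_ix[q]] = c
        networks.append(QuantNetwork(walk_id, plants, pollinators, a))
    return networks


def filter_networks(networks: Sequence[QuantNetwork], min_interactions: int = 5) -> list[QuantNetwork]:
    """Keep networks with at least ``min_interactions`` total events (m)."""
    if min_interactions < 1:
        raise ValueError("min_interactions must be >= 1")
    kept = [n for n in networks if n.m >= min_interactions]
    removed = len(networks) - len(kept)
    if removed:
        logger.info("filter_networks: removed %d network(s) with m < %d", removed, min_interactions)
    return kept


def matrix_size(net: QuantNetwork) -> int:
    """Number of plant species times number of pollinator species."""
    return net.n_plants * net.n_pollinators


def pool_site_networks(
    networks: Sequence[QuantNetwork],
    site_map: Mapping[str, str],
    min_walks: int = 5,
) -> list[QuantNetwork]:
    """Lump walk-level networks into one joint network per site.

    Only sites contributing at least ``min_walks`` networks are pooled;
    species are matched by taxon label within a site (an approximation for
    morphospecies, which are only strictly comparable within one walk).
    The pooled network's ``walk_id`` is the site id.
    """
    by_site: dict[str, list[QuantNetwork]] = {}
    for net in networks:
        if net.walk_id not in site_map:
            raise KeyError(f"walk {net.walk_id!r} not present in site_map")
        by_site.setdefault(site_map[net.walk_id], []).append(net)
    pooled = []
    for site_id in sorted(by_site):
        nets = by_site[site_id]
        if len(nets) < min_walks:
            continue
        cells: dict[tuple[str, str], int] = {}
        for net in nets:
            for i, p in enumerate(net.plants):
                for j, q in enumerate(net.pollinators):
                    if net.a[i, j]:
                        key = (p, q)
                        cells[key] = cells.get(key, 0) + int(net.a[i, j])
        plants = tuple(sorted({p for p, _ in cells}))
        pollinators = tuple(sorted({q for _, q in cells}))
        a = np.zeros((len(plants), len(pollinators)), dtype=np.int64)
        p_ix = {p: i for i, p in enumerate(plants)}
        q_ix = {q: j for j, q in enumerate(pollinators)}
        for (p, q), c in cells.items():
            a[p_ix[p], q_ix[q]] = c
        pooled.append(QuantNetwork(site_id, plants, pollinators, a))
    return pooled


def visitation_rate(n_interactions: int, flower_abundance: int) -> float:
    """Interactions per flower head during one walk (insect activity proxy)."""
    if flower_abundance <= 0:
        raise UndefinedRateError("visitation rate undefined: flower_abundance is zero")
    return n_interactions / flower_abundance


def elevational_range(occurrences: Iterable[tuple[str, float]]) -> dict[str, float]:
    """Elevational range per species: max minus min elevation of occurrence."""
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    for species, elev in occurrences:
        e = float(elev)
        lo[species] = min(lo.get(species, e), e)
        hi[species] = max(hi.get(species, e), e)
    return {s: hi[s] - lo[s] for s in lo}
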