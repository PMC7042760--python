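"""Specialization and structure indices for quantitative bipartite networks.

Implements the standardized Kullback-Leibler specialization index d' for
single species, the network-level complementary specialization H2', the
weighted nestedness metric WNODF, and signed dependence asymmetry.  d' and
H2' are standardized between integer-constrained extremes of the observed
marginal totals, so a value of 0 means "as generalized as the marginals
allow" and 1 means "as exclusive as the marginals allow".

The integer reference tables (d_min allocation, H2_min / H2_max matrices)
are built by deterministic constructive heuristics followed by a
single-unit local-improvement pass; on small matrices these provably reach
the exhaustive-enumeration optima (asserted in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .assembly import QuantNetwork

Level = Literal["plant", "pollinator"]


@dataclass(frozen=True)
class SpecializationScore:
    """Species-level specialization d' with its normalization bounds (nats)."""

    species: str
    level: Level
    d: float
    d_min: float
    d_max: float
    d_prime: float
    n_events: int


@dataclass(frozen=True)
class CommunitySummary:
    walk_id: str
    level: Level
    mean_dprime: float
    cv_dprime: float | None
    n_species: int


@dataclass(frozen=True)
class H2Result:
    """Network-level two-dimensional entropy and its standardized form."""

    h2: float
    h2_min: float
    h2_max: float
    h2_prime: float


@dataclass(frozen=True)
class NotComputable:
    """Typed marker for networks on which an index is undefined.

    Distinct from a numeric 0 or 1: e.g. H2' needs at least two species on
    each level and m >= 2.
    """

    reason: str

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return False


def _kl(counts: np.ndarray, q: np.ndarray) -> float:
    """KL divergence (nats) of the normalized count vector from q."""
    total = counts.sum()
    out = 0.0
    for c, qk in zip(counts, q):
        if c > 0:
            p = c / total
            out += p * math.log(p / qk)
    return out


def _min_kl_allocation(A: int, q: np.ndarray) -> np.ndarray:
    """Most-generalized integer allocation of A events across partners.

    Largest-remainder rounding of the proportional allocation A*q, then
    single-unit transfers while they reduce the KL divergence from q.
    The objective is separable and convex in the allocation, so unit-step
    descent terminates at the global integer optimum.
    """
    target = A * q
    x = np.floor(target).astype(np.int64)
    rem = A - x.sum()
    if rem > 0:
        frac = target - np.floor(target)
        # ties broken by index order (stable sort on negated fractions)
        order = np.argsort(-frac, kind="stable")
        for k in order[:rem]:
            x[k] += 1

    def term(v: np.ndarray) -> np.ndarray:
        out = np.zeros_like(v, dtype=float)
        nz = v > 0
        out[nz] = (v[nz] / A) * np.log(v[nz] / (A * q[nz]))
        return out

    while True:
        t0 = term(x)
        inc = term(x + 1) - t0                      # cost change of +1 unit
        dec = np.full(len(x), np.inf)
        pos = x > 0
        dec[pos] = term(x - 1)[pos] - t0[pos]       # cost change of -1 unit
        # best transfer src -> dst (src != dst) minimizing dec[src] + inc[dst];
        # consider the two smallest of each side to honor the src != dst rule
        s_ord = np.argsort(dec, kind="stable")[:2]
        d_ord = np.argsort(inc, kind="stable")[:2]
        best_pair, best_gain = None, -1e-12
        for s in s_ord:
            for d in d_ord:
                if s != d and dec[s] + inc[d] < best_gain:
                    best_pair, best_gain = (int(s), int(d)), dec[s] + inc[d]
        if best_pair is None:
            return x
        x[best_pair[0]] -= 1
        x[best_pair[1]] += 1


def species_dprime(net: QuantNetwork, level: Level) -> list[SpecializationScore]:
    """d' for every species on one trophic level of a network.

    For a focal species with counts ``a_k`` over partners k (species total
    A), partner availability is ``q_k = A_k / m``.  Then

        d     = sum_{a_k>0} (a_k/A) ln((a_k/A) / q_k)
        d_max = ln(m / A)                (all events on the rarest use)
        d_min = KL of the most-generalized integer allocation of A events
        d'    = (d - d_min) / (d_max - d_min), clamped to [0, 1].
    """
    if net.m == 0:
        raise ValueError("network is empty")
    if level == "pollinator":
        mat = net.a.T
        labels = net.pollinators
        partner_totals = net.row_totals
    elif level == "plant":
        mat = net.a
        labels = net.plants
        partner_totals = net.col_totals
    else:
        raise ValueError(f"unknown level {level!r}")
    m = net.m
    q = partner_totals / m
    scores = []
    for label, counts in zip(labels, mat):
        A = int(counts.sum())
        d = _kl(counts, q)
        d_max = math.log(m / A)
        d_min = _kl(_min_kl_allocation(A, q), q)
        if d_max - d_min <= 1e-12:
            d_prime = 0.0
        else:
            d_prime = (d - d_min) / (d_max - d_min)
        d_prime = min(1.0, max(0.0, d_prime))
        scores.append(SpecializationScore(label, level, d, d_min, d_max, d_prime, A))
    return scores


def community_dprime(
    scores: Sequence[SpecializationScore],
    walk_id: str = "",
    weighted: bool = True,
    population_sd: bool = True,
) -> CommunitySummary:
    """Community mean (abundance-weighted by default) and CV of d'.

    The CV is computed on the unweighted d' values (sd / mean, population
    sd by default) and is undefined for singleton communities or a zero
    mean.
    """
    if not scores:
        raise ValueError("no scores supplied")
    levels = {s.level for s in scores}
    if len(levels) != 1:
        raise ValueError("scores mix trophic levels")
    d = np.array([s.d_prime for s in scores], dtype=float)
    w = np.array([s.n_events for s in scores], dtype=float) if weighted else np.ones(len(scores))
    mean_w = float(np.average(d, weights=w))
    cv: float | None = None
    if len(d) >= 2 and d.mean() > 0:
        sd = float(d.std(ddof=0 if population_sd else 1))
        cv = sd / float(d.mean())
    return CommunitySummary(walk_id, scores[0].level, mean_w, cv, len(scores))


def species_mean_dprime(
    score_table: pd.DataFrame,
    min_obs: int = 3,
    species_col: str = "species",
    dprime_col: str = "d_prime",
) -> pd.Series:
    """Unweighted mean d' per species across networks.

    ``score_table`` holds one row per species x network.  Species occurring
    in fewer than ``min_obs`` networks are excluded.
    """
    grouped = score_table.groupby(species_col)[dprime_col]
    counts = grouped.count()
    means = grouped.mean()
    return means[counts >= min_obs]


# ---------------------------------------------------------------------------
# H2' reference tables


def _repair_rounded_table(expected: np.ndarray, row: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Integer table with the given marginals, near the expected table.

    Floors the expected values, then assigns the remaining units to cells
    with the largest fractional parts whose row and column still have a
    deficit; any stubborn remainder is placed by a transportation fill over
    the residual marginals.
    """
    x = np.floor(expected).astype(np.int64)
    r_def = row - x.sum(axis=1)
    c_def = col - x.sum(axis=0)
    frac = expected - np.floor(expected)
    order = np.argsort(-frac, axis=None, kind="stable")
    for flat in order:
        i, j = np.unravel_index(flat, x.shape)
        if r_def[i] > 0 and c_def[j] > 0:
            x[i, j] += 1
            r_def[i] -= 1
            c_def[j] -= 1
    # transportation fill for whatever is left (rare)
    while r_def.sum() > 0:
        i = int(np.argmax(r_def))
        j = int(np.argmax(c_def))
        add = min(r_def[i], c_def[j])
        x[i, j] += add
        r_def[i] -= add
        c_def[j] -= add
    return x


def _greedy_concentrated_table(
    row: np.ndarray, col: np.ndarray, first: tuple[int, int] | None = None
) -> np.ndarray:
    """Most-heterogeneous start: pair largest remaining marginals greedily.

    ``first`` optionally forces the initial placement cell; the rest of the
    fill follows the largest-row / largest-column rule (ties by index).
    """
    r = row.astype(np.int64).copy()
    c = col.astype(np.int64).copy()
    x = np.zeros((len(r), len(c)), dtype=np.int64)
    if first is not None:
        i, j = first
        amount = min(r[i], c[j])
        x[i, j] += amount
        r[i] -= amount
        c[j] -= amount
    while r.sum() > 0:
        i = int(np.argmax(r))  # argmax breaks ties by index order
        j = int(np.argmax(c))
        amount = min(r[i], c[j])
        x[i, j] += amount
        r[i] -= amount
        c[j] -= amount
    return x


def _entropy(x: np.ndarray) -> float:
    m = x.sum()
    p = x[x > 0] / m
    return float(-(p * np.log(p)).sum())


def _swap_polish(x: np.ndarray, maximize: bool) -> np.ndarray:
    """Steepest 2x2 unit-swap ascent/descent on matrix entropy.

    The move a[i,j]+t, a[k,l]+t, a[i,l]-t, a[k,j]-t preserves both
    marginals; these moves connect all integer tables with fixed marginals.
    For entropy maximization (concave objective, interior optimum) unit
    steps (t = 1) are taken; for minimization the optimum sits at a vertex
    of the transportation polytope, so each candidate swap is pushed to its
    full extent (t = min of the two decremented cells), hopping from vertex
    to vertex.  Entropy changes are evaluated incrementally (only four
    cells change), vectorized over all candidate quadruples.
    """
    x = x.astype(np.int64).copy()
    sign = 1.0 if maximize else -1.0
    nr, nc = x.shape
    m = x.sum()

    def cell_term(v: np.ndarray) -> np.ndarray:
        p = v / m
        out = np.zeros_like(p, dtype=float)
        nz = p > 0
        out[nz] = -p[nz] * np.log(p[nz])
        return out

    ii = np.arange(nr)
    jj = np.arange(nc)
    while True:
        H = cell_term(x)
        if maximize:
            t = np.ones((nr, nr, nc, nc), dtype=np.int64)
            invalid = (x[:, None, None, :] < 1) | (x[None, :, :, None] < 1)
            t[invalid] = 0
        else:
            t = np.minimum(x[:, None, None, :], x[None, :, :, None]).astype(np.int64)
            t = np.broadcast_to(t, (nr, nr, nc, nc)).copy()
        delta = sign * (
            cell_term(x[:, None, :, None] + t)
            + cell_term(x[None, :, None, :] + t)
            + cell_term(x[:, None, None, :] - t)
            + cell_term(x[None, :, :, None] - t)
            - (
                H[:, None, :, None]
                + H[None, :, None, :]
                + H[:, None, None, :]
                + H[None, :, :, None]
            )
        )
        delta[t == 0] = -np.inf
        delta[ii, ii, :, :] = -np.inf
        delta[:, :, jj, jj] = -np.inf
        flat = int(np.argmax(delta))
        if not np.isfinite(delta.flat[flat]) or delta.flat[flat] <= 1e-12:
            return x
        i, k, j, l = np.unravel_index(flat, delta.shape)
        step = int(t[i, k, j, l])
        x[i, j] += step
        x[k, l] += step
        x[i, l] -= step
        x[k, j] -= step


def h2_extreme_tables(row_totals: np.ndarray, col_totals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(min-entropy, max-entropy) integer tables with the given marginals."""
    row = np.asarray(row_totals, dtype=np.int64)
    col = np.asarray(col_totals, dtype=np.int64)
    if row.sum() != col.sum():
        raise ValueError("marginal totals disagree")
    m = row.sum()
    # vertex descent can be trapped behind a worse vertex; on small matrices
    # restart the greedy fill from every possible first placement and keep
    # the most concentrated result before polishing
    starts: list[tuple[int, int] | None] = [None]
    if row.size * col.size <= 24:
        starts += [(i, j) for i in range(len(row)) for j in range(len(col))]
    candidates = [_greedy_concentrated_table(row, col, s) for s in starts]
    lo = min(candidates, key=_entropy)
    lo = _swap_polish(lo, maximize=False)
    expected = np.outer(row, col) / m
    hi = _swap_polish(_repair_rounded_table(expected, row, col), maximize=True)
    return lo, hi


def h2prime(net: QuantNetwork) -> H2Result | NotComputable:
    """Network-level complementary specialization H2'.

    H2 is the Shannon entropy of the interaction matrix (nats); it is
    standardized between the minimum and maximum entropies achievable by
    integer matrices with the observed marginal totals.  Networks with
    fewer than two species on either level, or fewer than two events, are
    reported as :class:`NotComputable`.
    """
    if net.n_plants < 2 or net.n_pollinators < 2:
        return NotComputable("H2' needs at least two species on each trophic level")
    if net.m < 2:
        return NotComputable("H2' needs at least two interaction events")
    h2 = _entropy(net.a)
    lo, hi = h2_extreme_tables(net.row_totals, net.col_totals)
    h2_min, h2_max = _entropy(lo), _entropy(hi)
    if h2_max - h2_min <= 1e-12:
        return H2Result(h2, h2_min, h2_max, 0.0)
    val = (h2_max - h2) / (h2_max - h2_min)
    return H2Result(h2, h2_min, h2_max, min(1.0, max(0.0, val)))


def wnodf(net: QuantNetwork) -> float:
    """Weighted nestedness based on overlap and decreasing fill, in [0, 100].

    Rows and columns are sorted by decreasing marginal totals.  For an
    ordered pair (u richer than v, strictly), the pairwise score is the
    percentage of v's nonzero cells that are strictly smaller than u's cell
    at the same position; equal totals score 0.  WNODF averages all row
    pairs and all column pairs.
    """
    if net.n_plants < 2 or net.n_pollinators < 2:
        raise ValueError("WNODF needs at least a 2x2 matrix")
    a = net.a
    r_order = np.argsort(-net.row_totals, kind="stable")
    c_order = np.argsort(-net.col_totals, kind="stable")
    a = a[np.ix_(r_order, c_order)]

    def pair_scores(mat: np.ndarray) -> list[float]:
        totals = mat.sum(axis=1)
        out = []
        for u in range(len(mat)):
            for v in range(u + 1, len(mat)):
                if totals[u] <= totals[v]:
                    out.append(0.0)
                    continue
                nz = mat[v] > 0
                if nz.sum() == 0:  # unreachable for valid networks
                    out.append(0.0)
                    continue
                hits = int(((mat[v] < mat[u]) & nz).sum())
                out.append(100.0 * hits / int(nz.sum()))
        return out

    scores = pair_scores(a) + pair_scores(a.T)
    return float(np.mean(scores))


def dependence_asymmetry(net: QuantNetwork) -> float:
    """Signed mean asymmetry of mutual dependences over links, in [-1, 1].

    For each link, the pollinator's dependence is a_ij / A_j (its share of
    events on this plant) and the plant's is a_ij / A_i; the link asymmetry
    is their difference normalized by the larger of the two.  Positive
    network values mean the higher trophic level (pollinators) depends more
    strongly on its partners than vice versa.
    """
    if net.m == 0:
        raise ValueError("network is empty")
    A_i = net.row_totals
    A_j = net.col_totals
    vals = []
    for i in range(net.n_plants):
        for j in range(net.n_pollinators):
            a = net.a[i, j]
            if a == 0:
                continue
            d_pol = a / A_j[j]
            d_pla = a / A_i[i]
            denom = max(d_pol, d_pla)
            vals.append((d_pol - d_pla) / denom)
    return float(np.mean(vals))


def network_index_table(networks: Iterable[QuantNetwork]) -> pd.DataFrame:
    """One row of headline indices per network.

    Columns: walk_id, n_plants, n_pollinators, matrix_size, m, H2 family,
    WNODF, dependence asymmetry, and community mean/CV of d' per level.
    Indices that are not computable on a network are left as NaN.
    """
    from .assembly import matrix_size

    rows = []
    for net in networks:
        h2 = h2prime(net)
        row: dict[str, object] = {
            "walk_id": net.walk_id,
            "n_plants": net.n_plants,
            "n_pollinators": net.n_pollinators,
            "matrix_size": matrix_size(net),
            "m": net.m,
            "h2_prime": h2.h2_prime if isinstance(h2, H2Result) else np.nan,
            "h2": h2.h2 if isinstance(h2, H2Result) else np.nan,
            "wnodf": wnodf(net) if net.n_plants >= 2 and net.n_pollinators >= 2 else np.nan,
            "dep_asym": dependence_asymmetry(net),
        }
        for level in ("pollinator", "plant"):
            scores = species_dprime(net, level)  # type: ignore[arg-type]
            summary = community_dprime(scores, net.walk_id)
            unweighted = community_dprime(scores, net.walk_id, weighted=False)
            row[f"mean_dprime_{level}"] = summary.mean_dprime
            row[f"mean_dprime_{level}_unweighted"] = unweighted.mean_dprime
            row[f"cv_dprime_{level}"] = summary.cv_dprime if summary.cv_dprime is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def community_dprime_table(
    networks: Iterable[QuantNetwork], level: Level = "pollinator", weighted: bool = True
) -> pd.DataFrame:
    """Community mean d' per network only (cheap path for large sweeps)."""
    rows = []
    for net in networks:
        summary = community_dprime(species_dprime(net, level), net.walk_id, weighted=weighted)
        rows.append({"walk_id": net.walk_id, f"mean_dprime_{level}": summary.mean_dprime})
    return pd.DataFrame(rows)


def species_score_table(networks: Iterable[QuantNetwork], level: Level = "pollinator") -> pd.DataFrame:
    """Long table of per-network species d' scores (for species means)."""
    rows = []
    for net in networks:
        for s in species_dprime(net, level):
            rows.append(
                {
                    "walk_id": net.walk_id,
                    "species": s.species,
                    "level": s.level,
                    "d": s.d,
                    "d_prime": s.d_prime,
                    "n_events": s.n_events,
                }
            )
    return pd.DataFrame(rows)
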