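"""Specialization and structure indices against hand and enumeration oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pollinet import (
    NotComputable,
    community_dprime,
    dependence_asymmetry,
    h2prime,
    species_dprime,
    species_mean_dprime,
    wnodf,
)
from pollinet.indices import H2Result, _min_kl_allocation, h2_extreme_tables
from conftest import make_net


# --- independent oracles ---------------------------------------------------

def compositions(total, parts):
    """All integer vectors of length `parts` summing to `total`."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            yield (first,) + rest


def kl(counts, q):
    total = sum(counts)
    return sum((c / total) * math.log((c / total) / qk) for c, qk in zip(counts, q) if c > 0)


def exact_min_kl(A, q):
    return min(kl(c, q) for c in compositions(A, len(q)))


def tables_with_marginals(row, col):
    """Enumerate all integer tables with the given marginals (recursive)."""
    nr, nc = len(row), len(col)
    if nr == 1:
        yield (tuple(col),)
        return
    for first in compositions(row[0], nc):
        if all(f <= c for f, c in zip(first, col)):
            rest_col = tuple(c - f for c, f in zip(col, first))
            for rest in tables_with_marginals(row[1:], rest_col):
                yield (first,) + rest


def entropy(table):
    m = sum(map(sum, table))
    return -sum((v / m) * math.log(v / m) for r in table for v in r if v > 0)


# --- d' --------------------------------------------------------------------

class TestSpeciesDprime:
    def test_perfect_specialists(self):
        scores = species_dprime(make_net([[2, 0], [0, 2]]), "pollinator")
        for s in scores:
            assert s.d == pytest.approx(math.log(2))
            assert s.d_min == pytest.approx(0.0)
            assert s.d_prime == pytest.approx(1.0)

    def test_perfect_generalists(self):
        for level in ("plant", "pollinator"):
            for s in species_dprime(make_net([[1, 1], [1, 1]]), level):
                assert s.d_prime == pytest.approx(0.0)

    def test_integer_floor_makes_observed_optimal(self):
        # column (3, 1) of [[3,1],[1,1]]: the most even achievable integer
        # split of 4 events over availabilities (2/3, 1/3) is (3, 1) itself
        scores = species_dprime(make_net([[3, 1], [1, 1]]), "pollinator")
        s = scores[0]
        assert s.d == pytest.approx(0.016417, abs=1e-5)
        assert s.d_min == pytest.approx(s.d)
        assert s.d_max == pytest.approx(math.log(6 / 4))
        assert s.d_prime == pytest.approx(0.0)

    def test_dmin_allocation_matches_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            k = int(rng.integers(2, 5))
            q = rng.dirichlet(np.ones(k) * rng.uniform(0.3, 3))
            A = int(rng.integers(1, 9))
            got = kl(_min_kl_allocation(A, q), q)
            assert got == pytest.approx(exact_min_kl(A, q), abs=1e-10)

    def test_bounds_and_permutation_invariance(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 5, (3, 4))
        a[a.sum(1) == 0, 0] = 1
        a[0, a.sum(0) == 0] = 1
        net = make_net(a)
        perm = make_net(a[np.ix_([2, 0, 1], [3, 1, 0, 2])])
        for s in species_dprime(net, "pollinator"):
            assert 0.0 <= s.d_prime <= 1.0
            assert s.d_min - 1e-9 <= s.d <= s.d_max + 1e-9
        got = {s.species: s.d_prime for s in species_dprime(net, "plant")}
        # plants reordered as rows [2,0,1]: P0->row2 etc.; labels regenerate,
        # so compare sorted d' multisets
        got_p = sorted(s.d_prime for s in species_dprime(perm, "plant"))
        assert np.allclose(sorted(got.values()), got_p)

    def test_scaling_preserves_ranking(self):
        a = np.array([[4, 1, 0], [1, 2, 2], [0, 1, 3]])
        base = [s.d_prime for s in species_dprime(make_net(a), "pollinator")]
        scaled = [s.d_prime for s in species_dprime(make_net(2 * a), "pollinator")]
        assert np.argsort(base).tolist() == np.argsort(scaled).tolist()


class TestCommunitySummaries:
    def test_single_species_has_no_cv(self):
        s = species_dprime(make_net([[3, 1]]), "plant")
        summary = community_dprime(s, "w")
        assert summary.cv_dprime is None
        assert summary.n_species == 1

    def test_equal_values_have_zero_cv(self):
        scores = species_dprime(make_net([[2, 0], [0, 2]]), "pollinator")
        summary = community_dprime(scores, "w")
        assert summary.cv_dprime == pytest.approx(0.0)

    def test_abundance_weighted_mean(self):
        # d' = 1 with weight 3 and d' = 0 with weight 1 -> 0.75
        from pollinet.indices import SpecializationScore

        scores = [
            SpecializationScore("a", "pollinator", 1, 0, 1, 1.0, 3),
            SpecializationScore("b", "pollinator", 0, 0, 1, 0.0, 1),
        ]
        assert community_dprime(scores, "w").mean_dprime == pytest.approx(0.75)
        assert community_dprime(scores, "w", weighted=False).mean_dprime == pytest.approx(0.5)

    def test_species_mean_filters_and_averages(self):
        table = pd.DataFrame(
            {
                "species": ["a"] * 3 + ["b"] * 2,
                "d_prime": [0.2, 0.4, 0.6, 0.9, 0.7],
            }
        )
        means = species_mean_dprime(table, min_obs=3)
        assert means.to_dict() == {"a": pytest.approx(0.4)}

    def test_species_mean_matches_brute_force(self, strong_study):
        from pollinet import build_networks, filter_networks, species_score_table

        nets = filter_networks(build_networks(strong_study.records), 5)
        table = species_score_table(nets, "pollinator")
        means = species_mean_dprime(table, min_obs=3)
        for sp, val in means.items():
            sub = table[table["species"] == sp]["d_prime"]
            assert len(sub) >= 3
            assert val == pytest.approx(sub.mean())


# --- H2' -------------------------------------------------------------------

class TestH2Prime:
    def test_perfect_specialization(self):
        res = h2prime(make_net([[2, 0], [0, 2]]))
        assert isinstance(res, H2Result)
        assert res.h2 == pytest.approx(math.log(2))
        assert res.h2_min == pytest.approx(math.log(2))
        assert res.h2_max == pytest.approx(math.log(4))
        assert res.h2_prime == pytest.approx(1.0)

    def test_independence_table(self):
        res = h2prime(make_net([[1, 1], [1, 1]]))
        assert res.h2_prime == pytest.approx(0.0)

    def test_marginals_can_force_h2prime_zero(self):
        res = h2prime(make_net([[3, 1], [1, 1]]))
        assert res.h2_min == pytest.approx(0.636514, abs=1e-5)
        assert res.h2_max == pytest.approx(res.h2)
        assert res.h2_prime == pytest.approx(0.0)

    def test_degenerate_networks_are_flagged_not_zero(self):
        assert isinstance(h2prime(make_net([[1, 1]])), NotComputable)
        assert isinstance(h2prime(make_net([[1], [1]])), NotComputable)

    def test_extreme_tables_match_enumeration(self):
        rng = np.random.default_rng(6)
        seen = set()
        for _ in range(40):
            a = rng.integers(0, 4, (2, 3))
            if (a.sum(1) == 0).any() or (a.sum(0) == 0).any() or a.sum() > 8:
                continue
            key = (tuple(a.sum(1)), tuple(a.sum(0)))
            if key in seen:
                continue
            seen.add(key)
            lo, hi = h2_extreme_tables(a.sum(1), a.sum(0))
            entropies = [entropy(t) for t in tables_with_marginals(*key)]
            assert entropy(lo.tolist()) == pytest.approx(min(entropies), abs=1e-10)
            assert entropy(hi.tolist()) == pytest.approx(max(entropies), abs=1e-10)

    def test_permutation_invariance(self):
        a = np.array([[4, 1, 0], [1, 2, 2], [0, 1, 3]])
        r1 = h2prime(make_net(a))
        r2 = h2prime(make_net(a[np.ix_([1, 2, 0], [2, 0, 1])]))
        assert r1.h2_prime == pytest.approx(r2.h2_prime)


# --- WNODF -----------------------------------------------------------------

def wnodf_oracle(a):
    """Direct restatement of the pairwise rule, independent of the package."""
    a = np.asarray(a)
    a = a[np.argsort(-a.sum(1), kind="stable")][:, np.argsort(-a.sum(0), kind="stable")]
    scores = []
    for mat in (a, a.T):
        tot = mat.sum(1)
        n = len(mat)
        for u, v in itertools.combinations(range(n), 2):
            if tot[u] <= tot[v]:
                scores.append(0.0)
            else:
                nz = mat[v] > 0
                scores.append(100.0 * ((mat[v] < mat[u]) & nz).sum() / nz.sum())
    return float(np.mean(scores))


class TestWnodf:
    def test_fully_nested_example(self):
        assert wnodf(make_net([[5, 2], [3, 0]])) == pytest.approx(100.0)

    def test_equal_marginals_score_zero(self):
        assert wnodf(make_net([[1, 0], [0, 1]])) == pytest.approx(0.0)

    def test_matches_pairwise_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        done = 0
        while done < 50:
            a = rng.integers(0, 6, (4, 4))
            if (a.sum(1) == 0).any() or (a.sum(0) == 0).any():
                continue
            assert wnodf(make_net(a)) == pytest.approx(wnodf_oracle(a))
            done += 1


# --- dependence asymmetry --------------------------------------------------

class TestDependenceAsymmetry:
    def test_symmetric_matrix_is_balanced(self):
        assert dependence_asymmetry(make_net([[1, 1], [1, 1]])) == pytest.approx(0.0)

    def test_single_plant_two_pollinators(self):
        assert dependence_asymmetry(make_net([[1, 1]])) == pytest.approx(0.5)

    def test_transpose_negates(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.integers(0, 5, (3, 4))
            if (a.sum(1) == 0).any() or (a.sum(0) == 0).any():
                continue
            net = make_net(a)
            assert dependence_asymmetry(net.transpose()) == pytest.approx(
                -dependence_asymmetry(net)
            )
            assert -1.0 <= dependence_asymmetry(net) <= 1.0
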