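import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import metshift as ms
from metshift.io import AbundanceTable


def net(*pairs):
    return ms.UndirectedNetwork.from_edges(list(pairs))


def random_table(n, p, seed):
    rng = np.random.default_rng(seed)
    return AbundanceTable(
        pd.DataFrame(
            rng.standard_normal((n, p)),
            index=[f"s{i}" for i in range(n)],
            columns=[f"v{j:02d}" for j in range(p)],
        )
    )


class TestEsd:
    def test_identical_networks_score_zero(self):
        a = net(("A", "B"), ("B", "C"))
        assert ms.esd(a, a).value == 0.0

    def test_disjoint_networks_score_one(self):
        a = net(("A", "B"), ("B", "C"), ("C", "D"))
        b = net(("E", "F"), ("F", "G"))
        res = ms.esd(a, b)
        assert res.value == 1.0
        assert (res.size_first, res.size_second) == (3, 2)

    def test_study_scale_counts_give_printed_value(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(200)]
        pool = list(itertools.combinations(nodes, 2))
        idx = rng.choice(len(pool), size=93 + 57 - 16, replace=False)
        edges = [pool[i] for i in idx]
        shared, only_hfd, only_nd = edges[:16], edges[16:93], edges[93:]
        hfd = ms.UndirectedNetwork.from_edges(shared + only_hfd)
        nd = ms.UndirectedNetwork.from_edges(shared + only_nd)
        res = ms.esd(hfd, nd)
        assert res.shared == 16
        assert res.value == pytest.approx(118 / 150)
        assert round(res.value, 3) == 0.787  # printed as 0.786 after truncation

    def test_symmetry(self):
        a = net(("A", "B"), ("C", "D"))
        b = net(("A", "B"), ("E", "F"), ("G", "H"))
        assert ms.esd(a, b).value == ms.esd(b, a).value

    def test_two_empty_networks_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ms.esd(ms.UndirectedNetwork(), ms.UndirectedNetwork())

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.sets(
            st.tuples(st.integers(0, 15), st.integers(0, 15)).filter(
                lambda t: t[0] != t[1]
            ),
            min_size=1, max_size=30,
        ),
        st.sets(
            st.tuples(st.integers(0, 15), st.integers(0, 15)).filter(
                lambda t: t[0] != t[1]
            ),
            min_size=1, max_size=30,
        ),
    )
    def test_esd_axioms_on_random_edge_sets(self, pairs_a, pairs_b):
        a = ms.UndirectedNetwork.from_edges([(str(i), str(j)) for i, j in pairs_a])
        b = ms.UndirectedNetwork.from_edges([(str(i), str(j)) for i, j in pairs_b])
        res = ms.esd(a, b)
        assert 0.0 <= res.value <= 1.0
        assert res.value == ms.esd(b, a).value
        assert (res.value == 0.0) == (a.edges == b.edges)
        assert (res.value == 1.0) == (not a.edges & b.edges)
        assert res.shared == res.size_first - res.only_in_first
        assert res.shared == res.size_second - res.only_in_second


class TestCorrelationNetwork:
    def test_threshold_at_or_above_one_gives_empty_network(self):
        table = random_table(20, 5, seed=0)
        assert ms.correlation_network(table, 1.0).n_edges == 0

    def test_duplicated_variable_yields_single_perfect_edge(self):
        rng = np.random.default_rng(1)
        x1 = rng.standard_normal(30)
        df = pd.DataFrame(
            {"x1": x1, "x2": x1, "x3": rng.standard_normal(30)},
            index=[f"s{i}" for i in range(30)],
        )
        netw = ms.correlation_network(AbundanceTable(df), 0.9)
        assert netw.edges == frozenset({("x1", "x2")})
        assert netw.weights[("x1", "x2")] == pytest.approx(1.0)

    def test_matches_all_pairs_oracle(self):
        table = random_table(25, 5, seed=2)
        thr = 0.2
        netw = ms.correlation_network(table, thr)
        vals = table.values
        expected = set()
        for a, b in itertools.combinations(vals.columns, 2):
            r = np.corrcoef(vals[a], vals[b])[0, 1]
            if abs(r) > thr:
                expected.add((a, b))
        assert netw.edges == frozenset(expected)

    def test_edge_count_non_increasing_in_threshold(self):
        table = random_table(30, 8, seed=3)
        counts = [
            ms.correlation_network(table, t).n_edges
            for t in (0.0, 0.1, 0.3, 0.5, 0.8, 0.99)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            ms.correlation_network(random_table(2, 4, seed=4), 0.5)


class TestMatchEdgeCount:
    def test_target_zero_gives_empty_network(self):
        thr, netw = ms.match_edge_count_threshold(random_table(20, 5, seed=5), 0)
        assert netw.n_edges == 0

    def test_matches_exhaustive_sorting_oracle(self):
        table = random_table(22, 4, seed=6)
        vals = table.values
        absr = sorted(
            (
                abs(np.corrcoef(vals[a], vals[b])[0, 1])
                for a, b in itertools.combinations(vals.columns, 2)
            ),
            reverse=True,
        )
        thr, netw = ms.match_edge_count_threshold(table, 2)
        assert thr == pytest.approx(absr[2])
        assert netw.n_edges == 2

    def test_exact_count_in_generic_position(self):
        table = random_table(40, 12, seed=7)
        for target in (1, 5, 20, 50):
            _, netw = ms.match_edge_count_threshold(table, target)
            assert netw.n_edges == target

    def test_tied_correlations_prefer_larger_count(self):
        # duplicated columns create ties at |r| = 1
        rng = np.random.default_rng(8)
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        df = pd.DataFrame(
            {"a": x, "b": x, "c": y, "d": y}, index=[f"s{i}" for i in range(20)]
        )
        # pairs (a,b) and (c,d) both have |r| = 1; target 1 is unachievable
        thr, netw = ms.match_edge_count_threshold(AbundanceTable(df), 1)
        assert netw.n_edges == 2

    def test_target_above_pair_count_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            ms.match_edge_count_threshold(random_table(10, 4, seed=9), 7)


class TestCorrelationPvalue:
    def test_zero_correlation_gives_p_one(self):
        assert ms.correlation_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_printed_cutoff_value(self):
        assert ms.correlation_pvalue(0.9235, 31) == pytest.approx(1.354e-13, rel=1e-3)

    def test_strictly_decreasing_in_abs_r_and_n(self):
        ps = [ms.correlation_pvalue(r, 20) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert ps == sorted(ps, reverse=True)
        ps_n = [ms.correlation_pvalue(0.5, n) for n in (5, 10, 30, 100)]
        assert ps_n == sorted(ps_n, reverse=True)

    def test_matches_permutation_null(self):
        rng = np.random.default_rng(10)
        n, r_obs, B = 30, 0.5, 200_000
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        xz = (x - x.mean()) / x.std()
        yz = (y - y.mean()) / y.std()
        hits = 0
        chunk = 20_000
        for _ in range(B // chunk):
            perms = np.array([rng.permutation(n) for _ in range(chunk)])
            r_perm = (xz[perms] @ yz) / n
            hits += int((np.abs(r_perm) >= r_obs).sum())
        p_perm = hits / B
        p_t = ms.correlation_pvalue(r_obs, n)
        se = np.sqrt(p_t * (1 - p_t) / B)
        assert abs(p_perm - p_t) < 5 * se + 5e-4

    def test_degenerate_perfect_correlation(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert ms.correlation_pvalue(1.0, 10) == 0.0

    def test_tiny_n_rejected(self):
        with pytest.raises(ValueError):
            ms.correlation_pvalue(0.5, 2)


class TestOverlap3:
    def test_identical_networks_fill_central_region(self):
        a = net(("A", "B"), ("B", "C"))
        res = ms.overlap3(a, a, a)
        assert res.region_counts == {frozenset({"HFD", "ND", "complete"}): 2}

    def test_disjoint_networks_fill_exclusive_regions(self):
        res = ms.overlap3(net(("A", "B")), net(("C", "D")), net(("E", "F")))
        assert res.count("HFD") == 1
        assert res.count("ND") == 1
        assert res.count("complete") == 1
        assert sum(res.region_counts.values()) == 3

    def test_region_counts_partition_the_union(self):
        hfd = net(("A", "B"), ("B", "C"), ("C", "D"))
        nd = net(("B", "C"), ("D", "E"))
        comp = net(("A", "B"), ("B", "C"), ("D", "E"), ("F", "G"))
        res = ms.overlap3(hfd, nd, comp)
        union = hfd.edges | nd.edges | comp.edges
        assert sum(res.region_counts.values()) == len(union)
        for name, g in (("HFD", hfd), ("ND", nd), ("complete", comp)):
            total = sum(c for k, c in res.region_counts.items() if name in k)
            assert total == g.n_edges

    def test_per_edge_correlations_and_flagging(self):
        rng = np.random.default_rng(11)
        n = 20
        x = rng.standard_normal(n)
        hfd_df = pd.DataFrame(
            {"A": x, "B": x + 0.1 * rng.standard_normal(n),
             "C": rng.standard_normal(n)}, index=[f"h{i}" for i in range(n)],
        )
        nd_df = pd.DataFrame(
            rng.standard_normal((n, 3)), index=[f"n{i}" for i in range(n)],
            columns=["A", "B", "C"],
        )
        tables = {
            "HFD": AbundanceTable(hfd_df),
            "ND": AbundanceTable(nd_df),
            "complete": AbundanceTable(pd.concat([hfd_df, nd_df])),
        }
        # edge (A,B) belongs to the ND net though HFD carries the higher |r|
        res = ms.overlap3(net(("A", "C")), net(("A", "B")), net(("A", "C")), tables)
        assert ("A", "B") in res.membership_not_highest
        row = res.per_edge_correlations.set_index(["node_a", "node_b"]).loc[("A", "B")]
        assert abs(row["r_HFD"]) > 0.9

    def test_edge_endpoints_missing_from_table_rejected(self):
        tables = {
            "HFD": random_table(10, 2, seed=12),
            "ND": random_table(10, 2, seed=13),
            "complete": random_table(10, 2, seed=14),
        }
        with pytest.raises(ValueError, match="absent"):
            ms.overlap3(net(("Q", "R")), net(("Q", "R")), net(("Q", "R")), tables)
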