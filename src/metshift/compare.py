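"""Network-difference statistics for condition-specific metabolite graphs.

Covers the edge symmetric difference (esd) between two networks, the
Pearson correlation network baseline with edge-count matching, the
significance of a correlation cutoff, and the three-way edge-overlap
decomposition with per-edge correlations across datasets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable
from .network import Edge, UndirectedNetwork, canonical_edge


@dataclass
class EsdResult:
    """Edge symmetric difference between two edge sets.

    value = (|A\\B| + |B\\A|) / (|A| + |B|): the proportion of edges not
    shared — 0 for identical edge sets, 1 for disjoint ones.
    """

    value: float
    only_in_first: int
    only_in_second: int
    size_first: int
    size_second: int
    shared: int


def esd(network_a: UndirectedNetwork, network_b: UndirectedNetwork) -> EsdResult:
    """Edge symmetric difference; symmetric in its arguments.

    Weights are ignored — the statistic is purely edge-set based. Raises
    ValueError when both networks are empty (0/0 undefined).
    """
    A, B = network_a.edges, network_b.edges
    if not A and not B:
        raise ValueError("esd undefined for two empty networks (0/0)")
    only_a = len(A - B)
    only_b = len(B - A)
    return EsdResult(
        value=(only_a + only_b) / (len(A) + len(B)),
        only_in_first=only_a,
        only_in_second=only_b,
        size_first=len(A),
        size_second=len(B),
        shared=len(A & B),
    )


def _correlation_matrix(table: AbundanceTable) -> tuple[np.ndarray, list[str]]:
    if table.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    vals = table.values
    sd = vals.std(axis=0, ddof=1)
    keep = list(sd[sd > 0].index)
    dropped = [c for c in vals.columns if sd[c] == 0]
    if dropped:
        warnings.warn(f"zero-variance metabolites excluded: {dropped}", stacklevel=3)
    r = np.corrcoef(vals[keep].values, rowvar=False)
    return r, keep


def correlation_network(table: AbundanceTable, threshold: float) -> UndirectedNetwork:
    """Edges where |Pearson r| strictly exceeds the threshold; weights are r."""
    r, names = _correlation_matrix(table)
    edges, weights = [], {}
    for i, j in combinations(range(len(names)), 2):
        if abs(r[i, j]) > threshold:
            e = canonical_edge(names[i], names[j])
            edges.append(e)
            weights[e] = float(r[i, j])
    return UndirectedNetwork.from_edges(edges, weights, nodes=names)


def match_edge_count_threshold(
    table: AbundanceTable, target_edge_count: int
) -> tuple[float, UndirectedNetwork]:
    """Threshold whose strict-|r| network has (nearest to) the target edge count.

    All pairwise |r| are sorted descending; the returned threshold is the
    (target+1)-th largest |r|, so exactly ``target`` pairs exceed it when
    values are distinct. Under ties at the boundary the nearest achievable
    count is returned, preferring the larger.
    """
    r, names = _correlation_matrix(table)
    pairs = list(combinations(range(len(names)), 2))
    if target_edge_count > len(pairs):
        raise ValueError(
            f"target {target_edge_count} exceeds {len(pairs)} metabolite pairs"
        )
    absr = np.sort(np.abs([r[i, j] for i, j in pairs]))[::-1]
    if target_edge_count == 0:
        thr = float(absr[0])
        return thr, correlation_network(table, thr)
    if target_edge_count == len(absr):
        thr = float(absr[-1]) - 1e-12
        return thr, correlation_network(table, thr)
    v = float(absr[target_edge_count])
    count_strict = int((absr > v).sum())
    if count_strict == target_edge_count:
        return v, correlation_network(table, v)
    # Ties straddle the boundary: achievable counts bracket the target.
    # Lowering the cutoff to the next distinct |r| admits the whole tie
    # group; pick the achievable count nearest the target, preferring the
    # larger when equidistant.
    below = absr[absr < v]
    thr_low = float(below[0]) if len(below) else v - 1.0
    count_ge = int((absr > thr_low).sum())
    if abs(count_ge - target_edge_count) <= abs(count_strict - target_edge_count):
        return thr_low, correlation_network(table, thr_low)
    return v, correlation_network(table, v)


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value of a Pearson correlation under the t reference.

    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom. |r| = 1 is a
    degenerate perfect correlation and returns 0.0 with a warning.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) > 1:
        raise ValueError("|r| cannot exceed 1")
    if abs(r) == 1:
        warnings.warn("degenerate |r| = 1; p reported as 0", stacklevel=2)
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(t, n - 2))


@dataclass
class OverlapResult:
    """Three-way edge overlap with per-edge correlations per dataset.

    ``region_counts`` keys are frozensets of dataset names; e.g. the edges
    found only in the HFD graph sit under frozenset({"HFD"}), those in all
    three under frozenset({"HFD", "ND", "complete"}).
    """

    region_counts: dict[frozenset[str], int]
    per_edge_correlations: pd.DataFrame
    membership_not_highest: list[Edge] = field(default_factory=list)

    def count(self, *datasets: str) -> int:
        return self.region_counts.get(frozenset(datasets), 0)


def _pairwise_r(table: AbundanceTable, a: str, b: str) -> float:
    x = table.values[a]
    y = table.values[b]
    ok = x.notna() & y.notna()
    if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
        return float("nan")
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def overlap3(
    net_hfd: UndirectedNetwork,
    net_nd: UndirectedNetwork,
    net_complete: UndirectedNetwork,
    tables: dict[str, AbundanceTable] | None = None,
) -> OverlapResult:
    """Decompose three edge sets into their 7 exclusive regions.

    When per-dataset tables are supplied (keys "HFD", "ND", "complete"),
    every union edge gets its Pearson r within each dataset, and edges whose
    member dataset does not carry the highest |r| are flagged.
    """
    nets = {"HFD": net_hfd, "ND": net_nd, "complete": net_complete}
    vocab = {name: n.nodes for name, n in nets.items()}
    if tables:
        for name, tab in tables.items():
            missing = sorted(vocab.get(name, frozenset()) - set(tab.metabolite_ids))
            # Isolated nodes need not appear; only edge endpoints must.
            endpoints = {u for e in nets[name].edges for u in e}
            missing = sorted(endpoints - set(tab.metabolite_ids))
            if missing:
                raise ValueError(
                    f"{name}: edge endpoints absent from its table: {missing[:10]}"
                )
    union = set().union(*(n.edges for n in nets.values()))
    region_counts: dict[frozenset[str], int] = {}
    membership: dict[Edge, frozenset[str]] = {}
    for e in union:
        members = frozenset(name for name, n in nets.items() if e in n.edges)
        membership[e] = members
        region_counts[members] = region_counts.get(members, 0) + 1

    rows = []
    flagged: list[Edge] = []
    if tables:
        for e in sorted(union):
            rs = {name: _pairwise_r(tables[name], *e) for name in nets}
            rows.append({"node_a": e[0], "node_b": e[1], **{f"r_{k}": v for k, v in rs.items()},
                         "membership": "+".join(sorted(membership[e]))})
            member_abs = [abs(rs[m]) for m in membership[e] if not np.isnan(rs[m])]
            all_abs = [abs(v) for v in rs.values() if not np.isnan(v)]
            if member_abs and all_abs and max(member_abs) < max(all_abs) - 1e-12:
                flagged.append(e)
    per_edge = pd.DataFrame(rows)
    return OverlapResult(
        region_counts=region_counts,
        per_edge_correlations=per_edge,
        membership_not_highest=flagged,
    )
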