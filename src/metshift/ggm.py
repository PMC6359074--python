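"""Gaussian graphical model selection by two-step nodewise Lasso.

Suited to the n << p regime of metabolomics tables, the estimator follows a
two-step scheme: (1) build a data-driven family of candidate graphs from the
Lasso regularization path of each variable regressed on all others — the
first ``dmax`` variables to enter a node's path are its candidate neighbors,
in entry order; (2) score every family member with a penalized
residual-sum-of-squares criterion and keep the minimizer.

The criterion is

    Crit(G) = sum_a RSS_a(G) * (1 + pen(d_a) / (n - d_a)),

where RSS_a(G) is the residual sum of squares of the least-squares
regression of variable a on its neighbors in G and d_a its degree. The
default penalty,

    pen(d) = K * d * (1 + sqrt(2 * log(p - 1)))^2,

carries the complexity scale of model selection over ~p candidate
neighbors per node: under the null, the best-entering candidate behaves
like the maximum of ~p-1 chi-square(1) variables (~2 log(p-1)), which this
penalty dominates, so selection stays sparse even at K = 2. The simpler
``penalty="log"`` variant pen(d) = K * d * log(p - 1) is available but
admits spurious edges in that regime. The scalar K (conventionally between
2 and 5) sets the penalty strength — larger K, sparser graph — while dmax
caps the node degree. The criterion reproduces the qualitative behavior
expected of the two-parameter (K, dmax) scheme: sparse selection even at
K = 2, monotone sparsification in K, and an edge-count plateau once dmax
exceeds the true maximum degree.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path

from .io import AbundanceTable
from .network import UndirectedNetwork

ENTRY_TOL = 1e-10


@dataclass
class GgmConfig:
    """Selection parameters: penalty scalar K, degree cap dmax."""

    K: float = 2.0
    dmax: int = 5
    lasso_path_length: int = 100
    standardize: bool = True
    symmetrization: str = "and"  # "and" (conservative) or "or"
    penalty: str = "sqrt_log"  # "sqrt_log" (default) or "log"

    def __post_init__(self) -> None:
        if not 2.0 <= self.K <= 5.0:
            warnings.warn(
                f"K={self.K} outside the conventional [2, 5] range", stacklevel=3
            )
        if self.dmax < 1:
            raise ValueError("dmax must be >= 1")
        if self.symmetrization not in ("and", "or"):
            raise ValueError("symmetrization must be 'and' or 'or'")
        if self.penalty not in ("sqrt_log", "log"):
            raise ValueError("penalty must be 'sqrt_log' or 'log'")


@dataclass
class GgmFit:
    """Selected graph with its neighborhoods and criterion bookkeeping."""

    graph: UndirectedNetwork
    neighborhoods: dict[str, frozenset[str]]
    criterion_value: float
    family_size: int
    config: GgmConfig


def _standardized_matrix(
    table: AbundanceTable, scale: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Zero-mean (and unit-variance) columns; zero-variance columns dropped."""
    vals = table.values
    if vals.isna().any().any():
        raise ValueError("table contains missing values; impute first")
    sd = vals.std(axis=0, ddof=0)
    keep = sd[sd > 0].index
    dropped = [c for c in vals.columns if c not in set(keep)]
    if dropped:
        warnings.warn(f"zero-variance metabolites excluded: {dropped}", stacklevel=3)
    X = vals[keep].values.astype(float)
    X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=0)
    return X, list(keep)


def nodewise_entry_orders(
    X: np.ndarray, dmax: int, path_length: int = 100
) -> list[list[int]]:
    """Per node, the first-``dmax`` variables to enter its Lasso path, in order.

    For node a, the Lasso path of column a on all remaining columns is
    traced over ``path_length`` log-spaced penalties from the per-node null
    knot; a predictor's entry position is the first knot at which its
    coefficient is nonzero. Ties at a knot are broken by absolute
    correlation with the response.
    """
    n, p = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for nodewise regression")
    if dmax >= n - 2:
        warnings.warn(
            f"dmax={dmax} >= n-2; neighborhoods capped at {n - 3}", stacklevel=3
        )
        dmax = n - 3
    orders: list[list[int]] = []
    others_template = np.arange(p)
    for a in range(p):
        others = others_template[others_template != a]
        Xo, ya = X[:, others], X[:, a]
        _, coefs, _ = lasso_path(Xo, ya, alphas=path_length, eps=1e-3)
        nz = np.abs(coefs) > ENTRY_TOL
        first = np.where(nz.any(axis=1), nz.argmax(axis=1), np.inf)
        corr = np.abs(Xo.T @ ya) / n
        entering = np.where(np.isfinite(first))[0]
        entering = sorted(entering, key=lambda j: (first[j], -corr[j]))
        orders.append([int(others[j]) for j in entering[:dmax]])
    return orders


def assemble_family(
    orders: list[list[int]], dmax: int, symmetrization: str = "and"
) -> list[frozenset[tuple[int, int]]]:
    """Graphs indexed by a shared path position h = 0..dmax.

    Graph h joins a and b when each lies within the other's first h path
    entries (AND rule) or within at least one (OR rule). Per-node prefixes
    are nested in h, so the family is an increasing chain of edge sets,
    deduplicated; the empty graph (h = 0) is always a member.
    """
    p = len(orders)
    family: list[frozenset[tuple[int, int]]] = []
    seen = set()
    for h in range(dmax + 1):
        prefix = [set(o[:h]) for o in orders]
        edges = set()
        for a in range(p):
            for b in prefix[a]:
                mutual = a in prefix[b]
                if symmetrization == "and" and not mutual:
                    continue
                edges.add((min(a, b), max(a, b)))
        fs = frozenset(edges)
        if fs not in seen:
            seen.add(fs)
            family.append(fs)
    return family


def _rss(X: np.ndarray, a: int, neighbors: tuple[int, ...]) -> float:
    y = X[:, a]
    if not neighbors:
        return float(y @ y)
    Z = X[:, list(neighbors)]
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    return float(resid @ resid)


def _pen(d: int, p: int, K: float, penalty: str) -> float:
    if d == 0 or p <= 1:
        return 0.0
    L = math.log(p - 1)
    if penalty == "log":
        return K * d * L
    return K * d * (1.0 + math.sqrt(2.0 * L)) ** 2


def criterion_from_matrix(
    X: np.ndarray,
    edges: frozenset[tuple[int, int]],
    K: float,
    rss_cache: dict[tuple[int, tuple[int, ...]], float] | None = None,
    penalty: str = "sqrt_log",
) -> float:
    """Penalized RSS criterion on an index-labeled graph (columns of X)."""
    n, p = X.shape
    nbrs: dict[int, list[int]] = {a: [] for a in range(p)}
    for i, j in edges:
        nbrs[i].append(j)
        nbrs[j].append(i)
    total = 0.0
    for a in range(p):
        d = len(nbrs[a])
        if n - d <= 0:
            raise ValueError(f"degree {d} of node {a} leaves no residual df (n={n})")
        key = (a, tuple(sorted(nbrs[a])))
        if rss_cache is not None and key in rss_cache:
            rss = rss_cache[key]
        else:
            rss = _rss(X, a, key[1])
            if rss_cache is not None:
                rss_cache[key] = rss
        total += rss * (1.0 + _pen(d, p, K, penalty) / (n - d))
    return total


def selection_criterion(
    table: AbundanceTable,
    graph: UndirectedNetwork,
    K: float,
    penalty: str = "sqrt_log",
) -> float:
    """Public criterion on a named graph over the table's metabolites."""
    X, names = _standardized_matrix(table)
    idx = {nm: i for i, nm in enumerate(names)}
    missing = sorted({u for e in graph.edges for u in e} - set(names))
    if missing:
        raise ValueError(f"graph nodes absent from table: {missing}")
    edges = frozenset((min(idx[u], idx[v]), max(idx[u], idx[v])) for u, v in graph.edges)
    return criterion_from_matrix(X, edges, K, penalty=penalty)


def nodewise_lasso_family(
    table: AbundanceTable, config: GgmConfig
) -> list[UndirectedNetwork]:
    """The deduplicated candidate-graph family, smallest (empty) first."""
    X, names = _standardized_matrix(table, config.standardize)
    orders = nodewise_entry_orders(X, config.dmax, config.lasso_path_length)
    family = assemble_family(orders, config.dmax, config.symmetrization)
    return [
        UndirectedNetwork.from_edges(
            [(names[i], names[j]) for i, j in fs], nodes=names
        )
        for fs in family
    ]


def select_graph(table: AbundanceTable, config: GgmConfig) -> GgmFit:
    """Fit the two-step estimator: build the family, keep the criterion minimizer.

    Ties break toward fewer edges, then the lexicographically smallest edge
    set, so selection is fully deterministic.
    """
    X, names = _standardized_matrix(table, config.standardize)
    orders = nodewise_entry_orders(X, config.dmax, config.lasso_path_length)
    family = assemble_family(orders, config.dmax, config.symmetrization)
    cache: dict[tuple[int, tuple[int, ...]], float] = {}
    scored = [
        (
            criterion_from_matrix(X, fs, config.K, cache, penalty=config.penalty),
            len(fs),
            sorted(fs),
            fs,
        )
        for fs in family
    ]
    scored.sort(key=lambda t: (t[0], t[1], t[2]))
    crit, _, _, best = scored[0]
    graph = UndirectedNetwork.from_edges(
        [(names[i], names[j]) for i, j in best], nodes=names
    )
    nbrs: dict[str, set[str]] = {nm: set() for nm in names}
    for u, v in graph.edges:
        nbrs[u].add(v)
        nbrs[v].add(u)
    return GgmFit(
        graph=graph,
        neighborhoods={k: frozenset(v) for k, v in nbrs.items()},
        criterion_value=float(crit),
        family_size=len(family),
        config=config,
    )


@dataclass
class SweepResult:
    """Edge counts over a (K, dmax) grid, with per-K constant-count plateaus."""

    edge_counts: pd.DataFrame  # index K, columns dmax
    plateaus: dict[float, tuple[int, int]] = field(default_factory=dict)


def sweep_k_dmax(
    table: AbundanceTable,
    K_values: list[float] = (2.0, 3.0, 4.0, 5.0),
    dmax_values: list[int] = tuple(range(1, 11)),
    lasso_path_length: int = 100,
    penalty: str = "sqrt_log",
) -> SweepResult:
    """Edge count of the selected graph at every (K, dmax) combination.

    The Lasso entry orders are computed once at the largest dmax and reused;
    per-K plateaus report the longest (latest) contiguous dmax range with a
    constant edge count, the diagnostic used to fix dmax.
    """
    K_values = list(K_values)
    dmax_values = sorted(dmax_values)
    X, names = _standardized_matrix(table)
    orders_full = nodewise_entry_orders(X, max(dmax_values), lasso_path_length)
    cache: dict[tuple[int, tuple[int, ...]], float] = {}
    counts = pd.DataFrame(index=K_values, columns=dmax_values, dtype=int)
    for dmax in dmax_values:
        orders = [o[:dmax] for o in orders_full]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            family = assemble_family(orders, dmax)
        for K in K_values:
            scored = [
                (criterion_from_matrix(X, fs, K, cache, penalty=penalty), len(fs), sorted(fs))
                for fs in family
            ]
            scored.sort(key=lambda t: (t[0], t[1], t[2]))
            counts.loc[K, dmax] = scored[0][1]
    plateaus: dict[float, tuple[int, int]] = {}
    for K in K_values:
        row = counts.loc[K]
        best: tuple[int, int] | None = None
        start = 0
        for i in range(1, len(dmax_values) + 1):
            if i == len(dmax_values) or row.iloc[i] != row.iloc[start]:
                if best is None or (i - 1 - start) >= (best[1] - best[0]):
                    best = (dmax_values[start], dmax_values[i - 1])
                start = i
        plateaus[float(K)] = best  # type: ignore[assignment]
    return SweepResult(edge_counts=counts, plateaus=plateaus)
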