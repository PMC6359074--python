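"""Synthetic metabolite tables with known condition-specific dependence graphs.

The generator emulates the statistical structure of a two-diet Drosophila
larval metabolomics study: ~350 metabolites over ~31 samples (15 high-fat
diet, 16 normal diet) drawn from 16 genotypes in three triglyceride
reaction-norm classes; sparse diet-specific Gaussian dependence graphs of
~57 (ND) and ~93 (HFD) edges with low overlap (edge symmetric difference
~0.79); a block of diet-shifted differentiator metabolites standing in for
the medium-chain fatty acids; a correlated, phenotype-linked block standing
in for the dipeptides; and below-detection-limit left-censoring.

Latent abundances are multivariate normal with covariance equal to the
inverse of a sparse precision matrix whose support is the condition graph;
tables are exponentiated to a positive abundance scale so that the
pipeline's min-imputation + log transform returns them to Gaussianity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import AbundanceTable, SampleAnnotation
from .network import UndirectedNetwork

# Genotype assignment order; the last genotype (whose HFD sample is dropped
# when n_hfd = n_genotypes - 1) belongs to the N_gt_HF class, so the default
# design yields 12 N_lt_HF, 10 zero and 9 N_gt_HF samples.
REACTION_NORM_CLASSES = ("N_lt_HF", "zero", "N_gt_HF")


@dataclass
class SyntheticSpec:
    """Generative parameters; defaults mirror the emulated study design.

    Effect sizes are in within-condition latent SD units. The diet
    differentiator shift (2.5 SD) makes the block clearly separable by a
    classifier, as medium-chain fatty acids are between diets; the phenotype
    block shift (2.0 SD on one extreme class, diluted by the within-block
    shared factor) is deliberately weaker, giving the noisier moderate-error
    contrast seen between reaction-norm classes.
    """

    p: int = 350
    n_nd: int = 16
    n_hfd: int = 15
    edges_nd: int = 57
    edges_hfd: int = 93
    target_esd: float = 0.786
    max_degree: int = 5
    partial_corr_magnitude: float = 0.35
    differentiator_size: int = 10
    differentiator_shift: float = 2.5
    phenotype_block_size: int = 7
    phenotype_block_corr: float = 0.6
    phenotype_block_shift: float = 2.0
    n_genotypes: int = 16
    genotypes_per_class: tuple[int, int, int] = (6, 5, 5)  # N_lt_HF, N_gt_HF, zero
    detection_floor_quantile: float = 0.1
    baseline_log_abundance: float = 10.0
    seed: int = 0

    def metabolite_names(self) -> list[str]:
        """Stable names; differentiators get medium-chain fatty-acid analog names."""
        mcfa = ["caproate_analog", "caprylate_analog", "caprate_analog", "laurate_analog"]
        names = []
        for i in range(self.p):
            if i < self.differentiator_size:
                if i < len(mcfa):
                    names.append(mcfa[i])
                else:
                    names.append(f"diet_marker_{i:03d}")
            elif i < self.differentiator_size + self.phenotype_block_size:
                j = i - self.differentiator_size
                names.append(f"dipeptide_analog_{j:02d}")
            else:
                names.append(f"met_{i:03d}")
        return names

    @property
    def differentiator_ids(self) -> list[str]:
        return self.metabolite_names()[: self.differentiator_size]

    @property
    def phenotype_block_ids(self) -> list[str]:
        n = self.metabolite_names()
        return n[self.differentiator_size : self.differentiator_size + self.phenotype_block_size]


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated table, for recovery testing."""

    graph_nd: UndirectedNetwork
    graph_hfd: UndirectedNetwork
    precision_nd: np.ndarray
    precision_hfd: np.ndarray
    differentiator_ids: list[str]
    phenotype_block_ids: list[str]
    realized_esd: float
    partial_corr_range: tuple[float, float] = (0.0, 0.0)


def feasible_shared_edges(e1: int, e2: int, target_esd: float) -> int:
    """Integer shared-edge count s making (e1+e2-2s)/(e1+e2) nearest target_esd.

    Ties round toward more sharing (larger s). Feasible range 0..min(e1,e2).
    """
    if e1 <= 0 or e2 <= 0:
        raise ValueError("both edge counts must be positive")
    if not 0.0 <= target_esd <= 1.0:
        raise ValueError("target_esd must lie in [0, 1]")
    total = e1 + e2
    s_real = total * (1.0 - target_esd) / 2.0
    s = int(np.floor(s_real + 0.5))  # .5 rounds up: prefer more shared edges
    s = max(0, min(s, min(e1, e2)))
    lo = 2.0 * min(e1, e2) / total
    if target_esd < 1.0 - lo - 1e-12:
        raise ValueError(
            f"target_esd={target_esd} infeasible: with |E1|={e1}, |E2|={e2} the "
            f"smallest achievable esd is {1.0 - lo:.4f} (full sharing)"
        )
    return s


def esd_of_counts(e1: int, e2: int, shared: int) -> float:
    return (e1 + e2 - 2 * shared) / (e1 + e2)


def _random_edges(
    rng: np.random.Generator,
    p: int,
    count: int,
    degree: np.ndarray,
    max_degree: int,
    forbidden: set[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Draw `count` new edges on nodes 0..p-1 under a shared degree cap."""
    edges: list[tuple[int, int]] = []
    attempts = 0
    limit = 200 * count + 10_000
    while len(edges) < count:
        attempts += 1
        if attempts > limit:
            raise ValueError(
                f"could not place {count} edges under max_degree={max_degree} "
                f"on p={p} nodes; graph spec too dense"
            )
        i, j = rng.integers(0, p, size=2)
        if i == j:
            continue
        e = (min(i, j), max(i, j))
        if e in forbidden or degree[i] >= max_degree or degree[j] >= max_degree:
            continue
        forbidden.add(e)
        degree[i] += 1
        degree[j] += 1
        edges.append(e)
    return edges


def make_condition_graphs(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> tuple[UndirectedNetwork, UndirectedNetwork]:
    """Build the ND and HFD dependence graphs with controlled edge overlap.

    The shared-edge count is the feasible integer nearest ``target_esd``, so
    the realized edge symmetric difference is exact by construction.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    s = feasible_shared_edges(spec.edges_nd, spec.edges_hfd, spec.target_esd)
    names = spec.metabolite_names()
    degree = np.zeros(spec.p, dtype=int)
    used: set[tuple[int, int]] = set()
    shared = _random_edges(rng, spec.p, s, degree, spec.max_degree, used)
    # Per-condition degree continues from the shared edges' degrees.
    deg_nd = degree.copy()
    deg_hfd = degree.copy()
    used_nd = set(used)
    used_hfd = set(used)
    only_nd = _random_edges(rng, spec.p, spec.edges_nd - s, deg_nd, spec.max_degree, used_nd)
    # HFD-specific edges must also avoid ND-specific ones (else they'd be shared).
    used_hfd |= used_nd
    only_hfd = _random_edges(rng, spec.p, spec.edges_hfd - s, deg_hfd, spec.max_degree, used_hfd)

    def net(pairs: Sequence[tuple[int, int]]) -> UndirectedNetwork:
        return UndirectedNetwork.from_edges(
            [(names[i], names[j]) for i, j in pairs], nodes=names
        )

    return net(shared + only_nd), net(shared + only_hfd)


def graph_to_precision(
    graph: UndirectedNetwork,
    node_order: Sequence[str],
    partial_corr_magnitude: float = 0.35,
    seed: int = 0,
) -> np.ndarray:
    """Sparse symmetric positive-definite precision matrix supported on `graph`.

    Off-diagonal entries get random signs and magnitudes near
    ``partial_corr_magnitude``, then each entry (a,b) is divided by
    1.2 * max(weighted degree a, weighted degree b), which enforces strict
    diagonal dominance (diagonal fixed at 1), hence positive definiteness,
    while preserving the support exactly.
    """
    p = len(node_order)
    if p == 0:
        raise ValueError("empty node set")
    idx = {n: i for i, n in enumerate(node_order)}
    rng = np.random.default_rng(seed)
    omega = np.eye(p)
    mags: dict[tuple[int, int], float] = {}
    for u, v in sorted(graph.edges):
        i, j = idx[u], idx[v]
        sign = rng.choice([-1.0, 1.0])
        mag = partial_corr_magnitude * rng.uniform(0.8, 1.2)
        mags[(i, j)] = sign * mag
    wdeg = np.zeros(p)
    for (i, j), v in mags.items():
        wdeg[i] += abs(v)
        wdeg[j] += abs(v)
    for (i, j), v in mags.items():
        scaled = v / (1.2 * max(wdeg[i], wdeg[j]))
        # Entry-wise cap keeps low-degree pairs near the requested partial
        # correlation; shrinking magnitudes preserves diagonal dominance.
        if abs(scaled) > partial_corr_magnitude:
            scaled = np.sign(scaled) * partial_corr_magnitude
        omega[i, j] = omega[j, i] = scaled
    # Strict diagonal dominance guarantees the smallest eigenvalue is positive.
    return omega


def implied_partial_correlations(omega: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    return rho


def build_truth(spec: SyntheticSpec) -> SyntheticTruth:
    rng = np.random.default_rng(spec.seed)
    g_nd, g_hfd = make_condition_graphs(spec, rng)
    names = spec.metabolite_names()
    om_nd = graph_to_precision(g_nd, names, spec.partial_corr_magnitude, spec.seed + 1)
    om_hfd = graph_to_precision(g_hfd, names, spec.partial_corr_magnitude, spec.seed + 2)
    realized = esd_of_counts(
        g_nd.n_edges, g_hfd.n_edges, len(g_nd.edges & g_hfd.edges)
    )
    pcs = []
    for om, g in ((om_nd, g_nd), (om_hfd, g_hfd)):
        rho = implied_partial_correlations(om)
        idx = {n: i for i, n in enumerate(names)}
        pcs.extend(abs(rho[idx[u], idx[v]]) for u, v in g.edges)
    pc_range = (float(min(pcs)), float(max(pcs))) if pcs else (0.0, 0.0)
    return SyntheticTruth(
        graph_nd=g_nd,
        graph_hfd=g_hfd,
        precision_nd=om_nd,
        precision_hfd=om_hfd,
        differentiator_ids=spec.differentiator_ids,
        phenotype_block_ids=spec.phenotype_block_ids,
        realized_esd=realized,
        partial_corr_range=pc_range,
    )


STUDY_OVERLAP_REGIONS: dict[frozenset[str], int] = {
    frozenset({"HFD"}): 45,
    frozenset({"ND"}): 16,
    frozenset({"complete"}): 57,
    frozenset({"HFD", "ND"}): 1,
    frozenset({"HFD", "complete"}): 32,
    frozenset({"ND", "complete"}): 25,
    frozenset({"HFD", "ND", "complete"}): 15,
}
"""Synthetic stand-in overlap structure for the emulated study's three
condition networks (HFD, ND, complete): the unique 7-region decomposition
consistent with edge totals 93/57/129, pairwise HFD-ND sharing 16, and
per-set exclusive counts 45/16/57."""


def make_overlapping_edge_sets(
    region_counts: dict[frozenset[str], int] | None = None,
    p: int = 350,
    seed: int = 0,
) -> dict[str, UndirectedNetwork]:
    """Named edge sets realizing exact overlap-region counts (synthetic stand-in).

    Distinct unordered node pairs are drawn at random and assigned to the
    requested exclusive regions, so each named network's edge total and every
    pairwise/threewise overlap equal the requested counts exactly. Defaults
    to the emulated study's three-network structure.
    """
    regions = dict(STUDY_OVERLAP_REGIONS if region_counts is None else region_counts)
    set_names = sorted({name for key in regions for name in key})
    total = sum(regions.values())
    rng = np.random.default_rng(seed)
    names = [f"met_{i:03d}" for i in range(p)]
    pairs: set[tuple[int, int]] = set()
    while len(pairs) < total:
        i, j = rng.integers(0, p, size=2)
        if i != j:
            pairs.add((min(i, j), max(i, j)))
    pool = sorted(pairs)
    rng.shuffle(pool)
    edges_by_set: dict[str, list[tuple[str, str]]] = {s: [] for s in set_names}
    k = 0
    for key in sorted(regions, key=lambda fs: sorted(fs)):
        for _ in range(regions[key]):
            i, j = pool[k]
            k += 1
            for s in key:
                edges_by_set[s].append((names[i], names[j]))
    return {
        s: UndirectedNetwork.from_edges(edges_by_set[s], nodes=names)
        for s in set_names
    }


def _assign_genotypes(spec: SyntheticSpec) -> list[tuple[str, str]]:
    """(genotype, reaction_norm) per genotype, class sizes per the spec."""
    n_lt, n_gt, n_zero = spec.genotypes_per_class
    if n_lt + n_gt + n_zero != spec.n_genotypes:
        raise ValueError("genotypes_per_class must sum to n_genotypes")
    out = []
    k = 0
    for cls, cnt in zip(REACTION_NORM_CLASSES, (n_lt, n_zero, n_gt)):
        for _ in range(cnt):
            out.append((f"G{k:02d}", cls))
            k += 1
    return out


def sample_table(
    spec: SyntheticSpec, truth: SyntheticTruth | None = None
) -> tuple[AbundanceTable, list[SampleAnnotation], SyntheticTruth]:
    """Draw one synthetic study: abundance table, metadata and ground truth.

    Per condition, latent log abundances are multivariate normal with
    covariance equal to the inverse condition precision; the differentiator
    block is mean-shifted under HFD, the phenotype block gains a shared
    within-block factor plus a reaction-norm-class shift (up for N_lt_HF,
    down for N_gt_HF); values are exponentiated to abundance scale and each
    metabolite's lowest ``detection_floor_quantile`` fraction is censored to
    missing. Fully deterministic given ``spec.seed``.
    """
    if spec.n_nd < 2 or spec.n_hfd < 2:
        raise ValueError("need at least 2 samples per condition")
    truth = build_truth(spec) if truth is None else truth
    rng = np.random.default_rng(spec.seed + 1000)
    names = spec.metabolite_names()
    p = spec.p

    genos = _assign_genotypes(spec)
    # One sample per genotype per diet; drop trailing samples to hit the
    # requested per-condition counts (emulating the removed aberrant sample).
    design: list[tuple[str, str, str]] = []  # (sample_id, diet, genotype)
    meta_class = {g: c for g, c in genos}
    for diet, n_target in (("ND", spec.n_nd), ("HFD", spec.n_hfd)):
        chosen = [g for g, _ in genos][: spec.n_genotypes]
        if n_target > len(chosen):
            raise ValueError("n per condition exceeds genotype count")
        for g in chosen[:n_target]:
            design.append((f"{diet}_{g}", diet, g))

    diff_idx = np.arange(spec.differentiator_size)
    pheno_idx = np.arange(
        spec.differentiator_size, spec.differentiator_size + spec.phenotype_block_size
    )
    # Dipeptide-analog block elevated in the class storing less triglyceride
    # on the high-fat diet; other classes sit at baseline.
    class_sign = {"N_gt_HF": +1.0, "N_lt_HF": 0.0, "zero": 0.0}

    chol = {
        "ND": np.linalg.cholesky(np.linalg.inv(truth.precision_nd)),
        "HFD": np.linalg.cholesky(np.linalg.inv(truth.precision_hfd)),
    }
    sd = {
        d: np.sqrt(np.diag(np.linalg.inv(om)))
        for d, om in (("ND", truth.precision_nd), ("HFD", truth.precision_hfd))
    }
    # Within-block correlation rho via a shared factor: x += sqrt(rho/(1-rho))*f*sd,
    # then the block's marginal correlation between members is ~rho.
    rho = spec.phenotype_block_corr
    factor_load = np.sqrt(rho / (1.0 - rho)) if 0 < rho < 1 else 0.0

    rows = np.empty((len(design), p))
    meta: list[SampleAnnotation] = []
    trig_base = 100.0
    for r, (sid, diet, geno) in enumerate(design):
        z = rng.standard_normal(p)
        x = chol[diet] @ z
        if diet == "HFD":
            x[diff_idx] += spec.differentiator_shift * sd[diet][diff_idx]
        cls = meta_class[geno]
        shared_factor = rng.standard_normal()
        x[pheno_idx] += factor_load * shared_factor * sd[diet][pheno_idx]
        x[pheno_idx] *= 1.0 / np.sqrt(1.0 + factor_load**2)
        x[pheno_idx] += class_sign[cls] * spec.phenotype_block_shift * sd[diet][pheno_idx]
        rows[r] = x + spec.baseline_log_abundance
        # Triglyceride phenotype consistent with the class definition (25% rule).
        if cls == "N_lt_HF":
            trig = trig_base * (1.4 if diet == "HFD" else 1.0)
        elif cls == "N_gt_HF":
            trig = trig_base * (1.4 if diet == "ND" else 1.0)
        else:
            trig = trig_base * 1.05
        trig *= float(np.exp(0.05 * rng.standard_normal()))
        meta.append(
            SampleAnnotation(
                sample_id=sid, diet=diet, genotype=geno,
                reaction_norm=cls, triglyceride=trig,
            )
        )

    abundance = np.exp(rows)
    df = pd.DataFrame(abundance, index=[d[0] for d in design], columns=names)
    q = spec.detection_floor_quantile
    if q > 0:
        n_censor = int(np.floor(q * len(design)))
        for col in range(p):
            if n_censor == 0:
                break
            order = np.argsort(df.iloc[:, col].values)
            df.iloc[order[:n_censor], col] = np.nan
    return AbundanceTable(df), meta, truth
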