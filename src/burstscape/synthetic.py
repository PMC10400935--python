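"""Lineage-structured synthetic single-cell data with full ground truth.

The generator plants a rooted tree of cell clusters and models
differentiation as burst-frequency modulation: each gene has an intrinsic
transcription rate and burst size, while its promoter activation rate
(burst frequency) performs a per-gene drift walk in log space along the
tree edges.  Neighbouring clusters therefore resemble each other, separation
grows with lineage depth, and sibling branches — which receive
opposite-signed drift components on top of the inherited trunk drift — stay
distinguishable.

Designated transition clusters engage a burst module: a randomly chosen
subset of genes whose bursting is inflated with a ramp that builds up over
two lineage hops, peaks at the transition cluster (burst size x f, burst
frequency x sqrt(f)) and disengages in the fates beyond, emulating the burst
surge and uncertainty peak observed in transition states.

Counts are drawn from the exact stationary sampler.  A velocity proxy gives
each cell, per gene, the absolute difference between the mean expression of
clusters ``velocity_lag`` depth units ahead and its own cluster's mean, plus
seeded noise — so the velocity magnitude leads the burst-driven uncertainty
rise by a configurable number of cluster units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import ExpressionMatrix
from .telegraph import TelegraphParams

__all__ = ["LineageScenario", "GroundTruth", "generate", "preset_scenarios"]


@dataclass
class LineageScenario:
    """Specification of a planted lineage; see module docstring.

    ``topology`` lists directed edges of a tree rooted at cluster 1.
    ``transition_clusters`` maps cluster labels to burst-inflation factors
    f (>= 1): at the transition cluster the burst module's burst size is
    multiplied by f and its burst frequency by sqrt(f), with a graded ramp
    on neighbouring clusters.
    """

    name: str
    topology: list[tuple[int, int]]
    cells_per_cluster: int = 100
    n_genes: int = 60
    transition_clusters: dict[int, float] = field(default_factory=dict)
    velocity_lag: int = 1
    seed: int = 0
    transition_gene_fraction: float = 0.15
    theta_t_range: tuple[float, float] = (8.0, 40.0)
    burst_size_range: tuple[float, float] = (5.0, 50.0)
    theta_on_root_range: tuple[float, float] = (0.03, 0.6)
    theta_on_bounds: tuple[float, float] = (0.01, 2.5)
    theta_off_bounds: tuple[float, float] = (0.25, 4.0)
    drift_sd: float = 0.6
    drift_jitter_sd: float = 0.7
    branch_step_sd: float = 0.6
    pseudotime_jitter_sd: float = 0.02
    velocity_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        g = nx.DiGraph(self.topology)
        nodes = sorted(g.nodes)
        if nodes != list(range(1, len(nodes) + 1)):
            raise ValueError("clusters must be labelled 1..K")
        if not nx.is_arborescence(g):
            raise ValueError("topology must be a tree rooted at cluster 1")
        roots = [n for n in g.nodes if g.in_degree(n) == 0]
        if roots != [1]:
            raise ValueError("topology must be rooted at cluster 1")
        for k, f in self.transition_clusters.items():
            if k not in g.nodes:
                raise ValueError(f"transition cluster {k} not in topology")
            if f < 1:
                raise ValueError("inflation factors must be >= 1")
        if self.cells_per_cluster < 1 or self.n_genes < 1:
            raise ValueError("cells_per_cluster and n_genes must be >= 1")

    @property
    def n_clusters(self) -> int:
        return len(set(c for e in self.topology for c in e))

    @property
    def tree(self) -> nx.DiGraph:
        return nx.DiGraph(self.topology)

    def depths(self) -> dict[int, int]:
        return nx.single_source_shortest_path_length(self.tree, 1)


@dataclass
class GroundTruth:
    """Planted quantities aligned with the generated matrix."""

    labels: np.ndarray
    pseudotime: np.ndarray
    theta_on: np.ndarray   # (K, G)
    theta_off: np.ndarray
    theta_t: np.ndarray
    burst_size: np.ndarray
    burst_frequency: np.ndarray
    velocity_lag: int
    topology: list[tuple[int, int]]
    depths: dict[int, int]

    def params(self, cluster: int, gene: int) -> TelegraphParams:
        k = cluster - 1
        return TelegraphParams(
            theta_on=float(self.theta_on[k, gene]),
            theta_off=float(self.theta_off[k, gene]),
            theta_t=float(self.theta_t[k, gene]),
        )


def _plant_parameters(scenario: LineageScenario, rng: np.random.Generator):
    """Plant per-(gene, cluster) telegraph rates along the lineage tree.

    Differentiation is modelled as burst-frequency modulation: the
    transcription rate and burst size are gene-intrinsic, while the
    activation rate theta_on performs a per-gene drift walk in log space
    along the tree edges, so neighbouring clusters resemble each other and
    separation grows with lineage depth.  Sibling branches receive
    opposite-signed drift components on top of the inherited trunk drift.
    """
    K, G = scenario.n_clusters, scenario.n_genes
    lo_t, hi_t = scenario.theta_t_range
    theta_t = np.tile(np.exp(rng.uniform(np.log(lo_t), np.log(hi_t), G)),
                      (K, 1))
    lo_s, hi_s = scenario.burst_size_range
    size = np.exp(rng.uniform(np.log(lo_s), np.log(hi_s), G))
    theta_off = np.tile(
        np.clip(theta_t[0] / size, *scenario.theta_off_bounds), (K, 1))
    lo_on, hi_on = scenario.theta_on_root_range
    log_on = np.zeros((K, G))
    log_on[0] = rng.uniform(np.log(lo_on), np.log(hi_on), G)
    tree = scenario.tree
    drift = {1: rng.normal(0.0, scenario.drift_sd, G)}
    for node in nx.topological_sort(tree):
        children = sorted(tree.successors(node))
        if not children:
            continue
        if len(children) >= 2:
            u = rng.normal(0.0, scenario.branch_step_sd, G)
            child_drifts = [drift[node] + (u if i % 2 == 0 else -u)
                            for i in range(len(children))]
        else:
            child_drifts = [drift[node]]
        for child, d in zip(children, child_drifts):
            drift[child] = d
            log_on[child - 1] = (
                log_on[node - 1] + d
                + rng.normal(0.0, scenario.drift_jitter_sd, G)
            )
    # reflect the walk at the bounds so deep clusters keep separating
    # instead of piling up on a clamp
    lo_b, hi_b = np.log(scenario.theta_on_bounds)
    period = 2.0 * (hi_b - lo_b)
    y = np.mod(log_on - lo_b, period)
    theta_on = np.exp(lo_b + np.minimum(y, period - y))
    # Burst inflation acts on a transition-specific gene module and ramps
    # over two lineage hops on either side of the transition cluster, so
    # the module engages gradually and disengages in the fates.  At ramp
    # level c the module's burst size scales by c and its burst frequency
    # by sqrt(c): theta_t * sqrt(c), theta_off / sqrt(c), theta_on *
    # sqrt(c); the transition cluster itself sits at c = f.
    n_mod = max(1, int(round(scenario.transition_gene_fraction * G)))
    undirected = tree.to_undirected()
    for k, f in sorted(scenario.transition_clusters.items()):
        module = rng.choice(G, size=n_mod, replace=False)
        # Engagement profile over graph hops from the transition cluster.
        # The concave drop (1 -> 0.45) followed by a shallow tail keeps a
        # saddle between the hills of two transitions that sit two hops
        # apart, while the tail limits the per-edge footprint the module
        # adds to cluster distances.
        ramp = {0: 1.0, 1: 0.45, 2: 0.25}
        hops = nx.single_source_shortest_path_length(undirected, k)
        for j in range(1, K + 1):
            e = ramp.get(hops[j], 0.0)
            if e == 0.0:
                continue
            c = f ** e
            theta_t[j - 1, module] = theta_t[j - 1, module] * c ** 0.5
            theta_off[j - 1, module] = theta_off[j - 1, module] / c ** 0.5
            theta_on[j - 1, module] = theta_on[j - 1, module] * c ** 0.5
    return theta_on, theta_off, theta_t


def generate(
    scenario: LineageScenario,
) -> tuple[ExpressionMatrix, np.ndarray, GroundTruth]:
    """Sample counts, the velocity proxy and ground truth for a scenario.

    Deterministic given ``scenario.seed``: identical scenarios produce
    byte-identical outputs.
    """
    rng = np.random.default_rng(scenario.seed)
    K, G = scenario.n_clusters, scenario.n_genes
    n_per = scenario.cells_per_cluster
    theta_on, theta_off, theta_t = _plant_parameters(scenario, rng)
    depths = scenario.depths()
    max_depth = max(depths.values()) or 1

    labels = np.repeat(np.arange(1, K + 1), n_per)
    N = labels.size
    counts = np.empty((N, G), dtype=np.int64)
    for k in range(1, K + 1):
        rows = slice((k - 1) * n_per, k * n_per)
        p = rng.beta(theta_on[k - 1][None, :], theta_off[k - 1][None, :],
                     size=(n_per, G))
        counts[rows] = rng.poisson(theta_t[k - 1][None, :] * p)

    pseudotime = np.clip(
        np.array([depths[k] / max_depth for k in labels])
        + rng.normal(0.0, scenario.pseudotime_jitter_sd, N),
        0.0, 1.0,
    )

    # velocity proxy: |mean expression `velocity_lag` depths ahead - own mean|
    mean_expr = theta_t * theta_on / (theta_on + theta_off)  # (K, G)
    tree = scenario.tree
    ahead = np.zeros((K, G))
    for k in range(1, K + 1):
        targets = [d for d in nx.descendants(tree, k)
                   if depths[d] == depths[k] + scenario.velocity_lag]
        if targets:
            ahead[k - 1] = np.mean([mean_expr[d - 1] for d in targets],
                                   axis=0)
        else:
            ahead[k - 1] = mean_expr[k - 1]  # leaf region: no change ahead
    base_v = np.abs(ahead - mean_expr)  # (K, G)
    noise_scale = scenario.velocity_noise_sd * max(
        1e-12, float(np.sqrt(np.mean(base_v**2))))
    velocity = base_v[labels - 1] + rng.normal(0.0, noise_scale, (N, G))

    cell_ids = [f"cell_{i:04d}" for i in range(N)]
    gene_ids = [f"gene_{g:03d}" for g in range(G)]
    matrix = ExpressionMatrix(
        values=counts,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        capture_time=np.array([float(depths[k]) for k in labels]),
    )
    truth = GroundTruth(
        labels=labels,
        pseudotime=pseudotime,
        theta_on=theta_on,
        theta_off=theta_off,
        theta_t=theta_t,
        burst_size=theta_t / theta_off,
        burst_frequency=theta_on,
        velocity_lag=scenario.velocity_lag,
        topology=list(scenario.topology),
        depths=depths,
    )
    return matrix, velocity, truth


def preset_scenarios(seed: int = 0) -> dict[str, LineageScenario]:
    """Named scenarios covering linear, single- and double-branching lineages.

    * ``linear-4`` — four clusters in a path (50 genes, 400 cells), transition
      cluster 3 inflated; a compact clustering benchmark.
    * ``linear-6`` — six clusters in a path, transition cluster 3 inflated.
    * ``bifurcation-5`` — 1->2->3 with 3 branching into 4 and 5; the branch
      cluster 3 is the inflated transition state (60 genes, 100
      cells/cluster).
    * ``two-bifurcation-7`` — two branch points (clusters 2 and 5), both
      inflated, yielding two uncertainty hills.
    """
    return {
        "linear-4": LineageScenario(
            name="linear-4",
            topology=[(1, 2), (2, 3), (3, 4)],
            cells_per_cluster=100,
            n_genes=50,
            transition_clusters={3: 5.0},
            seed=seed,
        ),
        "linear-6": LineageScenario(
            name="linear-6",
            topology=[(1, 2), (2, 3), (3, 4), (4, 5), (5, 6)],
            cells_per_cluster=100,
            n_genes=50,
            transition_clusters={3: 5.0},
            seed=seed,
        ),
        "bifurcation-5": LineageScenario(
            name="bifurcation-5",
            topology=[(1, 2), (2, 3), (3, 4), (3, 5)],
            cells_per_cluster=100,
            n_genes=60,
            transition_clusters={3: 5.0},
            seed=seed,
        ),
        "two-bifurcation-7": LineageScenario(
            name="two-bifurcation-7",
            topology=[(1, 2), (2, 3), (2, 4), (4, 5), (5, 6), (5, 7)],
            cells_per_cluster=100,
            n_genes=60,
            transition_clusters={2: 5.0, 5: 5.0},
            seed=seed,
        ),
    }
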