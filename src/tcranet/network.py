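"""Per-(sample, time point) repertoire graphs and their discriminative statistics.

Filtered Clone-Attractors become graph nodes; an edge joins two attractors
whenever the weighted edit distance between their representatives does not
exceed a cutoff.  Each (sample, time point) has its own graph over the
attractors active there.  Two statistics summarise a graph:

MTI (molecular topological index)
    ``MTI = sum_i sum_j d_i (A_ij + D_ij)`` with ``d`` the degree vector,
    ``A`` the adjacency indicator and ``D`` the shortest-path edge-count
    matrix.  The index decreases as a graph of fixed size becomes more
    branched.  On a disconnected graph ``D`` is undefined across
    components; the index is evaluated per connected component and summed,
    which coincides with the definition on connected graphs.

sBWC (summed betweenness centrality)
    Per node, the unnormalised betweenness ``BWC(i) = sum_{j<k} g_jk(i)/g_jk``;
    per graph, the sum of the components strictly exceeding a threshold
    pooled over *all* graphs (by default the pooled median, th50) —
    "the average amount of influential CAs".

The module also fits the cluster-size power law ``P(K) ~ K^-alpha``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from tcranet.clustering import ActivityMatrix, AttractorSet
from tcranet.distance import ABOVE_CUTOFF, EditWeights, distance_within

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GraphFilters:
    """Attractor and edge filters applied before graph construction.

    Defaults: nodes need at least 10 member sequences, edges are kept up to
    representative distance 8, and an attractor must be active (amplitude
    > 0 in at least one sample) in more than 60% of the time points.
    """

    min_members: int = 10
    max_edge_distance: float = 8.0
    min_timepoint_fraction: float = 0.6

    def __post_init__(self) -> None:
        if self.min_members <= 0 or self.max_edge_distance <= 0:
            raise ValueError("filters must be positive")
        if not 0 < self.min_timepoint_fraction <= 1:
            raise ValueError("min_timepoint_fraction must be in (0, 1]")


@dataclass
class RepGraph:
    """Graph of active Clone-Attractors for one (sample, time point)."""

    sample_id: str
    time_point: int
    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class PowerLawFit:
    """Least-squares fit of ``P(K) ~ K^-alpha`` on log-binned sizes."""

    alpha: float
    prefactor: float
    k_range: tuple[int, int]
    r_squared: float
    alpha_mle: float  # discrete maximum-likelihood estimate, diagnostic


@dataclass
class MeasureTable:
    """MTI and sBWC per (sample, time point) plus per-sample summaries."""

    per_point: pd.DataFrame  # index (sample_id, time_point); columns mti, sbwc, n_nodes
    per_sample: pd.DataFrame  # index sample_id; columns {mti,sbwc}_{median,std}


def filter_attractors(
    aset: AttractorSet, activity: ActivityMatrix, f: GraphFilters = GraphFilters()
) -> list[int]:
    """Attractor ids passing the size and temporal-coverage filters.

    An attractor is kept iff it has at least ``f.min_members`` member
    sequences *and* is active — amplitude > 0 in at least one sample — in
    strictly more than ``f.min_timepoint_fraction`` of the time points.
    """
    sizes = {ca.ca_id: ca.size for ca in aset.attractors}
    tps = activity.time_points
    active_tp = (activity.data > 0).T.groupby(level="time_point").any().T
    kept = []
    for ca_id in activity.data.index:
        if sizes.get(ca_id, 0) < f.min_members:
            continue
        frac = active_tp.loc[ca_id].sum() / len(tps)
        if frac > f.min_timepoint_fraction:
            kept.append(ca_id)
    if not kept:
        logger.warning("attractor filtering produced an empty set")
    logger.info("kept %d of %d attractors after filtering", len(kept), len(sizes))
    return kept


def representative_distances(
    representatives: Mapping[int, str],
    w: EditWeights = EditWeights(),
    cutoff: float = 8.0,
) -> dict[tuple[int, int], float]:
    """Pairwise representative distances not exceeding ``cutoff``."""
    ids = sorted(representatives)
    out: dict[tuple[int, int], float] = {}
    for i, a in enumerate(ids):
        ra = representatives[a]
        for b in ids[i + 1 :]:
            d = distance_within(ra, representatives[b], w, cutoff)
            if d is not ABOVE_CUTOFF:
                out[(a, b)] = d
    return out


def build_graph(
    filtered: Sequence[int],
    amplitudes: Mapping[int, float],
    representatives: Mapping[int, str],
    w: EditWeights = EditWeights(),
    f: GraphFilters = GraphFilters(),
    *,
    sample_id: str = "",
    time_point: int = 0,
    sizes: Mapping[int, int] | None = None,
    distances: Mapping[tuple[int, int], float] | None = None,
) -> RepGraph:
    """Graph over the filtered attractors active at one (sample, time point).

    Nodes are the filtered attractors with positive amplitude; an edge
    joins nodes whose representative distance is <= ``f.max_edge_distance``.
    ``distances`` may carry precomputed pairwise distances (as produced by
    :func:`representative_distances`) to avoid recomputation across the
    many graphs sharing one attractor space.
    """
    nodes = [ca for ca in filtered if amplitudes.get(ca, 0) > 0]
    g = nx.Graph()
    for ca in nodes:
        g.add_node(
            ca,
            amplitude=float(amplitudes[ca]),
            size=int(sizes[ca]) if sizes is not None else 0,
        )
    if distances is None:
        distances = representative_distances(
            {ca: representatives[ca] for ca in nodes}, w, f.max_edge_distance
        )
    node_set = set(nodes)
    for (a, b), d in distances.items():
        if a in node_set and b in node_set and d <= f.max_edge_distance:
            g.add_edge(a, b, weight=float(d))
    return RepGraph(sample_id, time_point, g)


def build_graphs(
    aset: AttractorSet,
    activity: ActivityMatrix,
    f: GraphFilters = GraphFilters(),
    filtered: Sequence[int] | None = None,
) -> list[RepGraph]:
    """All per-(sample, time point) graphs over one shared attractor space."""
    if filtered is None:
        filtered = filter_attractors(aset, activity, f)
    reps = aset.representatives
    sizes = {ca.ca_id: ca.size for ca in aset.attractors}
    dist = representative_distances(
        {ca: reps[ca] for ca in filtered}, aset.weights, f.max_edge_distance
    )
    graphs = []
    for sample_id, time_point in activity.data.columns:
        col = activity.data[(sample_id, time_point)]
        graphs.append(
            build_graph(
                filtered, col.to_dict(), reps, aset.weights, f,
                sample_id=sample_id, time_point=int(time_point),
                sizes=sizes, distances=dist,
            )
        )
    return graphs


def _as_graph(g: RepGraph | nx.Graph) -> nx.Graph:
    return g.graph if isinstance(g, RepGraph) else g


def mti(g: RepGraph | nx.Graph) -> float:
    """Molecular topological index ``sum_i d_i sum_j (A_ij + D_ij)``.

    Evaluated per connected component and summed, so pairs of mutually
    unreachable nodes contribute nothing; on a connected graph this is the
    plain double sum.  ``sum_j A_ij`` is the degree, hence the row term is
    ``d_i (d_i + sum_j D_ij)``.
    """
    graph = _as_graph(g)
    total = 0.0
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        spl = dict(nx.all_pairs_shortest_path_length(sub))
        for i in sub.nodes:
            di = sub.degree(i)
            total += di * (di + sum(spl[i].values()))
    return float(total)


def bwc(g: RepGraph | nx.Graph) -> dict:
    """Unnormalised betweenness centrality per node.

    For every unordered pair (j, k) distinct from i, the fraction of
    shortest j-k paths passing through i; pairs in different components
    contribute 0.
    """
    return {k: float(v) for k, v in
            nx.betweenness_centrality(_as_graph(g), normalized=False).items()}


def sbwc_scores(
    bwc_by_graph: Mapping, percentile: float = 50.0
) -> tuple[dict, float]:
    """Per-graph sBWC given the BWC vectors of *all* graphs.

    The threshold is the ``percentile`` (default the median, th50) of the
    BWC values pooled across every graph; empty graphs contribute no
    values.  Each graph's sBWC is the sum of its components *strictly*
    above the threshold.
    """
    pooled = [v for vec in bwc_by_graph.values() for v in vec.values()]
    if not pooled:
        return {k: 0.0 for k in bwc_by_graph}, 0.0
    th = float(np.percentile(pooled, percentile))
    scores = {
        k: float(sum(v for v in vec.values() if v > th))
        for k, vec in bwc_by_graph.items()
    }
    return scores, th


def measure_table(graphs: Iterable[RepGraph], percentile: float = 50.0) -> MeasureTable:
    """MTI and sBWC per (sample, time point), with per-sample median and std
    taken over that sample's own time points."""
    graphs = list(graphs)
    keys = [(g.sample_id, g.time_point) for g in graphs]
    bwc_by_graph = {k: bwc(g) for k, g in zip(keys, graphs)}
    scores, th = sbwc_scores(bwc_by_graph, percentile)
    per_point = pd.DataFrame(
        {
            "mti": [mti(g) for g in graphs],
            "sbwc": [scores[k] for k in keys],
            "n_nodes": [g.n_nodes for g in graphs],
        },
        index=pd.MultiIndex.from_tuples(keys, names=["sample_id", "time_point"]),
    )
    grouped = per_point.groupby(level="sample_id")
    if (grouped.size() == 1).any():
        warnings.warn("per-sample std computed over a single time point is 0", stacklevel=2)
    per_sample = pd.DataFrame(
        {
            "mti_median": grouped["mti"].median(),
            "mti_std": grouped["mti"].std(ddof=0),
            "sbwc_median": grouped["sbwc"].median(),
            "sbwc_std": grouped["sbwc"].std(ddof=0),
        }
    )
    per_point.attrs["bwc_threshold"] = th
    return MeasureTable(per_point, per_sample)


def powerlaw_fit(
    sizes: Iterable[int],
    min_count: int = 4,
    mode: str = "persize",
    bin_factor: float = 2.0,
) -> PowerLawFit:
    """Fit the exponent of ``P(K) ~ K^-alpha`` to a collection of sizes.

    Primary estimate (``mode="persize"``): least-squares slope of log count
    versus log size over the distinct integer sizes, restricted to sizes
    observed at least ``min_count`` times.  For a discrete power law the
    per-size counts are exact evaluations of the density, so this slope is
    unbiased where counts are informative, whereas wide logarithmic bins
    systematically distort steep discrete laws; the minimum-count guard
    discards the Poisson-dominated tail.  ``mode="logbin"`` instead bins
    sizes logarithmically (width factor ``bin_factor``) and fits count
    density at the within-bin geometric mean.  A discrete
    maximum-likelihood estimate (zeta likelihood) is reported alongside as
    a diagnostic.

    Raises
    ------
    ValueError
        On degenerate input (< 5 distinct sizes, e.g. all sizes equal).
    """
    sizes = np.asarray(list(sizes), dtype=float)
    if sizes.size == 0 or np.any(sizes < 1):
        raise ValueError("sizes must be integers >= 1")
    distinct, counts = np.unique(sizes, return_counts=True)
    if distinct.size < 5:
        raise ValueError(
            f"power-law fit needs >= 5 distinct size values, got {distinct.size}"
        )
    kmin, kmax = int(distinct[0]), int(distinct[-1])

    if mode == "persize":
        keep = counts >= min_count
        while keep.sum() < 3 and min_count > 1:
            min_count -= 1
            keep = counts >= min_count
        xs, ys = distinct[keep], counts[keep]
    elif mode == "logbin":
        edges = [float(kmin)]
        while edges[-1] <= kmax:
            edges.append(edges[-1] * bin_factor)
        edges = np.array(edges)
        which = np.digitize(sizes, edges) - 1
        xs, ys = [], []
        for b in range(which.max() + 1):
            mask = which == b
            n = mask.sum()
            if n == 0:
                continue
            width = np.floor(edges[b + 1] - 1e-12) - np.ceil(edges[b]) + 1
            xs.append(np.exp(np.mean(np.log(sizes[mask]))))
            ys.append(n / max(width, 1.0))
    else:
        raise ValueError(f"unknown powerlaw_fit mode {mode!r}")
    if len(xs) < 3:
        raise ValueError("too few informative sizes/bins for a power-law fit")
    res = stats.linregress(np.log(xs), np.log(ys))
    alpha = -res.slope
    if alpha <= 0:
        raise ValueError(f"fitted exponent is not positive (alpha={alpha:.3f})")

    # discrete MLE: maximise -alpha*sum(log k) - n*log(zeta(alpha, kmin))
    logsum = np.sum(np.log(sizes))
    n = sizes.size

    def nll(a: float) -> float:
        return a * logsum + n * np.log(special.zeta(a, kmin))

    mle = optimize.minimize_scalar(nll, bounds=(1.01, 20.0), method="bounded")
    return PowerLawFit(
        alpha=float(alpha),
        prefactor=float(np.exp(res.intercept)),
        k_range=(kmin, kmax),
        r_squared=float(res.rvalue**2),
        alpha_mle=float(mle.x),
    )


def export_graph(g: RepGraph, path, fmt: str = "graphml") -> None:
    """Write a repertoire graph as GraphML or GEXF for external tools.

    Node attributes carry the CA size and amplitude; edge weights carry the
    representative distance.
    """
    graph = g.graph.copy()
    graph.graph["sample_id"] = g.sample_id
    graph.graph["time_point"] = g.time_point
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "gexf":
        nx.write_gexf(graph, path)
    else:
        raise ValueError(f"unknown graph export format {fmt!r} (use graphml or gexf)")
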