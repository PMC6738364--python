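"""Normal-mixture simulation of a small transcription-factor network.

The generator emulates a regulatory cascade: root (and independent) genes
express as Normal(1, 1); each target gene is, per sample, either

* unregulated (probability ``1 - b`` for binding efficiency ``b``), drawn
  from Normal(-1, 1), or
* regulated: drawn from Normal(s_i, 0.25) when its direct source's value
  s_i is positive (the source is expressed), and from Normal(-1, 0.25)
  otherwise.

All Normal(m, s) parameters are (mean, standard deviation). The default
topology is the six-node pseudo-network used throughout validation: root
A11 regulating A21 (b=0.9) and A22 (b=0.7), A21 regulating A31 (b=0.9) and
A32 (b=0.8), plus an independent negative-control node B.

:func:`replicate_experiment` repeatedly simulates the network, rebuilds it
with the CID/pCID procedure from each designated source, and tallies edge
detection, direction correctness, exact topology recovery, and
negative-control inclusion, optionally alongside the sampling distribution
of named CID/pCID statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import CIDEngine, ExpressionMatrix, KernelConfig
from .network import DirectedNetwork, assemble, build_subnetwork
from .significance import (PermutationPlan, StatisticSpec, permutation_test,
                           observed_value)

__all__ = [
    "NetworkSpec",
    "SimulationSummary",
    "six_node_spec",
    "simulate_dataset",
    "replicate_experiment",
    "analytic_root_positive_prob",
    "table3_statistics",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkSpec:
    """Topology and mixture parameters of a simulated network.

    ``edges`` are (source, target, binding_efficiency) triples; the edge
    graph must be a DAG in which every target has exactly one direct
    source. Root and independent nodes share the Normal(root_mean,
    root_sd) expression law; independent nodes have no edges at all.
    """

    root_nodes: tuple[str, ...]
    independent_nodes: tuple[str, ...]
    edges: tuple[tuple[str, str, float], ...]
    root_mean: float = 1.0
    root_sd: float = 1.0
    regulated_sd: float = 0.25
    off_mean: float = -1.0
    off_sd_unregulated: float = 1.0
    off_sd_regulated: float = 0.25

    def __post_init__(self) -> None:
        for s, t, b in self.edges:
            if not (0.0 < b <= 1.0):
                raise ValueError(f"binding efficiency {b} for ({s}, {t}) "
                                 "outside (0, 1]")
        g = nx.DiGraph()
        g.add_nodes_from(self.root_nodes)
        g.add_edges_from((s, t) for s, t, _ in self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("edge graph contains a cycle")
        indeg = dict(g.in_degree())
        multi = [n for n, d in indeg.items() if d > 1]
        if multi:
            raise ValueError("targets with more than one direct source: "
                             f"{sorted(multi)}")
        overlap = set(self.independent_nodes) & set(g.nodes)
        if overlap:
            raise ValueError(f"independent nodes appear in the edge graph: "
                             f"{sorted(overlap)}")

    @property
    def nodes(self) -> tuple[str, ...]:
        ordered: list[str] = list(self.root_nodes)
        for s, t, _ in self.edges:
            for n in (s, t):
                if n not in ordered:
                    ordered.append(n)
        ordered += [n for n in self.independent_nodes if n not in ordered]
        return tuple(ordered)

    @property
    def targets(self) -> tuple[str, ...]:
        return tuple(t for _, t, _ in self.edges)

    def undirected_pairs(self) -> set[frozenset[str]]:
        return {frozenset((s, t)) for s, t, _ in self.edges}

    def topological_targets(self) -> list[tuple[str, str, float]]:
        """Edges ordered so every source is generated before its targets."""
        g = nx.DiGraph()
        g.add_edges_from((s, t) for s, t, _ in self.edges)
        order = {n: i for i, n in
                 enumerate(nx.lexicographical_topological_sort(g))}
        return sorted(self.edges, key=lambda e: (order[e[1]], e[1]))


def six_node_spec() -> NetworkSpec:
    """The default six-node pseudo-network (root A11, control B)."""
    return NetworkSpec(
        root_nodes=("A11",),
        independent_nodes=("B",),
        edges=(("A11", "A21", 0.9), ("A11", "A22", 0.7),
               ("A21", "A31", 0.9), ("A21", "A32", 0.8)),
    )


def analytic_root_positive_prob(mean: float, sd: float) -> float:
    """P(S > 0) for S ~ Normal(mean, sd): 1 - Phi(-mean/sd)."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return float(norm.sf(-mean / sd))


def simulate_dataset(spec: NetworkSpec, n_samples: int,
                     seed: int | np.random.Generator = 0,
                     return_branches: bool = False):
    """One simulated expression matrix (probes x samples).

    Targets are generated in topological order; the regulated/unregulated
    branch is an independent Bernoulli(b) draw per sample per edge. With
    ``return_branches`` also returns, per target, which samples took the
    regulated branch and which had a positive (expressed) source — the
    mixture bookkeeping behind the per-edge transmission probability
    P(S -> T) = b * P(S > 0).
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    values: dict[str, np.ndarray] = {}
    branches: dict[str, dict[str, np.ndarray]] = {}
    for node in sorted(set(spec.root_nodes) | set(spec.independent_nodes)):
        values[node] = rng.normal(spec.root_mean, spec.root_sd, n_samples)
    for s, t, b in spec.topological_targets():
        src = values[s]
        regulated = rng.random(n_samples) < b
        expressed = src > 0
        out = rng.normal(spec.off_mean, spec.off_sd_unregulated, n_samples)
        on = regulated & expressed
        off = regulated & ~expressed
        out[on] = rng.normal(src[on], spec.regulated_sd)
        out[off] = rng.normal(spec.off_mean, spec.off_sd_regulated,
                              int(off.sum()))
        values[t] = out
        branches[t] = {"regulated": regulated, "source_positive": expressed}
    probes = list(spec.nodes)
    sample_ids = [f"s{i + 1}" for i in range(n_samples)]
    matrix = ExpressionMatrix(probes, sample_ids,
                              np.vstack([values[p] for p in probes]))
    if return_branches:
        return matrix, branches
    return matrix


# ---------------------------------------------------------------------------
# Replicate experiments
# ---------------------------------------------------------------------------

def table3_statistics(spec: NetworkSpec | None = None
                      ) -> list[StatisticSpec]:
    """The CID/pCID evaluations tracked in the replicate summaries.

    Covers the seed-step CIDs from the root and the negative control plus
    the pCIDs along the elongation walk of the default network.
    """
    s = [
        StatisticSpec("CID", "A11", ("A21",)),
        StatisticSpec("CID", "A11", ("A22",)),
        StatisticSpec("CID", "A11", ("A31",)),
        StatisticSpec("CID", "A11", ("A32",)),
        StatisticSpec("CID", "A11", ("B",)),
        StatisticSpec("CID", "A21", ("A11",)),
        StatisticSpec("pCID", "A11", ("A22",), ("A21",)),
        StatisticSpec("pCID", "A11", ("A31",), ("A21",)),
        StatisticSpec("pCID", "A11", ("A32",), ("A21",)),
        StatisticSpec("pCID", "A11", ("B",), ("A21",)),
        StatisticSpec("pCID", "A21", ("A22",), ("A11",)),
        StatisticSpec("pCID", "A22", ("A11",), ("A21",)),
        StatisticSpec("pCID", "A21", ("A31",), ("A11", "A22")),
        StatisticSpec("pCID", "A21", ("A32",), ("A11", "A22")),
        StatisticSpec("pCID", "A21", ("B",), ("A11", "A22")),
        StatisticSpec("pCID", "A31", ("A21",), ("A11", "A22")),
        StatisticSpec("pCID", "A21", ("A32",), ("A11", "A22", "A31")),
        StatisticSpec("pCID", "A32", ("A21",), ("A11", "A22", "A31")),
        StatisticSpec("CID", "B", ("A11",)),
        StatisticSpec("CID", "B", ("A21",)),
    ]
    return s


def _stat_label(spec: StatisticSpec) -> str:
    preds = ",".join(spec.predictors)
    if spec.kind == "pCID":
        return f"pCID({spec.response}|{preds}; {','.join(spec.conditioning)})"
    return f"CID({spec.response}|{preds})"


@dataclass
class SimulationSummary:
    """Replicate-level recovery counts and statistic distributions."""

    n_reps: int
    n_samples: int
    sources: tuple[str, ...]
    #: per true edge: detected / correct-direction / wrong-direction counts
    edge_counts: pd.DataFrame
    #: replicates whose root sub-network exactly matches the true topology
    exact_recovery: dict[str, int]
    #: replicates in which each independent node entered the assembly
    control_inclusion: dict[str, int]
    #: replicates in which each seed source was discarded outright
    discarded: dict[str, int]
    #: per tracked statistic: median, IQR, significant proportion (NaN when
    #: significance was not evaluated)
    statistics: pd.DataFrame | None = None

    def edge_detection_rate(self, s: str, t: str) -> float:
        return (self.edge_counts.loc[f"{s}->{t}", "detected"]
                / self.n_reps)

    def recovery_rate(self, source: str) -> float:
        return self.exact_recovery[source] / self.n_reps

    def inclusion_rate(self, node: str) -> float:
        return self.control_inclusion[node] / self.n_reps


def replicate_experiment(spec: NetworkSpec, n_samples: int, n_reps: int,
                         plan: PermutationPlan,
                         alpha: float = 0.05, seed: int = 0,
                         sources: Sequence[str] | None = None,
                         stat_specs: Iterable[StatisticSpec] | None = None,
                         stat_significance: bool = False,
                         cfg: KernelConfig | None = None
                         ) -> SimulationSummary:
    """Simulate-and-rebuild the network ``n_reps`` times and tally results.

    For each replicate the network is reconstructed independently from
    every designated source (by default the spec's roots and independent
    nodes, mirroring a study design with one true and one negative-control
    seed). Exact recovery is judged per root source: the sub-network's
    undirected edge set must equal the true edge set. Control inclusion is
    judged on the assembled union of all sub-networks.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if sources is None:
        sources = tuple(spec.root_nodes) + tuple(spec.independent_nodes)
    sources = tuple(sources)
    truth = spec.undirected_pairs()
    edge_labels = [f"{s}->{t}" for s, t, _ in spec.edges]
    counts = pd.DataFrame(0, index=edge_labels,
                          columns=["detected", "correct_direction",
                                   "wrong_direction"])
    exact = {r: 0 for r in spec.root_nodes if r in sources}
    control = {c: 0 for c in spec.independent_nodes}
    discarded = {s: 0 for s in sources}
    stat_specs = list(stat_specs) if stat_specs is not None else None
    stat_rows: list[dict[str, float]] = []
    sig_rows: list[dict[str, float]] = []

    for rep in range(n_reps):
        ss = np.random.SeedSequence([int(seed), rep])
        data_rng = np.random.default_rng(ss)
        matrix = simulate_dataset(spec, n_samples, data_rng)
        rep_seed = int(ss.generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
        rep_plan = replace(plan, seed=rep_seed)
        engine = CIDEngine(matrix, cfg)
        subnets: dict[str, DirectedNetwork] = {}
        for src in sources:
            subnets[src] = build_subnetwork(src, engine, rep_plan, alpha)
            if subnets[src].discarded:
                discarded[src] += 1
        assembled = assemble(subnets.values())
        pairs = assembled.undirected_pairs()
        directed = {(e.source, e.target) for e in assembled.edges}
        for (s, t, _), label in zip(spec.edges, edge_labels):
            if frozenset((s, t)) in pairs:
                counts.loc[label, "detected"] += 1
                if (s, t) in directed:
                    counts.loc[label, "correct_direction"] += 1
                if (t, s) in directed:
                    counts.loc[label, "wrong_direction"] += 1
        for root in exact:
            if subnets[root].undirected_pairs() == truth:
                exact[root] += 1
        for c in control:
            if c in assembled.nodes:
                control[c] += 1
        if stat_specs:
            row: dict[str, float] = {}
            sig: dict[str, float] = {}
            for st in stat_specs:
                label = _stat_label(st)
                if stat_significance:
                    res = permutation_test(st, engine, rep_plan)
                    row[label] = res.value
                    sig[label] = float(res.p_value <= alpha)
                else:
                    row[label] = observed_value(st, engine)
            stat_rows.append(row)
            if stat_significance:
                sig_rows.append(sig)

    statistics = None
    if stat_specs:
        values = pd.DataFrame(stat_rows)
        statistics = pd.DataFrame({
            "median": values.median(),
            "iqr": values.quantile(0.75) - values.quantile(0.25),
        })
        if sig_rows:
            statistics["sig_prop"] = pd.DataFrame(sig_rows).mean()
        else:
            statistics["sig_prop"] = float("nan")
    return SimulationSummary(n_reps=n_reps, n_samples=n_samples,
                             sources=sources, edge_counts=counts,
                             exact_recovery=exact,
                             control_inclusion=control,
                             discarded=discarded, statistics=statistics)
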