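"""Stepwise construction of directed gene regulatory networks.

The build has three stages:

1. **Seed pair** — from a chosen source probe ``T0``, test CID(T0|Ti)
   against every candidate target; the most significant candidate becomes
   the first node, and the edge direction is taken from whichever of
   CID(T0|T1) and CID(T1|T0) is more significant (the *response* of the
   winning statistic is the regulator).
2. **Elongation** — repeatedly add the candidate T with the most
   significant pCID(S|T; current\\{S}) over all eligible path members S,
   orienting each new edge by the same more-significant rule, until no
   partial statistic clears the significance level.
3. **Assembly** — union the per-source sub-networks, merging duplicate
   edges (keeping the smallest p-value) and leaving conflicting directions
   as two flagged edges.

"More significant" is a total order: smaller p-value first, then larger
statistic value, then lexicographically smaller probe id — which makes the
whole construction deterministic for a fixed seed and data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .core import CIDEngine, DependenceResult, ExpressionMatrix, KernelConfig
from .significance import PermutationPlan, StatisticSpec, permutation_test

__all__ = [
    "RoleTable",
    "RegulationEdge",
    "DirectedNetwork",
    "significance_key",
    "most_significant",
    "orient",
    "select_first_target",
    "elongation_step",
    "build_subnetwork",
    "assemble",
    "network_summaries",
]

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class RoleTable:
    """Which probes may act as regulation sources and/or targets.

    In the transcription-factor setting, source capability means the probe's
    gene product binds the cis-element (e.g. is a G-box binder) and target
    capability means the element occurs in the probe's promoter. A probe may
    hold both roles; every probe must hold at least one.
    """

    def __init__(self, roles: Mapping[str, tuple[bool, bool]]):
        for probe, (src, tgt) in roles.items():
            if not (src or tgt):
                raise ValueError(f"probe {probe!r} has no capability")
        self._roles = {str(p): (bool(s), bool(t))
                       for p, (s, t) in roles.items()}

    @classmethod
    def from_flags(cls, source_ids: Iterable[str],
                   target_ids: Iterable[str]) -> "RoleTable":
        src, tgt = set(source_ids), set(target_ids)
        return cls({p: (p in src, p in tgt) for p in src | tgt})

    def __contains__(self, probe: str) -> bool:
        return probe in self._roles

    def __len__(self) -> int:
        return len(self._roles)

    def source_capable(self, probe: str) -> bool:
        return self._roles.get(probe, (False, False))[0]

    def target_capable(self, probe: str) -> bool:
        return self._roles.get(probe, (False, False))[1]

    def sources(self) -> list[str]:
        return sorted(p for p, (s, _) in self._roles.items() if s)

    def targets(self) -> list[str]:
        return sorted(p for p, (_, t) in self._roles.items() if t)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [(p, s, t) for p, (s, t) in sorted(self._roles.items())]
        return pd.DataFrame(rows, columns=["probe_id", "source_capable",
                                           "target_capable"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RoleTable":
        return cls({str(r.probe_id): (bool(r.source_capable),
                                      bool(r.target_capable))
                    for r in df.itertuples(index=False)})


@dataclass(frozen=True)
class RegulationEdge:
    """A directed source -> target relation with the evidence behind it.

    ``forward_p``/``forward_value`` belong to the statistic oriented with
    the edge (response = source); ``reverse_p``/``reverse_value`` to the
    opposite orientation. ``value``/``p_value`` duplicate the forward pair.
    """

    source: str
    target: str
    step: int
    statistic_kind: str  # "CID" or "pCID"
    value: float
    p_value: float
    forward_p: float
    reverse_p: float
    reverse_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-loop edge")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.source, self.target))


@dataclass
class DirectedNetwork:
    """An accumulated directed network (one sub-network or an assembly)."""

    nodes: list[str]
    edges: list[RegulationEdge]
    origin: str

    @property
    def discarded(self) -> bool:
        """True when the seed source found no significant partner."""
        return not self.edges

    def undirected_pairs(self) -> set[frozenset[str]]:
        return {e.pair for e in self.edges}

    def has_pair(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.undirected_pairs()

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, step=e.step,
                       statistic_kind=e.statistic_kind, value=e.value,
                       p_value=e.p_value, forward_p=e.forward_p,
                       reverse_p=e.reverse_p)
        return g


# ---------------------------------------------------------------------------
# Selection and direction rules
# ---------------------------------------------------------------------------

def significance_key(p_value: float, value: float,
                     ids: tuple[str, ...]) -> tuple:
    """Total order for "more significant": min() of these keys wins."""
    return (p_value, -value, ids)


def most_significant(scored: Mapping[tuple | str, DependenceResult]):
    """The key whose result is most significant under the total order."""
    def key(item):
        k, res = item
        ids = (k,) if isinstance(k, str) else tuple(k)
        return significance_key(res.p_value, res.value, ids)
    return min(scored.items(), key=key)


def orient(a: str, a_given_b: tuple[float, float],
           b: str, b_given_a: tuple[float, float]) -> tuple[str, str]:
    """Assign the direction between probes ``a`` and ``b``.

    ``a_given_b`` is (value, p) of the statistic with ``a`` as response
    (evidence that *a regulates b*), and symmetrically for ``b_given_a``.
    The more significant orientation wins; full ties fall to the
    lexicographically smaller probe as source. Returns (source, target).
    """
    va, pa = a_given_b
    vb, pb = b_given_a
    # the id tie-break compares the would-be source ids
    if (pa, -va, a) <= (pb, -vb, b):
        return a, b
    return b, a


def _make_edge(source: str, target: str, step: int, kind: str,
               fwd: DependenceResult, rev: DependenceResult
               ) -> RegulationEdge:
    """fwd has response == source, rev has response == target."""
    return RegulationEdge(source=source, target=target, step=step,
                          statistic_kind=kind, value=fwd.value,
                          p_value=fwd.p_value, forward_p=fwd.p_value,
                          reverse_p=rev.p_value, reverse_value=rev.value)


def _score_first_targets(t0: str, candidates: Sequence[str],
                         engine: CIDEngine, plan: PermutationPlan
                         ) -> dict[str, DependenceResult]:
    return {t: permutation_test(StatisticSpec("CID", t0, (t,)), engine, plan)
            for t in sorted(candidates)}


def select_first_target(t0: str, candidates: Sequence[str],
                        engine: CIDEngine, plan: PermutationPlan,
                        alpha: float = DEFAULT_ALPHA,
                        scores: Mapping[str, DependenceResult] | None = None,
                        orientable: set[str] | None = None
                        ) -> RegulationEdge | None:
    """Seed-pair identification; returns None when ``t0`` is discarded.

    Computes CID(t0|Ti) for every candidate; the winner has the smallest
    p-value (ties: largest CID, then smallest id). If even the winner is
    insignificant the source is discarded. The direction of the created
    edge compares CID(t0|T1) with CID(T1|t0); a winner outside
    ``orientable`` (i.e. a target-only probe) cannot become the edge
    source, so the reverse orientation is not tested.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if t0 in candidates:
        raise ValueError("t0 must not be among the candidates")
    if scores is None:
        scores = _score_first_targets(t0, candidates, engine, plan)
    t1, fwd = most_significant(scores)
    if fwd.p_value > alpha:
        logger.info("source %s discarded: best CID p=%.4f > alpha", t0,
                    fwd.p_value)
        return None
    if orientable is not None and t1 not in orientable:
        return RegulationEdge(source=t0, target=t1, step=0,
                              statistic_kind="CID", value=fwd.value,
                              p_value=fwd.p_value, forward_p=fwd.p_value,
                              reverse_p=float("nan"))
    rev = permutation_test(StatisticSpec("CID", t1, (t0,)), engine, plan)
    src, tgt = orient(t0, (fwd.value, fwd.p_value),
                      t1, (rev.value, rev.p_value))
    if src == t0:
        return _make_edge(t0, t1, 0, "CID", fwd, rev)
    return _make_edge(t1, t0, 0, "CID", rev, fwd)


def elongation_step(current: Sequence[str], candidates: Sequence[str],
                    engine: CIDEngine, plan: PermutationPlan,
                    alpha: float = DEFAULT_ALPHA,
                    allowed_sources: Iterable[str] | None = None,
                    orientable: set[str] | None = None
                    ) -> RegulationEdge | None:
    """One elongation run; returns None for "stop".

    For every eligible path member S and candidate T, evaluates
    pCID(S|T; current\\{S}); if the most significant value clears ``alpha``
    an edge is created between that S and T (oriented against
    pCID(T|S; current\\{S})) and T joins the path. In unsupervised mode
    every current node may serve as S; in supervised mode only the
    designated sources may.
    """
    if not current:
        raise ValueError("current node set is empty")
    if not candidates:
        return None
    allowed = (list(current) if allowed_sources is None
               else [s for s in current if s in set(allowed_sources)])
    scored: dict[tuple[str, str], DependenceResult] = {}
    for s in allowed:
        cond = tuple(t for t in current if t != s)
        for tj in sorted(candidates):
            spec = StatisticSpec("pCID", s, (tj,), cond)
            scored[(s, tj)] = permutation_test(spec, engine, plan)
    if not scored:
        return None
    (s, tj), fwd = most_significant(scored)
    if fwd.p_value > alpha:
        return None
    step = len(current) - 1
    if orientable is not None and tj not in orientable:
        return RegulationEdge(source=s, target=tj, step=step,
                              statistic_kind="pCID", value=fwd.value,
                              p_value=fwd.p_value, forward_p=fwd.p_value,
                              reverse_p=float("nan"))
    cond = tuple(t for t in current if t != s)
    rev = permutation_test(StatisticSpec("pCID", tj, (s,), cond), engine,
                           plan)
    src, tgt = orient(s, (fwd.value, fwd.p_value),
                      tj, (rev.value, rev.p_value))
    if src == s:
        return _make_edge(s, tj, step, "pCID", fwd, rev)
    return _make_edge(tj, s, step, "pCID", rev, fwd)


def build_subnetwork(t0: str, data: ExpressionMatrix | CIDEngine,
                     plan: PermutationPlan, alpha: float = DEFAULT_ALPHA,
                     role_table: RoleTable | None = None,
                     supervised_sources: Iterable[str] | None = None,
                     stop_on_target_only: bool = False,
                     prefilter: bool = False,
                     max_steps: int | None = None,
                     cfg: KernelConfig | None = None) -> DirectedNetwork:
    """Grow one sub-network from seed source ``t0``.

    Iterates :func:`select_first_target` then :func:`elongation_step`. With
    a role table, candidates are restricted to target-capable probes; with
    ``stop_on_target_only`` elongation halts once the newly added node is
    target-capable but not source-capable. ``prefilter`` drops candidates
    whose seed-step CID p-value exceeds ``alpha`` from later steps
    (a computational shortcut, off by default). ``supervised_sources``
    switches elongation to supervised mode.
    """
    engine = data if isinstance(data, CIDEngine) else CIDEngine(data, cfg)
    matrix = engine.matrix
    if role_table is not None and not role_table.source_capable(t0):
        raise ValueError(f"seed {t0!r} is not source-capable")
    candidates = [p for p in matrix.probe_ids if p != t0]
    if role_table is not None:
        candidates = [p for p in candidates if role_table.target_capable(p)]
    if not candidates:
        raise ValueError("no candidate targets for seed " + repr(t0))
    if max_steps is None:
        max_steps = matrix.G - 1
    orientable = (set(role_table.sources()) | {t0}
                  if role_table is not None else None)

    scores0 = _score_first_targets(t0, candidates, engine, plan)
    edge0 = select_first_target(t0, candidates, engine, plan, alpha,
                                scores=scores0, orientable=orientable)
    if edge0 is None:
        return DirectedNetwork(nodes=[t0], edges=[], origin=t0)
    if prefilter:
        candidates = [c for c in candidates
                      if scores0[c].p_value <= alpha]
    t1 = edge0.target if edge0.source == t0 else edge0.source
    current = [t0, t1]
    edges = [edge0]
    candidates = [c for c in candidates if c != t1]

    def _target_only(node: str) -> bool:
        return (role_table is not None
                and role_table.target_capable(node)
                and not role_table.source_capable(node))

    halted = stop_on_target_only and _target_only(t1)
    while (not halted and candidates and len(edges) < max_steps):
        edge = elongation_step(current, candidates, engine, plan, alpha,
                               allowed_sources=supervised_sources,
                               orientable=orientable)
        if edge is None:
            break
        new = edge.target if edge.target not in current else edge.source
        edges.append(edge)
        current.append(new)
        candidates = [c for c in candidates if c != new]
        if stop_on_target_only and _target_only(new):
            halted = True
    return DirectedNetwork(nodes=current, edges=edges, origin=t0)


# ---------------------------------------------------------------------------
# Assembly and summaries
# ---------------------------------------------------------------------------

def assemble(subnetworks: Iterable[DirectedNetwork]) -> DirectedNetwork:
    """Union of sub-networks into one network.

    Duplicate (source, target) edges keep the one with the smallest
    p-value; opposite-direction duplicates are both retained and flagged in
    the log. Probes not connected to any other probe are excluded.
    """
    best: dict[tuple[str, str], RegulationEdge] = {}
    for net in subnetworks:
        for e in net.edges:
            key = (e.source, e.target)
            if key not in best or e.p_value < best[key].p_value:
                best[key] = e
    for s, t in sorted(best):
        if (t, s) in best and s < t:
            logger.warning("conflicting directions retained for pair "
                           "%s -- %s", s, t)
    edges = [best[k] for k in sorted(best)]
    nodes = sorted({n for e in edges for n in (e.source, e.target)})
    return DirectedNetwork(nodes=nodes, edges=edges, origin="assembled")


def network_summaries(net: DirectedNetwork
                      ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-node degree table plus global diagnostics.

    Returns a DataFrame with ``in.degree``, ``out.degree``, ``total.degree``
    per node, and a dict with node/edge counts, the average total degree
    2|E|/|V|, and a power-law (scale-free) diagnostic: the least-squares
    slope of log(frequency) on log(total degree).
    """
    if not net.nodes or not net.edges:
        raise ValueError("empty network")
    g = net.to_networkx()
    rows = [(n, g.in_degree(n), g.out_degree(n),
             g.in_degree(n) + g.out_degree(n)) for n in sorted(g.nodes)]
    df = pd.DataFrame(rows, columns=["probe_id", "in.degree", "out.degree",
                                     "total.degree"]).set_index("probe_id")
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    summary: dict[str, float] = {
        "n_nodes": float(n_nodes),
        "n_edges": float(n_edges),
        "average_degree": 2.0 * n_edges / n_nodes,
    }
    counts = df["total.degree"].value_counts()
    counts = counts[counts.index > 0]
    if len(counts) >= 2:
        logd = np.log(counts.index.to_numpy(dtype=float))
        logf = np.log(counts.to_numpy(dtype=float))
        slope, intercept = np.polyfit(logd, logf, 1)
        pred = slope * logd + intercept
        ss_res = float(np.sum((logf - pred) ** 2))
        ss_tot = float(np.sum((logf - logf.mean()) ** 2))
        summary["powerlaw_slope"] = float(slope)
        summary["powerlaw_r2"] = (1.0 - ss_res / ss_tot if ss_tot > 0
                                  else float("nan"))
    else:
        summary["powerlaw_slope"] = float("nan")
        summary["powerlaw_r2"] = float("nan")
    return df, summary
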