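"""Statistical-parsimony ribotype networks.

Observed ribotypes become nodes; nodes are connected by single mutational
steps, with unobserved intermediates inserted on multi-step joins.  Pairs
are joined only up to a *connection limit*: the largest number of steps at
which a connection is still judged parsimonious with a stated probability
(conventionally 95%).  Divergent lineages therefore fall apart into
separate subnetworks — the signature used to tell apart parental rDNA
lineages co-occurring in a hybrid's pool.

Assembly follows minimum-spanning-network semantics: a pair at mutational
distance ``d`` is joined exactly when its endpoints are not already
connected using joins of distance ``< d`` (all tying pairs at a given
distance are joined), so the total number of single-step edges equals the
total path length of the minimum spanning network over the observed
ribotypes, truncated at the connection limit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .pooling import SamplePool

GAP_MODES = ("step", "exclude")


class Occurrence(NamedTuple):
    sample_id: str
    label: str
    count: int
    percent: Optional[int]
    status: Optional[str]


@dataclass(frozen=True)
class NetworkNode:
    """A network vertex: an observed ribotype or an inferred intermediate."""

    node_id: str
    kind: str  # "observed" | "inferred"
    sequence: Optional[str]  # None for inferred placeholders
    occurrences: tuple = ()

    def __post_init__(self):
        if self.kind not in ("observed", "inferred"):
            raise ValueError(f"unknown node kind {self.kind!r}")
        if self.kind == "observed" and not self.occurrences:
            raise ValueError("observed nodes need at least one occurrence")

    @property
    def total_count(self) -> int:
        return sum(o.count for o in self.occurrences)

    @property
    def max_percent(self) -> int:
        return max((o.percent or 0) for o in self.occurrences) if self.occurrences else 0


@dataclass(frozen=True)
class ParsimonyNetwork:
    """Built network: nodes, single-step edges, subnetwork partition."""

    nodes: dict  # node_id -> NetworkNode
    edges: tuple  # ((node_id, node_id), ...), each spanning exactly 1 step
    connection_limit: int
    subnetworks: tuple  # (frozenset of node_ids, ...) in stable order

    @property
    def total_steps(self) -> int:
        """Total path length: every edge spans one mutational step."""
        return len(self.edges)

    @property
    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def subnetwork_of(self, node_id: str) -> str:
        for i, comp in enumerate(self.subnetworks, start=1):
            if node_id in comp:
                return f"S{i}"
        raise KeyError(node_id)


# ---------------------------------------------------------------------------
# mutational distance


def mutational_steps(a: str, b: str, gap_mode: str = "step") -> int:
    """Number of mutational steps separating two sequences.

    Equal-length inputs: Hamming distance.  Unequal lengths: a global
    alignment under unit edit costs anchors the homologous regions, and
    steps are counted on it with unit substitution cost and each
    contiguous gap collapsed to one step (``gap_mode="step"``), mirroring
    common haplotype-network practice of treating an indel as a single
    event.  With ``gap_mode="exclude"`` the gapped columns are ignored
    and only substitutions are counted.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if gap_mode not in GAP_MODES:
        raise ValueError(f"gap_mode must be one of {GAP_MODES}")
    if len(a) == len(b):
        if a == b:
            return 0
        x = np.frombuffer(a.encode(), dtype=np.uint8)
        y = np.frombuffer(b.encode(), dtype=np.uint8)
        return int(np.count_nonzero(x != y))
    steps, subs = _align_steps(a, b)
    return subs if gap_mode == "exclude" else steps


def _align_steps(a: str, b: str) -> Tuple[int, int]:
    """Global alignment step count: (total steps, substitution steps).

    The alignment itself minimises the ordinary unit edit cost
    (substitution 1, each gapped position 1), which anchors homologous
    regions; mutational steps are then counted on that alignment with
    every contiguous gap collapsed to a single event.  Among co-optimal
    edit alignments the one with the fewest steps (then fewest
    substitutions) is taken, so the result is well defined and symmetric.
    """
    INF = (float("inf"),) * 3
    n, m = len(a), len(b)
    # lexicographic cost (edit, steps, subs); M = aligned column,
    # X = gap in b (consumes a), Y = gap in a (consumes b)
    prev = {s: [INF] * (m + 1) for s in "MXY"}
    prev["M"][0] = (0, 0, 0)
    for j in range(1, m + 1):
        prev["Y"][j] = (j, 1, 0)  # one gap spanning b[:j]
    for i in range(1, n + 1):
        cur = {s: [INF] * (m + 1) for s in "MXY"}
        cur["X"][0] = (i, 1, 0)
        for j in range(1, m + 1):
            e = 0 if a[i - 1] == b[j - 1] else 1
            de, ds, dk = min(prev["M"][j - 1], prev["X"][j - 1], prev["Y"][j - 1])
            cur["M"][j] = (de + e, ds + e, dk + e)
            px, pm, py = prev["X"][j], prev["M"][j], prev["Y"][j]
            cur["X"][j] = min(
                (px[0] + 1, px[1], px[2]),  # extend an open gap: no new step
                (pm[0] + 1, pm[1] + 1, pm[2]),
                (py[0] + 1, py[1] + 1, py[2]),
            )
            cx, cm, cy = cur["X"][j - 1], cur["M"][j - 1], cur["Y"][j - 1]
            cur["Y"][j] = min(
                (cy[0] + 1, cy[1], cy[2]),
                (cm[0] + 1, cm[1] + 1, cm[2]),
                (cx[0] + 1, cx[1] + 1, cx[2]),
            )
        prev = cur
    _, steps, subs = min(prev["M"][m], prev["X"][m], prev["Y"][m])
    return int(steps), int(subs)


# ---------------------------------------------------------------------------
# probability of parsimony and the connection limit


def parsimony_probability(steps: int, seq_length: int) -> float:
    """Probability that a ``steps``-step connection is parsimonious.

    Model: per-site substitutions are Poisson with mean ``lam`` under a
    Jukes-Cantor substitution process; two sequences of length ``m``
    showing ``j`` differing sites imply a per-site difference probability
    ``p = j/m``, inverted to ``lam = -3/4 ln(1 - 4p/3)``.  A connection is
    parsimonious when every differing site experienced exactly one
    substitution; conditioning on a site differing, that has probability
    ``lam e^{-lam} / p``, and the ``j`` sites are treated independently:

        P_j = (lam * exp(-lam) / p) ** j

    P decreases in ``j`` and, at fixed ``j``, increases with ``m`` (longer
    sequences make the same count of differences less likely to hide
    multiple hits).
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if steps == 0:
        return 1.0
    p = steps / seq_length
    if p >= 0.75:
        return 0.0
    lam = -0.75 * math.log1p(-4.0 * p / 3.0)
    per_site = lam * math.exp(-lam) / p
    return per_site**steps


def connection_limit(seq_length: int, confidence: float = 0.95) -> int:
    """Largest step count still parsimonious at the stated confidence.

    Deterministic in (sequence length, confidence) and monotone
    non-decreasing in length.  Single-step connections are always allowed
    (the floor is 1): as confidence approaches 1 the limit collapses to 1.
    """
    if seq_length < 50:
        raise ValueError("seq_length must be >= 50")
    if not 0.5 < confidence < 1.0:
        raise ValueError("confidence must lie in (0.5, 1)")
    j = 1
    while parsimony_probability(j + 1, seq_length) >= confidence:
        j += 1
    return j


# ---------------------------------------------------------------------------
# network assembly


class _UnionFind:
    def __init__(self, items: Iterable[int]):
        self.parent = {i: i for i in items}

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _collect_nodes(pools: Sequence[SamplePool]):
    occurrences: Dict[str, list] = {}
    for pool in pools:
        for r in pool.ribotypes:
            if r.sequence is None:
                raise ValueError(
                    f"pool {pool.sample_id!r} has sequence-free ribotypes; "
                    "networks need sequences"
                )
            if set(r.sequence) - set("ACGT"):
                raise ValueError(
                    f"ambiguity codes in {pool.sample_id!r}/{r.label or r.sequence[:12]}; "
                    "exclude them upstream"
                )
            occurrences.setdefault(r.sequence, []).append(
                Occurrence(pool.sample_id, r.label, r.count, r.percent, r.status)
            )
    seqs = sorted(
        occurrences,
        key=lambda s: (-sum(o.count for o in occurrences[s]), s),
    )
    nodes = [
        NetworkNode(
            node_id=f"H{i + 1}",
            kind="observed",
            sequence=s,
            occurrences=tuple(sorted(occurrences[s])),
        )
        for i, s in enumerate(seqs)
    ]
    return nodes


def build_network(
    pools: Sequence[SamplePool],
    confidence: float = 0.95,
    gap_mode: str = "step",
) -> ParsimonyNetwork:
    """Assemble the statistical-parsimony network over one set of pools.

    Nodes are unique sequences across all pools (occurrences aggregated),
    ordered by total read count then sequence, so identical inputs in any
    pool order yield identical node ids.  All 1-step pairs are connected
    first; then, for each distance ``d`` up to the connection limit, every
    pair at distance ``d`` whose endpoints are not yet connected by
    shorter joins is linked through a path of ``d - 1`` inferred
    intermediates.  Ties at a distance are processed highest-frequency
    node first (then by node id), which fixes inferred-node naming.
    """
    nodes = _collect_nodes(pools)
    if not nodes:
        return ParsimonyNetwork(nodes={}, edges=(), connection_limit=0, subnetworks=())
    lengths = sorted(len(n.sequence) for n in nodes)
    rep_length = lengths[len(lengths) // 2]
    limit = connection_limit(rep_length, confidence)

    k = len(nodes)
    dist = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            dist[i, j] = dist[j, i] = mutational_steps(
                nodes[i].sequence, nodes[j].sequence, gap_mode
            )

    node_map = {n.node_id: n for n in nodes}
    edges: list = []
    uf = _UnionFind(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if dist[i, j] == 1:
                edges.append((nodes[i].node_id, nodes[j].node_id))
                uf.union(i, j)
    for d in range(2, limit + 1):
        roots = {i: uf.find(i) for i in range(k)}  # frozen: joins of distance < d
        candidates = [
            (i, j)
            for i in range(k)
            for j in range(i + 1, k)
            if dist[i, j] == d and roots[i] != roots[j]
        ]
        candidates.sort(
            key=lambda ij: (
                -max(nodes[ij[0]].total_count, nodes[ij[1]].total_count),
                ij,
            )
        )
        for i, j in candidates:
            u, v = nodes[i].node_id, nodes[j].node_id
            chain = [u]
            for step in range(1, d):
                mid_id = f"{u}.{v}.m{step}"
                node_map[mid_id] = NetworkNode(
                    node_id=mid_id, kind="inferred", sequence=None
                )
                chain.append(mid_id)
            chain.append(v)
            edges.extend(zip(chain, chain[1:]))
        for i, j in candidates:
            uf.union(i, j)

    g = nx.Graph()
    g.add_nodes_from(node_map)
    g.add_edges_from(edges)
    order = {n.node_id: idx for idx, n in enumerate(nodes)}
    comps = sorted(
        (frozenset(c) for c in nx.connected_components(g)),
        key=lambda c: min(order.get(x, len(order)) for x in c),
    )
    return ParsimonyNetwork(
        nodes=node_map,
        edges=tuple(edges),
        connection_limit=limit,
        subnetworks=tuple(comps),
    )


class Membership(NamedTuple):
    assignments: dict  # (sample_id, label) -> subnetwork id
    summary: pd.DataFrame  # per-subnetwork node/occurrence/read counts


def subnetwork_membership(net: ParsimonyNetwork) -> Membership:
    """Assign every observed occurrence to its subnetwork and summarise."""
    assignments: dict = {}
    rows = []
    for i, comp in enumerate(net.subnetworks, start=1):
        sid = f"S{i}"
        n_obs = n_inf = n_occ = n_reads = 0
        for node_id in comp:
            node = net.nodes[node_id]
            if node.kind == "inferred":
                n_inf += 1
                continue
            n_obs += 1
            for occ in node.occurrences:
                assignments[(occ.sample_id, occ.label)] = sid
                n_occ += 1
                n_reads += occ.count
        rows.append(
            {
                "subnetwork": sid,
                "observed_nodes": n_obs,
                "inferred_nodes": n_inf,
                "occurrences": n_occ,
                "reads": n_reads,
            }
        )
    return Membership(assignments, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# export


def to_json_dict(net: ParsimonyNetwork) -> dict:
    return {
        "connection_limit": net.connection_limit,
        "nodes": [
            {
                "id": n.node_id,
                "kind": n.kind,
                "sequence": n.sequence,
                "subnetwork": net.subnetwork_of(n.node_id),
                "percent_radius": n.max_percent,
                "occurrences": [o._asdict() for o in n.occurrences],
            }
            for n in net.nodes.values()
        ],
        "edges": [{"source": u, "target": v, "step": 1} for u, v in net.edges],
    }


def write_json(net: ParsimonyNetwork, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        json.dump(to_json_dict(net), fh, indent=1)


def write_graphml(net: ParsimonyNetwork, path: Union[str, Path]) -> None:
    g = nx.Graph()
    for n in net.nodes.values():
        g.add_node(
            n.node_id,
            kind=n.kind,
            sequence=n.sequence or "",
            subnetwork=net.subnetwork_of(n.node_id),
            percent_radius=n.max_percent,
            occurrences=";".join(
                f"{o.sample_id}:{o.label}:{o.count}" for o in n.occurrences
            ),
        )
    for u, v in net.edges:
        g.add_edge(u, v, step=1)
    nx.write_graphml(g, str(path))
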