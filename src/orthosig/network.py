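"""Weighted PPI networks, protein sets and induced subnetworks.

A PPI network is an undirected graph G(V, E) whose nodes are protein
identifiers and whose edges carry a positive confidence weight.  A protein
set X subset of V induces a subgraph G[X] whose edges are exactly those of G
with both endpoints in X.  The induced subnetwork distinguishes its
*singletons* X0 (degree-0 nodes of G[X]) from the *background* B(X) = X \\ X0;
the background is the protein universe used downstream for enrichment and
for the retrieval index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PPINetwork:
    """Undirected weighted protein-protein interaction network.

    Wraps a :class:`networkx.Graph`; every edge has a positive ``weight``
    attribute, there are no self-loops, and edges are stored once.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]

    def __contains__(self, node: str) -> bool:
        return node in self.graph


@dataclass
class ProteinSet:
    """A labelled set of protein identifiers (e.g. an ortholog list)."""

    ids: set[str]
    label: str = ""

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class InducedSubnetwork:
    """Subgraph G[X] together with its singleton and background partitions."""

    graph: PPINetwork
    source: ProteinSet
    singletons: set[str] = field(init=False)
    background: set[str] = field(init=False)

    def __post_init__(self) -> None:
        g = self.graph.graph
        self.singletons = {v for v in g.nodes if g.degree(v) == 0}
        self.background = set(g.nodes) - self.singletons


def load_network(path: str | Path, min_weight: float | None = None) -> PPINetwork:
    """Read a whitespace-separated edge list ``protein_a protein_b weight``.

    ``#`` starts a comment.  Duplicate edges keep the maximum weight
    (conservative merge of redundant evidence); self-loops are dropped.  If
    ``min_weight`` is given, edges with weight strictly below it are removed
    and nodes left isolated by that filter are discarded.

    Raises
    ------
    ValueError
        On a malformed row (with its line number), or if the network is
        empty after filtering.
    """
    path = Path(path)
    g = nx.Graph()
    n_self_loops = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 'idA idB weight', got {raw!r}"
                )
            a, b, wtxt = parts
            try:
                w = float(wtxt)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric weight {wtxt!r}"
                ) from exc
            if w <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive weight {w}")
            if a == b:
                n_self_loops += 1
                continue
            if g.has_edge(a, b):
                g.edges[a, b]["weight"] = max(g.edges[a, b]["weight"], w)
            else:
                g.add_edge(a, b, weight=w)
    if n_self_loops:
        logger.info("dropped %d self-loop rows from %s", n_self_loops, path)
    if min_weight is not None:
        weak = [
            (a, b) for a, b, w in g.edges(data="weight") if w < min_weight
        ]
        g.remove_edges_from(weak)
        isolated = [v for v in g.nodes if g.degree(v) == 0]
        g.remove_nodes_from(isolated)
        logger.info(
            "min_weight=%s removed %d edges and %d isolated nodes",
            min_weight,
            len(weak),
            len(isolated),
        )
    if g.number_of_nodes() == 0:
        raise ValueError(f"{path}: network empty after loading/filtering")
    return PPINetwork(g)


def induce_subgraph(net: PPINetwork, x: ProteinSet) -> InducedSubnetwork:
    """Induce G[X]: nodes X intersected with V, edges of G internal to X.

    Identifiers absent from the network are ignored with a logged count
    (ortholog lists routinely contain proteins missing from the
    interactome).  Raises ``ValueError`` if the intersection is empty.
    """
    present = x.ids & net.nodes
    missing = len(x.ids) - len(present)
    if missing:
        logger.warning(
            "%d/%d ids of %r absent from the network; ignored",
            missing,
            len(x.ids),
            x.label,
        )
    if not present:
        raise ValueError(f"protein set {x.label!r} shares no node with the network")
    sub = nx.Graph()
    sub.add_nodes_from(present)
    sub.add_weighted_edges_from(
        (a, b, w)
        for a, b, w in net.graph.edges(data="weight")
        if a in present and b in present
    )
    return InducedSubnetwork(
        graph=PPINetwork(sub), source=ProteinSet(ids=present, label=x.label)
    )


def sample_random_set(net: PPINetwork, n: int, seed: int, label: str = "") -> ProteinSet:
    """Uniform sample of ``n`` distinct proteins from V (singletons eligible)."""
    if not 1 <= n <= net.n_nodes:
        raise ValueError(f"sample size {n} outside [1, {net.n_nodes}]")
    rng = np.random.default_rng(seed)
    universe = sorted(net.nodes)
    picked = rng.choice(len(universe), size=n, replace=False)
    return ProteinSet(
        ids={universe[i] for i in picked}, label=label or f"random-{seed}"
    )
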