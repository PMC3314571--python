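"""Synthetic fixtures with known ground truth.

Generates a self-contained miniature of the study inputs: a weighted
planted-partition protein network, a small rooted ontology DAG with one
marker term per community at level >= 4, community-correlated annotations,
a GO-slim list (the level-1 branch heads), an ortholog protein set covering
selected "signal" communities, and a wider reference annotation set for
verified/novel classification.

Two deliberate departures from a plain stochastic block model make the
planted orthology signal detectable and falsifiable:

* **Halo carriers.**  Each signal community gets a few extra proteins that
  carry its marker annotation but are excluded from the ortholog set.  They
  are wired into one shared clique (no edges to the communities), so no
  single function covers more than half of that cluster and it can never
  become a putative complex.  In the whole-network run these carriers are
  background proteins outside every complex, pinning rho(marker, V) below
  1 while the ortholog run still attains rho(marker, O) = 1 — exactly the
  differential the method is designed to detect.
* **A shrouded community.**  The last signal community is densely wired to
  a blob of unannotated "shroud" proteins that are excluded from the
  ortholog set.  In the whole network the community and its shroud form one
  cluster in which no function covers more than half of the members, so
  the global run yields no complex there (rho(marker, V) = 0); in the
  ortholog-induced subnetwork the community stands alone and is recovered
  cleanly.  This also plants *unique* predictions — protein/function pairs
  inferred by an ortholog-class complex but by no global complex — with
  both verified and novel cases under the reference annotation set.
* **Exact annotation coverage.**  Each community annotates a random subset
  of exactly round(coverage * size) proteins to its marker (rather than
  i.i.d. coin flips), so the ">half of the cluster" coherence criterion
  holds by construction and the ground truth is unambiguous.

Decoy terms are annotated to a random half of the community proteins,
excluding the shrouded community: decoys are negative controls for the
random and global filters, so their carriers must sit in regions whose
global complexes are intact (every carrier retrieved globally,
rho(decoy, V) = 1); a decoy with carriers hidden in the shroud would carry
a genuine differential signal by construction and cease to be a control.

All outputs are emitted in the real external formats (edge list, OBO 1.2,
GAF 2.1, plain term/protein lists) so every parser is exercised end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from orthosig.network import PPINetwork, ProteinSet
from orthosig.ontology import (
    AnnotationSet,
    EXPERIMENTAL_CODES,
    GoDag,
    REFERENCE_CODES,
)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults define the standard test conditions: 8 planted communities of
    10 proteins (p_in = 0.9, p_out = 0.02), 2 signal communities fully
    inside an ortholog set holding 30% of the community proteins, one
    marker term per community at DAG level 4, 90% marker coverage, two
    half-coverage decoy terms, and 3 halo carriers per signal community.
    """

    n_communities: int = 8
    community_size: int = 10
    p_in: float = 0.9
    p_out: float = 0.02
    weight_range: tuple[float, float] = (0.5, 1.0)
    n_signal_communities: int = 2
    dag_depth: int = 5
    markers_per_community: int = 1
    annotation_coverage: float = 0.9
    ortholog_fraction: float = 0.22
    n_decoys: int = 2
    decoy_coverage: float = 0.5
    halo_per_signal: int = 6
    shroud_size: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.p_in > self.p_out:
            raise ValueError("p_in must exceed p_out")
        if self.dag_depth < 5:
            raise ValueError("dag_depth must be >= 5 so markers can sit at level >= 4")
        if self.n_signal_communities > self.n_communities:
            raise ValueError("more signal communities than communities")

    # -- naming conventions --------------------------------------------------

    def community_proteins(self, c: int) -> list[str]:
        return [f"C{c}P{i:02d}" for i in range(self.community_size)]

    def halo_proteins(self, c: int) -> list[str]:
        return [f"HALO{c}X{i}" for i in range(self.halo_per_signal)]

    def all_halo_proteins(self) -> list[str]:
        out = [
            p
            for c in range(self.n_signal_communities)
            for p in self.halo_proteins(c)
        ]
        if self.n_signal_communities < 2 and self.halo_per_signal:
            # padding so no marker can cover more than half of the halo clique
            out += [f"HALOPADX{i}" for i in range(self.halo_per_signal)]
        return out

    @property
    def shrouded_community(self) -> int | None:
        """Signal community wired to the shroud blob (None if no shroud)."""
        if self.shroud_size == 0 or self.n_signal_communities == 0:
            return None
        return self.n_signal_communities - 1

    def shroud_proteins(self) -> list[str]:
        if self.shrouded_community is None:
            return []
        return [f"SHRD{i:02d}" for i in range(self.shroud_size)]


@dataclass
class GroundTruth:
    """What the fixture planted, for assertions and reports."""

    communities: dict[int, list[str]]
    signal_communities: list[int]
    markers: dict[int, list[str]]  # community -> marker terms
    decoys: list[str]
    slim: list[str]
    halo: list[str]
    shroud: list[str]
    shrouded_community: int | None
    ortholog_ids: list[str]

    @property
    def signal_markers(self) -> set[str]:
        return {m for c in self.signal_communities for m in self.markers[c]}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def make_network(spec: FixtureSpec) -> PPINetwork:
    """Planted-partition graph plus the halo clique, seeded and deterministic."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.weight_range
    g = nx.Graph()
    members = [
        p for c in range(spec.n_communities) for p in spec.community_proteins(c)
    ]
    g.add_nodes_from(members)
    community_of = {
        p: c
        for c in range(spec.n_communities)
        for p in spec.community_proteins(c)
    }
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            p = spec.p_in if community_of[a] == community_of[b] else spec.p_out
            if rng.random() < p:
                g.add_edge(a, b, weight=float(rng.uniform(lo, hi)))
    halo = spec.all_halo_proteins()
    for i, a in enumerate(halo):
        for b in halo[i + 1 :]:
            g.add_edge(a, b, weight=float(rng.uniform(lo, hi)))
    g.add_nodes_from(halo)
    shroud = spec.shroud_proteins()
    if shroud:
        anchor = spec.community_proteins(spec.shrouded_community)
        for i, a in enumerate(shroud):
            for b in shroud[i + 1 :] + anchor:
                if rng.random() < spec.p_in:
                    g.add_edge(a, b, weight=float(rng.uniform(lo, hi)))
        g.add_nodes_from(shroud)
    return PPINetwork(g)


def make_ontology_and_annotations(
    spec: FixtureSpec,
) -> tuple[GoDag, AnnotationSet, set[str], GroundTruth]:
    """Toy DAG, community-correlated annotations, slim list and ground truth.

    The DAG is one namespace rooted at GO:0000001 with one chain per
    community (branch head at level 1 = slim term, marker(s) at level
    ``dag_depth - 1`` >= 4) and one chain per decoy term.
    """
    counter = [1]

    def new_term() -> str:
        t = f"GO:{counter[0]:07d}"
        counter[0] += 1
        return t

    root = new_term()
    parents: dict[str, set[str]] = {root: set()}
    names = {root: "biological_process"}
    slim: list[str] = []
    markers: dict[int, list[str]] = {}

    def chain(label: str, length: int) -> list[str]:
        """Build root -> t1 -> ... -> t_length; return the chain (minus root)."""
        terms = []
        prev = root
        for lvl in range(1, length + 1):
            t = new_term()
            parents[t] = {prev}
            names[t] = f"{label} level {lvl}"
            terms.append(t)
            prev = t
        return terms

    marker_level = spec.dag_depth - 1
    for c in range(spec.n_communities):
        terms = chain(f"community {c} process", marker_level)
        slim.append(terms[0])
        community_markers = [terms[-1]]
        for extra in range(1, spec.markers_per_community):
            t = new_term()
            parents[t] = {terms[-2]}
            names[t] = f"community {c} process variant {extra}"
            community_markers.append(t)
        markers[c] = community_markers

    decoys: list[str] = []
    for d in range(spec.n_decoys):
        terms = chain(f"decoy process {d}", marker_level)
        slim.append(terms[0])
        decoys.append(terms[-1])

    namespace = {t: "biological_process" for t in parents}
    dag = GoDag(parents=parents, namespace=namespace, names=names)

    rng = np.random.default_rng(spec.seed + 1)
    direct: dict[str, set[str]] = {}

    def annotate(protein: str, term: str) -> None:
        direct.setdefault(protein, set()).add(term)

    communities = {
        c: spec.community_proteins(c) for c in range(spec.n_communities)
    }
    n_carriers = round(spec.annotation_coverage * spec.community_size)
    for c, proteins in communities.items():
        carriers = rng.choice(proteins, size=n_carriers, replace=False)
        for p in carriers:
            for m in markers[c]:
                annotate(str(p), m)

    decoy_pool = [
        p
        for c, ps in communities.items()
        if c != spec.shrouded_community
        for p in ps
    ]
    n_decoy_carriers = round(spec.decoy_coverage * len(decoy_pool))
    for d in decoys:
        carriers = rng.choice(decoy_pool, size=n_decoy_carriers, replace=False)
        for p in carriers:
            annotate(str(p), d)

    halo = spec.all_halo_proteins()
    for c in range(spec.n_signal_communities):
        for p in spec.halo_proteins(c):
            for m in markers[c]:
                annotate(p, m)

    ann = AnnotationSet.from_direct(direct, dag, EXPERIMENTAL_CODES)
    truth = GroundTruth(
        communities=communities,
        signal_communities=list(range(spec.n_signal_communities)),
        markers=markers,
        decoys=decoys,
        slim=slim,
        halo=halo,
        shroud=spec.shroud_proteins(),
        shrouded_community=spec.shrouded_community,
        ortholog_ids=[],
    )
    return dag, ann, set(slim), truth


def make_ortholog_set(
    spec: FixtureSpec, net: PPINetwork, truth: GroundTruth | None = None
) -> ProteinSet:
    """Signal communities in full, plus random scatter from the others.

    The set is sized to ``ortholog_fraction`` of |V|; halo and shroud
    proteins are never orthologs.
    """
    rng = np.random.default_rng(spec.seed + 2)
    signal = [
        p
        for c in range(spec.n_signal_communities)
        for p in spec.community_proteins(c)
    ]
    others = sorted(
        p
        for c in range(spec.n_signal_communities, spec.n_communities)
        for p in spec.community_proteins(c)
        if p in net.nodes
    )
    total = round(spec.ortholog_fraction * net.n_nodes)
    n_scatter = max(0, min(total - len(signal), len(others)))
    scatter = [str(p) for p in rng.choice(others, size=n_scatter, replace=False)]
    ids = set(signal) | set(scatter)
    ps = ProteinSet(ids=ids, label="synthetic-orthologs")
    if truth is not None:
        truth.ortholog_ids = sorted(ids)
    return ps


def make_reference_annotations(
    spec: FixtureSpec, dag: GoDag, ann: AnnotationSet, truth: GroundTruth
) -> AnnotationSet:
    """Reference set = experimental annotations + computational (IEA-style) ones.

    Half of each community's non-carrier proteins additionally receive the
    community marker "computationally", so complex-level predictions for
    them classify as verified while the other half stay novel.
    """
    direct = {p: set(ts) for p, ts in ann.direct.items()}
    rng = np.random.default_rng(spec.seed + 3)
    for c, proteins in truth.communities.items():
        non_carriers = sorted(
            p for p in proteins if not set(truth.markers[c]) & ann.direct.get(p, set())
        )
        n_extra = len(non_carriers) // 2
        if n_extra:
            extra = rng.choice(non_carriers, size=n_extra, replace=False)
            for p in extra:
                direct.setdefault(str(p), set()).update(truth.markers[c])
    return AnnotationSet.from_direct(direct, dag, REFERENCE_CODES)


def make_fixture(
    spec: FixtureSpec,
) -> tuple[PPINetwork, GoDag, AnnotationSet, set[str], ProteinSet, AnnotationSet, GroundTruth]:
    """Generate the full in-memory fixture bundle."""
    net = make_network(spec)
    dag, ann, slim, truth = make_ontology_and_annotations(spec)
    orthologs = make_ortholog_set(spec, net, truth)
    reference = make_reference_annotations(spec, dag, ann, truth)
    return net, dag, ann, slim, orthologs, reference, truth


# -- file emission (real external formats) ----------------------------------


def write_edge_list(net: PPINetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# protein_a\tprotein_b\tweight\n")
        for a, b, w in sorted(
            (min(a, b), max(a, b), w) for a, b, w in net.graph.edges(data="weight")
        ):
            fh.write(f"{a}\t{b}\t{w:.6f}\n")


def write_obo(dag: GoDag, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for t in sorted(dag.terms):
            fh.write("\n[Term]\n")
            fh.write(f"id: {t}\n")
            fh.write(f"name: {dag.names.get(t, t)}\n")
            fh.write(f"namespace: {dag.namespace[t]}\n")
            for alt, primary in sorted(dag.alt_ids.items()):
                if primary == t:
                    fh.write(f"alt_id: {alt}\n")
            for p in sorted(dag.parents[t]):
                fh.write(f"is_a: {p} ! {dag.names.get(p, p)}\n")


def write_gaf(
    ann: AnnotationSet, path: str | Path, evidence: str = "IDA"
) -> None:
    """Emit direct annotations as GAF 2.1 rows (one evidence code for all)."""
    with Path(path).open("w") as fh:
        fh.write("!gaf-version: 2.1\n")
        for p in sorted(ann.direct):
            for t in sorted(ann.direct[p]):
                cols = [
                    "SYN", p, p, "", t, "SYN_REF:0000001", evidence, "",
                    "P", "", "", "protein", "taxon:4932", "20101113", "SYN",
                    "", "",
                ]
                fh.write("\t".join(cols) + "\n")


def write_protein_list(ps: ProteinSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write(f"# {ps.label}\n")
        for p in sorted(ps.ids):
            fh.write(p + "\n")


def write_term_list(terms: set[str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in sorted(terms):
            fh.write(t + "\n")


def generate_fixture_files(outdir: str | Path, spec: FixtureSpec) -> dict[str, Path]:
    """Write the complete fixture to ``outdir`` in external formats.

    Returns the path map; also drops ``ground_truth.json`` for inspection.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, dag, ann, slim, orthologs, reference, truth = make_fixture(spec)
    paths = {
        "network": outdir / "network.tsv",
        "obo": outdir / "ontology.obo",
        "gaf": outdir / "annotations.gaf",
        "reference_gaf": outdir / "reference.gaf",
        "orthologs": outdir / "orthologs.txt",
        "slim": outdir / "slim.txt",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_edge_list(net, paths["network"])
    write_obo(dag, paths["obo"])
    write_gaf(ann, paths["gaf"])
    write_gaf(reference, paths["reference_gaf"], evidence="IEA")
    write_protein_list(orthologs, paths["orthologs"])
    write_term_list(slim, paths["slim"])
    paths["ground_truth"].write_text(truth.to_json() + "\n")
    return paths
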