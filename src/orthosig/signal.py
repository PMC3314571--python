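"""The retrieval-index statistic and the orthology-signal filters.

For a protein sample X with induced subnetwork G[X], background B(X)
(non-singleton nodes of G[X]) and putative-complex protein union S(X), the
*retrieval index* of a function f is

    rho(f, X) = |P(f, S(X))| / |P(f, B(X))|,    P(f, U) = U ∩ C(f),

where C(f) is the candidate set of f: all proteins with a whitelisted
annotation to f or to a descendant of f.  rho measures which fraction of
the sample's carriers of f is captured by the sample's complexes; it is
undefined (0/0) when B(X) holds no carrier.

A function f is *orthology-related* when its retrieval from the ortholog
sample O strictly exceeds both its retrieval from the whole network V and
the 95th-percentile retrieval over N random samples of size |O|:

    rho(f, O) > max{ rho(f, V), rho(f, R_95%) }.

An ortholog-class complex is orthology-related when its full annotation
set contains at least one orthology-related function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from orthosig.complexes import PutativeComplex, infer_complexes
from orthosig.config import PipelineParams
from orthosig.mcl import cluster_stats, filter_min_size, mcl_cluster
from orthosig.network import (
    InducedSubnetwork,
    PPINetwork,
    induce_subgraph,
    sample_random_set,
)
from orthosig.ontology import AnnotationSet, GoDag


@dataclass
class RetrievalRecord:
    """rho(f, X) for one function in one sample."""

    term: str
    sample_label: str
    numerator: int  # |P(f, S(X))|
    denominator: int  # |P(f, B(X))|

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> float | None:
        if not self.defined:
            return None
        return self.numerator / self.denominator


@dataclass
class NullDistribution:
    """Per-function retrieval values over the N random runs."""

    term: str
    values: list[float]
    percentile: float = 0.95

    @property
    def n_runs(self) -> int:
        return len(self.values)

    @property
    def threshold95(self) -> float:
        return percentile95(self.values, self.percentile)


@dataclass
class RandomRunSummary:
    """Table-1 style bookkeeping for one random run."""

    run_index: int
    seed: int
    n_clusters: int
    mean_cluster_size: float
    n_complexes: int
    mean_complex_size: float


@dataclass
class NullResult:
    distributions: dict[str, NullDistribution]
    run_summaries: list[RandomRunSummary]
    n_runs: int

    def threshold(self, term: str) -> float:
        """95th-percentile null retrieval of ``term`` (0 if never observed)."""
        d = self.distributions.get(term)
        return d.threshold95 if d is not None else 0.0


def percentile95(values: list[float], q: float = 0.95) -> float:
    """Upper q-quantile as an order statistic: the rank-ceil(q*N) element.

    The threshold is an actual sample value (no interpolation): sort
    ascending and take the 1-based rank ceil(q*N).
    """
    if not values:
        raise ValueError("percentile of an empty list")
    ordered = sorted(values)
    rank = max(1, math.ceil(q * len(ordered)))
    return ordered[rank - 1]


def complex_protein_union(complexes: list[PutativeComplex]) -> set[str]:
    """S(X): all proteins contained in the sample's putative complexes."""
    s: set[str] = set()
    for cx in complexes:
        s |= cx.proteins
    return s


def retrieval_index(
    f: str,
    sub: InducedSubnetwork,
    complexes: list[PutativeComplex],
    dag: GoDag,
    ann: AnnotationSet,
) -> RetrievalRecord:
    """rho(f, X) for the sample behind ``sub`` and its ``complexes``."""
    t = dag.resolve(f)
    cand = ann.candidates(t)
    s = complex_protein_union(complexes)
    return RetrievalRecord(
        term=t,
        sample_label=sub.source.label,
        numerator=len(s & cand),
        denominator=len(sub.background & cand),
    )


def retrieval_table(
    sub: InducedSubnetwork,
    complexes: list[PutativeComplex],
    dag: GoDag,
    ann: AnnotationSet,
    terms: set[str] | None = None,
) -> dict[str, RetrievalRecord]:
    """rho(f, X) for every ``terms`` entry (default: all terms carried by B(X)).

    Only defined records (denominator > 0) are returned when ``terms`` is
    None; explicitly requested terms are returned even when undefined.
    """
    s = complex_protein_union(complexes)
    bg = sub.background
    if terms is None:
        carried: set[str] = set()
        for p in bg:
            carried |= ann.propagated.get(p, set())
        terms_iter = carried
        keep_undefined = False
    else:
        terms_iter = {dag.resolve(t) for t in terms}
        keep_undefined = True
    out: dict[str, RetrievalRecord] = {}
    for t in terms_iter:
        cand = ann.candidates(t)
        rec = RetrievalRecord(
            term=t,
            sample_label=sub.source.label,
            numerator=len(s & cand),
            denominator=len(bg & cand),
        )
        if rec.defined or keep_undefined:
            out[t] = rec
    return out


def run_branch(
    net: PPINetwork,
    sample,
    dag: GoDag,
    ann: AnnotationSet,
    params: PipelineParams,
    label: str,
    population: set[str] | None = None,
):
    """Cluster one sample and infer its complexes: induce -> MCL -> filter -> infer.

    ``population`` is the enrichment universe for Fisher's test; by default
    the whole network node set V, held constant across the global, ortholog
    and random branches so cluster p-values are comparable between classes
    (the usual single "population set" of GO-enrichment tools).  The
    retrieval index keeps its own per-sample background B(X).

    Returns (subnetwork, raw ClusterSet, size-filtered ClusterSet, complexes).
    """
    sub = induce_subgraph(net, sample)
    cs = mcl_cluster(
        sub.graph,
        inflation=params.inflation,
        max_iters=params.mcl_max_iters,
        tol=params.mcl_tol,
        prune=params.mcl_prune,
        source_label=label,
    )
    kept = filter_min_size(cs, params.min_cluster_size)
    complexes = infer_complexes(
        kept,
        net.nodes if population is None else population,
        ann,
        dag,
        alpha=params.alpha,
        min_level=params.min_level,
    )
    return sub, cs, kept, complexes


def build_null(
    net: PPINetwork,
    n: int,
    dag: GoDag,
    ann: AnnotationSet,
    params: PipelineParams,
    n_runs: int | None = None,
    seed: int | None = None,
) -> NullResult:
    """Random-sampling null: N runs of the full per-sample pipeline.

    Run i samples ``n`` proteins with seed ``seed + i``, induces, clusters,
    infers complexes and records rho(f, R_i) for every function carried by
    that run's background.  A function absent from a run's defined records
    contributes rho = 0 for that run (absence of retrieval is zero
    retrieval), so every distribution holds exactly N values and the
    percentile threshold is never biased upward by dropped runs.
    """
    n_runs = params.n_runs if n_runs is None else n_runs
    seed = params.seed if seed is None else seed
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")

    per_run: list[dict[str, float]] = []
    summaries: list[RandomRunSummary] = []
    all_terms: set[str] = set()
    for i in range(n_runs):
        run_seed = seed + i
        sample = sample_random_set(net, n, seed=run_seed, label=f"R{i}")
        sub, cs, kept, complexes = run_branch(
            net, sample, dag, ann, params, label=f"R{i}"
        )
        recs = retrieval_table(sub, complexes, dag, ann)
        values = {t: r.value for t, r in recs.items()}
        per_run.append(values)
        all_terms |= values.keys()
        cstats = cluster_stats(kept)  # size-filtered, same convention as GC/OC rows
        sizes = [len(cx.proteins) for cx in complexes]
        summaries.append(
            RandomRunSummary(
                run_index=i,
                seed=run_seed,
                n_clusters=cstats.n_clusters,
                mean_cluster_size=cstats.mean_size,
                n_complexes=len(complexes),
                mean_complex_size=sum(sizes) / len(sizes) if sizes else 0.0,
            )
        )

    distributions = {
        t: NullDistribution(
            term=t,
            values=[run.get(t, 0.0) for run in per_run],
            percentile=params.percentile,
        )
        for t in sorted(all_terms)
    }
    return NullResult(
        distributions=distributions, run_summaries=summaries, n_runs=n_runs
    )


def orthology_related_functions(
    rho_o: dict[str, RetrievalRecord],
    rho_v: dict[str, RetrievalRecord],
    null: NullResult,
) -> set[str]:
    """Functions with rho(f,O) strictly above both comparators.

    Candidacy requires rho(f,O) to be defined (>= 1 carrier in B(O));
    rho(f,V) counts as 0 when undefined for the whole-network run, and a
    function never seen in any random run has null threshold 0.
    """
    related: set[str] = set()
    for f, rec in rho_o.items():
        if not rec.defined:
            continue
        v_rec = rho_v.get(f)
        v = v_rec.value if (v_rec is not None and v_rec.defined) else 0.0
        if rec.value > max(v, null.threshold(f)):
            related.add(f)
    return related


def orthology_related_complexes(
    complexes: list[PutativeComplex], related: set[str]
) -> list[PutativeComplex]:
    """Complexes whose full (filial + inherited) annotations meet ``related``."""
    return [cx for cx in complexes if cx.full_functions & related]


def _gc_prediction_map(gc: list[PutativeComplex]) -> dict[str, set[str]]:
    pred: dict[str, set[str]] = {}
    for cx in gc:
        for p in cx.proteins:
            pred.setdefault(p, set()).update(cx.filial_functions)
    return pred


def unique_prediction_pairs(
    cx: PutativeComplex, gc: list[PutativeComplex]
) -> set[tuple[str, str]]:
    """(protein, function) predictions of ``cx`` made by no global-class complex.

    A pair is unique when no GC complex containing that protein predicts
    that function for it.
    """
    gc_pred = _gc_prediction_map(gc)
    return {
        (p, f)
        for p in cx.proteins
        for f in cx.filial_functions
        if f not in gc_pred.get(p, set())
    }


def unique_complexes(
    oc: list[PutativeComplex], gc: list[PutativeComplex]
) -> list[PutativeComplex]:
    """OC complexes with at least one prediction pair not covered by GC."""
    gc_pred = _gc_prediction_map(gc)
    out = []
    for cx in oc:
        if any(
            f not in gc_pred.get(p, set())
            for p in cx.proteins
            for f in cx.filial_functions
        ):
            out.append(cx)
    return out


def classify_predictions(
    cx: PutativeComplex,
    reference: AnnotationSet,
    gc: list[PutativeComplex] = (),
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Split a complex's unique prediction pairs into verified and novel.

    A pair (p, f) is *verified* when the reference annotation set (built
    with a wider, experimental + computational, evidence whitelist) places
    f — via f itself or a descendant — in p's propagated annotations;
    otherwise it is *novel*.  A complex may hold both kinds at once.
    """
    pairs = unique_prediction_pairs(cx, list(gc))
    verified = {(p, f) for p, f in pairs if f in reference.propagated.get(p, set())}
    return verified, pairs - verified


def goslim_summarize(
    related: set[str], slim: set[str], dag: GoDag
) -> dict[str, set[str]]:
    """Roll related functions up to GO-slim terms.

    Each related function appears under every slim term among its
    ancestors-or-self; functions with no slim ancestor land in the
    ``"unslimmed"`` bucket.
    """
    slim_resolved = {dag.resolve(s) for s in slim}
    unknown = slim_resolved - dag.terms
    if unknown:
        raise KeyError(f"slim terms not in the ontology: {sorted(unknown)}")
    summary: dict[str, set[str]] = {}
    for f in related:
        heads = ({f} | dag.ancestors(f)) & slim_resolved
        if not heads:
            summary.setdefault("unslimmed", set()).add(f)
        for s in heads:
            summary.setdefault(s, set()).add(f)
    return summary
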