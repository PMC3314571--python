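"""From clusters to putative protein complexes.

A cluster is promoted to a *putative complex* when at least one GO term is
significantly coherent in it.  A term is significantly coherent when all
three criteria hold:

1. it is over-represented in the cluster at Bonferroni-corrected
   ``p < alpha`` (one-sided Fisher's exact test against the background
   protein universe the clusters were derived from);
2. strictly more than half of the cluster's proteins carry the annotation
   (true-path propagated);
3. the term sits at level >= 4 of its namespace hierarchy, so the
   prediction is specific enough to be informative.

The coherent terms are reduced to their *filial* frontier (no retained term
an ancestor of another); the complex additionally inherits every ancestor
of a filial term as its full annotation set, and each of its proteins —
including previously unannotated ones — is predicted to carry every filial
function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from orthosig.mcl import ClusterSet
from orthosig.ontology import AnnotationSet, GoDag


def fisher_exact_greater(k, cluster_size: int, K: int, N: int):
    """One-sided (over-representation) Fisher exact p-value.

    Probability of drawing >= ``k`` annotated proteins when sampling
    ``cluster_size`` proteins from a universe of ``N`` containing ``K``
    annotated ones, i.e. the upper hypergeometric tail at ``k``.  ``k`` may
    be an array (vectorised over the tail index).
    """
    karr = np.asarray(k)
    if not (cluster_size <= N and K <= N):
        raise ValueError(f"inconsistent 2x2 table: n={cluster_size} K={K} N={N}")
    if karr.min() < 0 or karr.max() > min(cluster_size, K):
        raise ValueError(f"count k={k} outside [0, min(n, K)]")
    p = hypergeom.sf(karr - 1, N, K, cluster_size)
    return float(p) if np.ndim(k) == 0 else p


@dataclass
class EnrichmentResult:
    term: str
    p_raw: float
    p_corrected: float
    k: int  # cluster proteins carrying the term (propagated)
    cluster_size: int
    K: int  # background proteins carrying the term
    N: int  # background size


@dataclass
class PutativeComplex:
    """A cluster with its coherent (filial) functions and inherited set."""

    proteins: set[str]
    filial_functions: set[str]
    full_functions: set[str]
    source_label: str = ""

    def __post_init__(self) -> None:
        if not self.filial_functions:
            raise ValueError("a putative complex needs >= 1 filial function")


def enrich(
    cluster: set[str],
    background: set[str],
    ann: AnnotationSet,
    dag: GoDag,
) -> list[EnrichmentResult]:
    """Per-term over-representation of a cluster against its background.

    Every term carried (propagated) by at least one cluster protein is
    tested; Bonferroni correction uses m = number of terms tested for this
    cluster (per-cluster correction).
    """
    if not cluster:
        raise ValueError("cannot enrich an empty cluster")
    if not cluster <= background:
        raise ValueError("cluster must be a subset of the background universe")
    N = len(background)
    n = len(cluster)

    cluster_counts: dict[str, int] = {}
    for p in cluster:
        for t in ann.propagated.get(p, ()):
            cluster_counts[t] = cluster_counts.get(t, 0) + 1
    bg_counts: dict[str, int] = {}
    for p in background:
        for t in ann.propagated.get(p, ()):
            bg_counts[t] = bg_counts.get(t, 0) + 1

    m = len(cluster_counts)
    results = []
    for t in sorted(cluster_counts):
        k = cluster_counts[t]
        K = bg_counts[t]
        p_raw = fisher_exact_greater(k, n, K, N)
        results.append(
            EnrichmentResult(
                term=t,
                p_raw=p_raw,
                p_corrected=min(1.0, m * p_raw),
                k=k,
                cluster_size=n,
                K=K,
                N=N,
            )
        )
    return results


def coherent_functions(
    cluster: set[str],
    results: list[EnrichmentResult],
    dag: GoDag,
    ann: AnnotationSet,
    alpha: float = 0.001,
    min_level: int = 4,
) -> set[str]:
    """Significantly coherent terms of a cluster, reduced to the filial frontier.

    All three criteria are strict as stated: corrected p strictly below
    ``alpha``, annotated count strictly greater than half the cluster, term
    level at least ``min_level``.
    """
    half = len(cluster) / 2
    kept = {
        r.term
        for r in results
        if r.p_corrected < alpha and r.k > half and dag.level(r.term) >= min_level
    }
    # filial frontier: drop any term that is an ancestor of another kept term
    return {t for t in kept if not (dag.descendants(t) & kept)}


def infer_complexes(
    cs: ClusterSet,
    background: set[str],
    ann: AnnotationSet,
    dag: GoDag,
    alpha: float = 0.001,
    min_level: int = 4,
) -> list[PutativeComplex]:
    """One putative complex per cluster with a non-empty coherent set.

    The full annotation set is the filial terms plus all their ancestors,
    namespace roots excluded.  Clusters with no coherent function yield no
    prediction and are dropped.
    """
    roots = set(dag.roots.values())
    complexes = []
    for cluster in cs.clusters:
        results = enrich(cluster, background, ann, dag)
        filial = coherent_functions(
            cluster, results, dag, ann, alpha=alpha, min_level=min_level
        )
        if not filial:
            continue
        full = set(filial)
        for t in filial:
            full |= dag.ancestors(t)
        full -= roots
        complexes.append(
            PutativeComplex(
                proteins=set(cluster),
                filial_functions=filial,
                full_functions=full,
                source_label=cs.source_label,
            )
        )
    return complexes


def predict_protein_functions(cx: PutativeComplex) -> dict[str, set[str]]:
    """Predict every filial function of the complex for each of its proteins.

    This is the mechanism by which previously unannotated proteins acquire
    a functional prediction: membership in the complex suffices.
    """
    return {p: set(cx.filial_functions) for p in cx.proteins}
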