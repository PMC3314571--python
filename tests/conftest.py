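"""Shared fixtures: toy ontologies, small networks, the synthetic study."""

from __future__ import annotations

import numpy as np
import pytest

from orthosig.network import PPINetwork, load_network
from orthosig.ontology import AnnotationSet, GoDag
from orthosig.synth import FixtureSpec, make_fixture


def write_edges(tmp_path, rows: str, name: str = "net.tsv"):
    p = tmp_path / name
    p.write_text(rows)
    return p


@pytest.fixture
def small_net(tmp_path) -> PPINetwork:
    """Path a-b-c plus isolated pair d-e."""
    p = write_edges(tmp_path, "a b 1.0\nb c 0.5\nd e 0.8\n")
    return load_network(p)


@pytest.fixture
def toy_dag() -> GoDag:
    """One namespace: root -> a -> b -> c -> d chain plus a diamond.

    ``dia`` has a 2-edge path (root->x->dia) and a 3-edge path
    (root->a->b2->dia), so its level is 3 (longest path).
    """
    parents = {
        "root": set(),
        "a": {"root"},
        "b": {"a"},
        "c": {"b"},
        "d": {"c"},
        "x": {"root"},
        "b2": {"a"},
        "dia": {"x", "b2"},
    }
    ns = {t: "biological_process" for t in parents}
    return GoDag(parents=parents, namespace=ns)


@pytest.fixture
def toy_ann(toy_dag) -> AnnotationSet:
    direct = {
        "p1": {"d"},
        "p2": {"c"},
        "p3": {"b"},
        "p4": {"dia"},
        "p5": {"x"},
    }
    return AnnotationSet.from_direct(direct, toy_dag)


@pytest.fixture(scope="session")
def default_fixture():
    """The standard synthetic study (seed 0), shared across tests."""
    return make_fixture(FixtureSpec(seed=0))


# -- independent dense MCL oracle -------------------------------------------


def dense_mcl_oracle(
    net: PPINetwork, inflation: float, max_iters: int = 200, tol: float = 1e-6
) -> set[frozenset[str]]:
    """Straightforward dense-matrix MCL, coded independently of the package.

    Same model (self-loop = max incident weight, column-stochastic,
    expansion/inflation to a fixed point) but dense numpy arithmetic, no
    pruning, and a direct attractor read-out with overlap merging.
    """
    order = sorted(net.nodes)
    n = len(order)
    idx = {v: i for i, v in enumerate(order)}
    a = np.zeros((n, n))
    for u, v, w in net.graph.edges(data="weight"):
        a[idx[u], idx[v]] = w
        a[idx[v], idx[u]] = w
    loops = a.max(axis=0)
    loops[loops == 0] = 1.0
    a[np.diag_indices(n)] = loops
    m = a / a.sum(axis=0)
    for _ in range(max_iters):
        prev = m
        m = m @ m
        m = m ** inflation
        m = m / m.sum(axis=0)
        if np.abs(m - prev).max() < tol:
            break

    eps = 1e-6
    attractors = [i for i in range(n) if m[i, i] > eps]
    # attractor systems: merge attractor rows sharing any member column
    systems: list[tuple[set[int], set[int]]] = []  # (rows, member columns)
    for i in attractors:
        members = set(np.flatnonzero(m[i] > eps).tolist())
        hit = [s for s in systems if s[1] & members]
        rows, cols = {i}, set(members)
        for s in hit:
            systems.remove(s)
            rows |= s[0]
            cols |= s[1]
        systems.append((rows, cols))
    clusters: list[set[str]] = [set() for _ in systems]
    for j in range(n):
        owners = [si for si, (_, cols) in enumerate(systems) if j in cols]
        if not owners:
            continue
        best = max(owners, key=lambda si: sum(m[i, j] for i in systems[si][0]))
        clusters[best].add(order[j])
    return {frozenset(c) for c in clusters if c}
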