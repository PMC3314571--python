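"""End-to-end orchestration and report generation.

The pipeline executes the five-step methodology: (1) take each ortholog
protein set O, (2) cluster the whole network (global class, GYC), the
subnetwork induced by O (ortholog class, OYC) and N subnetworks induced by
random samples of size |O| (random class, RYC), (3) infer putative
complexes and per-function retrieval indices for every branch, (4) select
functions whose ortholog-class retrieval strictly exceeds both the global
retrieval and the 95th-percentile random retrieval, and (5) report the
ortholog-class complexes carrying those functions, together with
unique/verified/novel prediction bookkeeping and a GO-slim roll-up.

Outputs are plain TSV tables plus a JSON report and a YAML manifest that
records every parameter and seed; identical configuration and seed
reproduce every output byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from orthosig.complexes import PutativeComplex
from orthosig.config import PipelineParams, RunConfig
from orthosig.mcl import ClusterSet, cluster_stats, write_clusters
from orthosig.network import (
    InducedSubnetwork,
    PPINetwork,
    ProteinSet,
    induce_subgraph,
    load_network,
)
from orthosig.ontology import (
    AnnotationSet,
    GoDag,
    REFERENCE_CODES,
    load_term_list,
    parse_gaf,
    parse_obo,
)
from orthosig.signal import (
    NullResult,
    RetrievalRecord,
    build_null,
    classify_predictions,
    orthology_related_complexes,
    orthology_related_functions,
    retrieval_table,
    run_branch,
    goslim_summarize,
    unique_complexes,
)

logger = logging.getLogger(__name__)


@dataclass
class BranchResult:
    """One clustering branch: sample -> clusters -> complexes."""

    label: str
    sub: InducedSubnetwork
    clusters: ClusterSet
    kept: ClusterSet
    complexes: list[PutativeComplex]


@dataclass
class OrthologAnalysis:
    """Everything derived from one ortholog set."""

    label: str
    n_orthologs: int
    branch: BranchResult
    null: NullResult
    rho_o: dict[str, RetrievalRecord]
    rho_v: dict[str, RetrievalRecord]
    related_functions: set[str]
    related_complexes: list[PutativeComplex]
    unique: list[PutativeComplex]
    verified: dict[int, set] = field(default_factory=dict)  # idx in unique
    novel: dict[int, set] = field(default_factory=dict)
    slim_summary: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class SignalReport:
    gc: BranchResult
    analyses: dict[str, OrthologAnalysis]
    config: dict


def _load_protein_list(path: Path, label: str) -> ProteinSet:
    ids: set[str] = set()
    with Path(path).open() as fh:
        for line in fh:
            p = line.split("#", 1)[0].strip()
            if p:
                ids.add(p)
    return ProteinSet(ids=ids, label=label)


def run_pipeline(cfg: RunConfig) -> SignalReport:
    """Execute the full analysis and write all report files to cfg.outdir."""
    cfg.validate()
    params = cfg.params
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net = load_network(cfg.network, min_weight=params.min_weight)
    dag = parse_obo(cfg.obo)
    ann = parse_gaf(cfg.gaf, dag, params.evidence_whitelist)
    slim = load_term_list(cfg.slim) if cfg.slim else None
    reference = (
        parse_gaf(cfg.reference_gaf, dag, REFERENCE_CODES)
        if cfg.reference_gaf
        else None
    )
    logger.info(
        "loaded network |V|=%d |E|=%d, ontology %d terms, %d annotated proteins",
        net.n_nodes,
        net.n_edges,
        len(dag.terms),
        len(ann.direct),
    )

    everything = ProteinSet(ids=net.nodes, label="V")
    gc_branch = BranchResult("GYC", *run_branch(net, everything, dag, ann, params, "GYC"))
    write_clusters(gc_branch.kept, outdir / "gyc.clusters.tsv")

    analyses: dict[str, OrthologAnalysis] = {}
    for idx, (label, path) in enumerate(sorted(cfg.ortholog_lists.items())):
        orthologs = _load_protein_list(path, label)
        oc_label = f"OYC-{label}"
        oc_branch = BranchResult(
            oc_label, *run_branch(net, orthologs, dag, ann, params, oc_label)
        )
        n = len(oc_branch.sub.source.ids)
        null_seed = params.seed + 100_000 * (idx + 1)
        null = build_null(net, n, dag, ann, params, seed=null_seed)

        rho_o = retrieval_table(oc_branch.sub, oc_branch.complexes, dag, ann)
        rho_v = retrieval_table(
            gc_branch.sub, gc_branch.complexes, dag, ann, terms=set(rho_o)
        )
        related = orthology_related_functions(rho_o, rho_v, null)
        related_cx = orthology_related_complexes(oc_branch.complexes, related)
        unique = unique_complexes(oc_branch.complexes, gc_branch.complexes)
        verified: dict[int, set] = {}
        novel: dict[int, set] = {}
        if reference is not None:
            for i, cx in enumerate(unique):
                v, nvl = classify_predictions(cx, reference, gc_branch.complexes)
                verified[i] = v
                novel[i] = nvl
        slim_summary = (
            goslim_summarize(related, slim, dag) if slim is not None else {}
        )
        analyses[label] = OrthologAnalysis(
            label=label,
            n_orthologs=n,
            branch=oc_branch,
            null=null,
            rho_o=rho_o,
            rho_v=rho_v,
            related_functions=related,
            related_complexes=related_cx,
            unique=unique,
            verified=verified,
            novel=novel,
            slim_summary=slim_summary,
        )

        subdir = outdir / label
        subdir.mkdir(exist_ok=True)
        write_clusters(oc_branch.kept, subdir / "oyc.clusters.tsv")
        _write_complexes(oc_branch.complexes, subdir / "complexes.tsv")
        _write_retrieval(analyses[label], dag, subdir / "retrieval.tsv")
        _write_related(analyses[label], dag, subdir / "related_functions.tsv")
        _write_slim(analyses[label], subdir / "slim_summary.tsv")

    report = SignalReport(gc=gc_branch, analyses=analyses, config=cfg.manifest())

    make_table1(report).to_csv(outdir / "table1.tsv", sep="\t", index=False)
    make_table2(report).to_csv(outdir / "table2.tsv", sep="\t", index=False)
    make_table5(report).to_csv(outdir / "table5.tsv", sep="\t", index=False)
    with (outdir / "manifest.yaml").open("w") as fh:
        yaml.safe_dump(report.config, fh, sort_keys=True)
    (outdir / "report.json").write_text(report_json(report))
    return report


# -- per-branch output files -------------------------------------------------


def _write_complexes(complexes: list[PutativeComplex], path: Path) -> None:
    with path.open("w") as fh:
        fh.write("complex\tsize\tfilial_functions\tproteins\n")
        for i, cx in enumerate(
            sorted(complexes, key=lambda c: sorted(c.proteins))
        ):
            fh.write(
                f"{i}\t{len(cx.proteins)}\t"
                f"{','.join(sorted(cx.filial_functions))}\t"
                f"{','.join(sorted(cx.proteins))}\n"
            )


def _write_retrieval(a: OrthologAnalysis, dag: GoDag, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("term\tnamespace\tlevel\trho_O\trho_V\trho_R95\n")
        for t in sorted(a.rho_o):
            rec = a.rho_o[t]
            v = a.rho_v.get(t)
            v_val = v.value if (v is not None and v.defined) else 0.0
            fh.write(
                f"{t}\t{dag.namespace.get(t, '')}\t{dag.level(t)}\t"
                f"{rec.value:.6f}\t{v_val:.6f}\t{a.null.threshold(t):.6f}\n"
            )


def _write_related(a: OrthologAnalysis, dag: GoDag, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("term\tname\tnamespace\tlevel\n")
        for t in sorted(a.related_functions):
            fh.write(
                f"{t}\t{dag.names.get(t, '')}\t"
                f"{dag.namespace.get(t, '')}\t{dag.level(t)}\n"
            )


def _write_slim(a: OrthologAnalysis, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("slim_term\trelated_functions\n")
        for s in sorted(a.slim_summary):
            fh.write(f"{s}\t{','.join(sorted(a.slim_summary[s]))}\n")


# -- tables ------------------------------------------------------------------


def format_ratio(numerator: float, denominator: float, decimals: int) -> str:
    """Percentage string ``numerator/denominator*100`` at fixed precision.

    Zero denominators give ``"0.0%"`` style output flagged with ``*``.
    """
    if denominator == 0:
        return f"{0:.{decimals}f}%*"
    return f"{100 * numerator / denominator:.{decimals}f}%"


def _mean_std(values: list[float]) -> str:
    s = pd.Series(values, dtype=float)
    return f"{s.mean():.2f} (±{s.std(ddof=1) if len(s) > 1 else 0:.2f})"


def make_table1(report: SignalReport) -> pd.DataFrame:
    """Cluster/complex counts, mean sizes and complex-per-cluster ratios.

    Random-class rows report means (± standard deviation) over the runs;
    ratios are always recomputed from the row's own count columns and
    printed at 1 decimal.
    """
    rows = []

    def branch_row(group: str, branch: BranchResult) -> dict:
        cstats = cluster_stats(branch.kept)
        sizes = [len(cx.proteins) for cx in branch.complexes]
        n_cx = len(branch.complexes)
        return {
            "group": group,
            "n_clusters": str(cstats.n_clusters),
            "mean_cluster_size": f"{cstats.mean_size:.2f}"
            + ("*" if cstats.empty else ""),
            "n_complexes": str(n_cx),
            "mean_complex_size": f"{(sum(sizes) / n_cx) if n_cx else 0:.2f}"
            + ("" if n_cx else "*"),
            "ratio": format_ratio(n_cx, cstats.n_clusters, 1),
        }

    rows.append(branch_row("GYC", report.gc))
    for label, a in sorted(report.analyses.items()):
        rows.append(branch_row(f"OYC-{label}", a.branch))
        rs = a.null.run_summaries
        # ratios follow from the printed (2-decimal) count columns
        mean_clusters = round(sum(r.n_clusters for r in rs) / len(rs), 2)
        mean_complexes = round(sum(r.n_complexes for r in rs) / len(rs), 2)
        rows.append(
            {
                "group": f"RYC-{label}",
                "n_clusters": _mean_std([r.n_clusters for r in rs]),
                "mean_cluster_size": _mean_std([r.mean_cluster_size for r in rs]),
                "n_complexes": _mean_std([r.n_complexes for r in rs]),
                "mean_complex_size": _mean_std([r.mean_complex_size for r in rs]),
                "ratio": format_ratio(mean_complexes, mean_clusters, 1),
            }
        )
    return pd.DataFrame(rows)


def _survivors(
    a: OrthologAnalysis, mode: str
) -> tuple[set[str], list[PutativeComplex]]:
    """Functions (and complexes carrying them) surviving one filter."""
    funcs: set[str] = set()
    for f, rec in a.rho_o.items():
        if not rec.defined:
            continue
        v = a.rho_v.get(f)
        v_val = v.value if (v is not None and v.defined) else 0.0
        r_val = a.null.threshold(f)
        bound = {"random": r_val, "global": v_val, "combined": max(v_val, r_val)}[mode]
        if rec.value > bound:
            funcs.add(f)
    complexes = [cx for cx in a.branch.complexes if cx.full_functions & funcs]
    return funcs, complexes


def eligible_functions(a: OrthologAnalysis) -> set[str]:
    """Functions of the ortholog-class complexes with a defined rho(f, O)."""
    carried: set[str] = set()
    for cx in a.branch.complexes:
        carried |= cx.full_functions
    return {f for f in carried if f in a.rho_o and a.rho_o[f].defined}


def make_table2(report: SignalReport) -> pd.DataFrame:
    """Complexes/functions surviving the random, global and combined filters.

    The function universe per ortholog set is the full annotation set of
    its complexes (filial + inherited), restricted to functions with a
    defined ortholog-class retrieval index.  Retention is the combined
    column over the total, at 2 decimals.
    """
    rows = []
    for label, a in sorted(report.analyses.items()):
        total_funcs = eligible_functions(a)
        total_cx = list(a.branch.complexes)

        cols: dict[str, tuple[int, int]] = {}
        for mode in ("random", "global", "combined"):
            funcs, cxs = _survivors(a, mode)
            funcs &= total_funcs
            cols[mode] = (len(cxs), len(funcs))
        for kind, i, total in (
            ("complexes", 0, len(total_cx)),
            ("functions", 1, len(total_funcs)),
        ):
            rows.append(
                {
                    "group": f"OYC-{label}",
                    "kind": kind,
                    "total": str(total),
                    "after_random": str(cols["random"][i]),
                    "after_global": str(cols["global"][i]),
                    "after_combined": str(cols["combined"][i]),
                    "retention": format_ratio(cols["combined"][i], total, 2),
                }
            )
    return pd.DataFrame(rows)


def make_table5(report: SignalReport) -> pd.DataFrame:
    """All/unique/verified/novel complex counts, split by orthology-relatedness."""
    rows = []
    for label, a in sorted(report.analyses.items()):
        related_ids = {id(cx) for cx in a.related_complexes}
        unique = a.unique
        with_verified = [
            cx for i, cx in enumerate(unique) if a.verified.get(i)
        ]
        with_novel = [cx for i, cx in enumerate(unique) if a.novel.get(i)]

        def count(cxs, related_only: bool) -> int:
            if related_only:
                return sum(1 for cx in cxs if id(cx) in related_ids)
            return len(cxs)

        has_ref = bool(a.verified) or bool(a.novel) or not unique
        for scope, related_only in (("all", False), ("orthology-related", True)):
            rows.append(
                {
                    "group": f"OYC-{label}",
                    "scope": scope,
                    "total": count(a.branch.complexes, related_only),
                    "unique": count(unique, related_only),
                    "verified": count(with_verified, related_only)
                    if has_ref
                    else "NA",
                    "novel": count(with_novel, related_only) if has_ref else "NA",
                }
            )
    return pd.DataFrame(rows)


# -- serialisation -----------------------------------------------------------


def report_json(report: SignalReport) -> str:
    """Deterministic JSON summary of a run (counts, terms, complexes)."""

    def cx_obj(cx: PutativeComplex) -> dict:
        return {
            "proteins": sorted(cx.proteins),
            "filial_functions": sorted(cx.filial_functions),
            "full_functions": sorted(cx.full_functions),
        }

    # the output directory is where the file lives; keeping it out of the
    # payload lets identical runs in different directories compare equal
    config = {k: v for k, v in report.config.items() if k != "outdir"}
    payload = {
        "config": config,
        "gc": {
            "n_clusters": len(report.gc.kept),
            "n_complexes": len(report.gc.complexes),
            "complexes": [
                cx_obj(cx)
                for cx in sorted(
                    report.gc.complexes, key=lambda c: sorted(c.proteins)
                )
            ],
        },
        "analyses": {},
    }
    for label, a in sorted(report.analyses.items()):
        payload["analyses"][label] = {
            "n_orthologs": a.n_orthologs,
            "n_clusters": len(a.branch.kept),
            "n_complexes": len(a.branch.complexes),
            "n_null_runs": a.null.n_runs,
            "related_functions": sorted(a.related_functions),
            "n_related_complexes": len(a.related_complexes),
            "n_unique_complexes": len(a.unique),
            "n_verified_complexes": sum(1 for v in a.verified.values() if v),
            "n_novel_complexes": sum(1 for v in a.novel.values() if v),
            "complexes": [
                cx_obj(cx)
                for cx in sorted(
                    a.branch.complexes, key=lambda c: sorted(c.proteins)
                )
            ],
            "slim_summary": {
                s: sorted(fs) for s, fs in sorted(a.slim_summary.items())
            },
        }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"
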