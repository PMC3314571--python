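"""Run configuration: pipeline parameters and input paths."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from orthosig.ontology import EXPERIMENTAL_CODES


@dataclass
class PipelineParams:
    """Tunable parameters of the full analysis.

    Defaults are the settings used throughout: MCL inflation 1.8, clusters
    of size >= 3, coherence at Bonferroni-corrected p < 0.001 with term
    level >= 4, and a 1000-run random-sampling null summarised at its 95th
    percentile.
    """

    min_weight: float | None = None
    inflation: float = 1.8
    mcl_max_iters: int = 100
    mcl_tol: float = 1e-6
    mcl_prune: float = 1e-8
    min_cluster_size: int = 3
    alpha: float = 0.001
    min_level: int = 4
    n_runs: int = 1000
    percentile: float = 0.95
    evidence_whitelist: frozenset[str] = EXPERIMENTAL_CODES
    seed: int = 0

    def validate(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.percentile <= 1:
            raise ValueError("percentile must lie in (0, 1]")
        if self.min_cluster_size < 1 or self.min_level < 0 or self.n_runs < 1:
            raise ValueError("min_cluster_size/min_level/n_runs out of range")


@dataclass
class RunConfig:
    """Paths and parameters for one end-to-end pipeline run."""

    network: Path
    obo: Path
    gaf: Path
    ortholog_lists: dict[str, Path]  # label -> path
    outdir: Path
    slim: Path | None = None
    reference_gaf: Path | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    def validate(self) -> None:
        self.params.validate()
        paths = [self.network, self.obo, self.gaf, *self.ortholog_lists.values()]
        if self.slim is not None:
            paths.append(self.slim)
        if self.reference_gaf is not None:
            paths.append(self.reference_gaf)
        for p in paths:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        if not self.ortholog_lists:
            raise ValueError("at least one ortholog list is required")

    @classmethod
    def from_yaml(cls, path: str | Path, outdir: str | Path | None = None) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p):
            return (base / p).resolve() if p is not None else None

        pp = raw.get("params", {})
        if "evidence_whitelist" in pp:
            pp["evidence_whitelist"] = frozenset(pp["evidence_whitelist"])
        if "min_weight" in pp and pp["min_weight"] is not None:
            pp["min_weight"] = float(pp["min_weight"])
        params = PipelineParams(**pp)
        return cls(
            network=resolve(raw["network"]),
            obo=resolve(raw["obo"]),
            gaf=resolve(raw["gaf"]),
            ortholog_lists={
                label: resolve(p) for label, p in raw["ortholog_lists"].items()
            },
            slim=resolve(raw.get("slim")),
            reference_gaf=resolve(raw.get("reference_gaf")),
            outdir=Path(outdir) if outdir is not None else resolve(raw.get("outdir", "orthosig-out")),
            params=params,
        )

    def manifest(self) -> dict:
        d = {
            "network": str(self.network),
            "obo": str(self.obo),
            "gaf": str(self.gaf),
            "ortholog_lists": {k: str(v) for k, v in self.ortholog_lists.items()},
            "slim": str(self.slim) if self.slim else None,
            "reference_gaf": str(self.reference_gaf) if self.reference_gaf else None,
            "outdir": str(self.outdir),
            "params": asdict(self.params),
        }
        d["params"]["evidence_whitelist"] = sorted(self.params.evidence_whitelist)
        return d
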