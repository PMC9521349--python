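"""End-to-end orchestration: filter → binarize → landscape → screen →
neighbors → exact structure search → CPT fit → relative-risk report.

Every stage writes a self-describing delimited file into the output
directory, and a JSON manifest records the configuration, per-stage counts
and wall-clock times.  Two runs with the same configuration and seed
produce byte-identical result tables.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .cohort import (
    CohortError,
    Dialect,
    MutationMatrix,
    binarize,
    filter_pathogenic,
    landscape,
    read_alteration_table,
)
from .association import screen, write_association_tsv
from .inference import fit_cpts, relative_risk, write_rr_tsv
from .structure import (
    approximate_neighbors,
    exact_search,
    local_scores,
    to_dot,
    to_graphml,
)
from .synthetic import PlantedModel, default_cohort_model, sample_cohort

DEFAULT_ANCHORS = ("BRCA1", "BRCA2")

#: Default multi-gene RR queries: (anchor, condition genes).
DEFAULT_MULTI_QUERIES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("BRCA1", ("NOTCH1",)),
    ("BRCA1", ("NOTCH1", "ARID1A", "MTOR")),
)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit status 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit status 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Configuration of a full analysis run."""

    input_path: str
    output_dir: str
    input_kind: str = "matrix"  # "matrix" or "records"
    anchors: tuple[str, ...] = DEFAULT_ANCHORS
    alpha: float = 0.05
    landscape_min_freq: float = 0.05
    screen_min_freq: float = 0.0
    neighbor_k: int = 15
    score: str = "bdeu"
    ess: float = 1.0
    max_parents: int = 4
    pseudo_count: float = 0.1
    seed: int = 0
    cohort: str = "all"  # "all" or "brca-positive"
    rr_direction: str = "anchor_given_genes"
    multi_queries: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_MULTI_QUERIES
    csv: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0.0 <= self.landscape_min_freq < 1.0:
            raise ConfigError("landscape_min_freq must lie in [0, 1)")
        if self.neighbor_k < 1:
            raise ConfigError("neighbor_k must be ≥ 1")
        if self.input_kind not in {"matrix", "records"}:
            raise ConfigError(f"unknown input_kind {self.input_kind!r}")
        if self.cohort not in {"all", "brca-positive"}:
            raise ConfigError(f"unknown cohort option {self.cohort!r}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ConfigError(f"config {path} is not a mapping")
        if "anchors" in payload:
            payload["anchors"] = tuple(payload["anchors"])
        if "multi_queries" in payload:
            payload["multi_queries"] = tuple(
                (q["anchor"], tuple(q["condition"])) for q in payload["multi_queries"]
            )
        try:
            return cls(**payload)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict = field(default_factory=dict)
    seed: int = 0

    def record(self, stage: str, seconds: float, **counts) -> None:
        self.stages[stage] = {"seconds": round(seconds, 4), **counts}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def _log_stage(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def load_cohort(config: PipelineConfig) -> MutationMatrix:
    """Read the input as a matrix or as records (filter + binarize)."""
    sep = "," if config.csv else "\t"
    if config.input_kind == "matrix":
        matrix = MutationMatrix.from_tsv(config.input_path)
    else:
        records = read_alteration_table(config.input_path, Dialect(sep=sep))
        matrix = binarize(filter_pathogenic(records))
    return matrix


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run the full analysis; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={**asdict(config)}, version=__version__, seed=config.seed
    )

    def stage(name: str):
        class _Timer:
            def __enter__(self):
                self.start = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                self.seconds = time.perf_counter() - self.start
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Timer()

    with stage("load") as t:
        matrix = load_cohort(config)
        for anchor in config.anchors:
            if anchor not in matrix.genes:
                raise CohortError(f"anchor gene {anchor!r} absent from the panel")
        if config.cohort == "brca-positive":
            mask = np.zeros(matrix.n_patients, dtype=bool)
            for anchor in config.anchors:
                mask |= matrix.column(anchor)
            matrix = matrix.restrict_patients(mask)
        matrix.to_tsv(out / "cohort_matrix.tsv")
    manifest.record("load", t.seconds, patients=matrix.n_patients, genes=len(matrix.genes))
    _log_stage("load", f"{matrix.n_patients} patients × {len(matrix.genes)} genes")

    with stage("landscape") as t:
        summary = landscape(matrix, config.landscape_min_freq)
        summary.to_tsv(out / "landscape.tsv")
    manifest.record("landscape", t.seconds, retained=len(summary.retained_genes))
    _log_stage("landscape", f"{len(summary.retained_genes)} genes ≥ {config.landscape_min_freq:.0%}")

    significant: dict[str, list[str]] = {}
    with stage("screen") as t:
        for anchor in config.anchors:
            candidates = [
                g
                for g in matrix.genes
                if g not in config.anchors
                and summary.frequencies[g] >= config.screen_min_freq
            ]
            results = screen(matrix, anchor, candidates, alpha=config.alpha)
            write_association_tsv(results, out / f"assoc_{anchor}.tsv")
            significant[anchor] = [r.gene for r in results if r.significant]
    manifest.record(
        "screen",
        t.seconds,
        **{f"significant_{a}": len(significant[a]) for a in config.anchors},
    )
    for anchor in config.anchors:
        _log_stage("screen", f"{anchor}: {len(significant[anchor])} significant genes")

    with stage("neighbors") as t:
        neighbors = approximate_neighbors(
            matrix,
            list(config.anchors),
            k=config.neighbor_k,
            score=config.score,
            ess=config.ess,
            max_parents=config.max_parents,
            seed=config.seed,
        )
        (out / "neighbors.txt").write_text("\n".join(neighbors) + "\n")
    manifest.record("neighbors", t.seconds, neighbors=len(neighbors))
    _log_stage("neighbors", f"{len(neighbors)} candidate genes")

    with stage("learn") as t:
        nodes = sorted(set(config.anchors) | set(neighbors))
        table = local_scores(
            matrix,
            nodes,
            score=config.score,
            ess=config.ess,
            max_parents=config.max_parents,
        )
        table.to_tsv(out / "local_scores.tsv")
        result = exact_search(table)
        freqs = {g: summary.frequencies[g] for g in nodes}
        (out / "network.dot").write_text(to_dot(result.dag, freqs))
        to_graphml(result.dag, out / "network.graphml", freqs)
    manifest.record(
        "learn", t.seconds, nodes=len(nodes), edges=len(result.dag.edges()),
        total_score=result.total_score, expansions=result.expansions,
    )
    _log_stage("learn", f"{len(nodes)} nodes, {len(result.dag.edges())} edges, score {result.total_score:.3f}")

    with stage("fit") as t:
        cpts = fit_cpts(matrix, result.dag, pseudo_count=config.pseudo_count)
        cpts.to_tsv(out / "cpts.tsv")
    manifest.record("fit", t.seconds)

    with stage("infer") as t:
        estimates = []
        for anchor in config.anchors:
            for gene in result.dag.nodes:
                if gene in config.anchors:
                    continue
                estimates.append(
                    relative_risk(
                        result.dag, cpts, anchor, [gene], direction=config.rr_direction
                    )
                )
        if len(config.anchors) >= 2:
            estimates.append(
                relative_risk(
                    result.dag,
                    cpts,
                    config.anchors[1],
                    [config.anchors[0]],
                    direction=config.rr_direction,
                )
            )
        answered = {(e.anchor, e.condition, e.direction) for e in estimates}
        for anchor, condition in config.multi_queries:
            key = (anchor, frozenset(condition), config.rr_direction)
            if key in answered:
                continue
            if anchor in result.dag.nodes and set(condition) <= set(result.dag.nodes):
                estimates.append(
                    relative_risk(
                        result.dag, cpts, anchor, condition,
                        direction=config.rr_direction,
                    )
                )
        write_rr_tsv(estimates, out / "rr_report.tsv")
    manifest.record("infer", t.seconds, queries=len(estimates))
    _log_stage("infer", f"{len(estimates)} relative-risk queries")

    manifest.write(out / "manifest.json")
    return manifest


def simulate(
    model: PlantedModel | None,
    seed: int,
    output_dir: str | Path,
    n_patients: int | None = None,
) -> Path:
    """Sample a synthetic cohort and write matrix + ground-truth sidecar."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if model is None:
        model = default_cohort_model(seed=seed, n_patients=n_patients or 7707)
    elif n_patients is not None:
        model = PlantedModel(
            genes=model.genes,
            parents=model.parents,
            cpts=model.cpts,
            n_patients=n_patients,
            seed=seed,
        )
    realization = sample_cohort(model, seed=seed)
    realization.matrix.to_tsv(out / "cohort_matrix.tsv")
    model.to_yaml(out / "model.yaml")
    sidecar = {
        f"{anchor}|{','.join(sorted(condition))}": value
        for (anchor, condition), value in realization.true_rr.items()
    }
    (out / "true_rr.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return out / "cohort_matrix.tsv"


def render_report(run_dir: str | Path) -> str:
    """One-page text summary of a completed run directory.

    Missing stage files are listed as absent rather than raising.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise ConfigError(f"no manifest.json in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    lines = [
        "cosegnet run summary",
        "====================",
        f"version: {manifest.get('version')}   seed: {manifest.get('seed')}",
    ]
    import pandas as pd

    load_info = manifest.get("stages", {}).get("load", {})
    lines.append(
        f"cohort: {load_info.get('patients', '?')} patients × "
        f"{load_info.get('genes', '?')} genes"
    )
    anchors = manifest.get("config", {}).get("anchors", [])

    landscape_path = run_dir / "landscape.tsv"
    if landscape_path.exists():
        table = pd.read_csv(landscape_path, sep="\t")
        for anchor in anchors:
            row = table.loc[table["gene"] == anchor]
            if len(row):
                lines.append(
                    f"prevalence {anchor}: {float(row['frequency'].iloc[0]):.4f}"
                )
    else:
        lines.append("landscape.tsv: absent")

    for anchor in anchors:
        path = run_dir / f"assoc_{anchor}.tsv"
        if not path.exists():
            lines.append(f"assoc_{anchor}.tsv: absent")
            continue
        table = pd.read_csv(path, sep="\t")
        hits = table.loc[table["significant"] == 1, "gene"].tolist()
        lines.append(
            f"significant vs {anchor}: "
            + (", ".join(hits) if hits else "none")
        )

    network_path = run_dir / "network.dot"
    if network_path.exists():
        edges = [
            line.strip().rstrip(";")
            for line in network_path.read_text().splitlines()
            if "->" in line
        ]
        lines.append(f"network edges ({len(edges)}):")
        lines.extend(f"  {e}" for e in edges)
    else:
        lines.append("network.dot: absent")

    rr_path = run_dir / "rr_report.tsv"
    if rr_path.exists():
        table = pd.read_csv(rr_path, sep="\t")
        table = table.sort_values("rr", ascending=False)
        lines.append("top relative risks:")
        for _, row in table.head(8).iterrows():
            lines.append(
                f"  {row['anchor']} | {row['condition']} "
                f"({row['direction']}): RR = {row['rr']:.3f}"
            )
    else:
        lines.append("rr_report.tsv: absent")
    return "\n".join(lines) + "\n"
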