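"""End-to-end orchestration: files in, modules and validity metrics out.

The pipeline chains the four stages — distance modelling, shortest-path
sequencing, tour segmentation, and GO-guided post-processing — and, when an
output directory is configured, writes stage-by-stage module dumps, the
final module table, a JSON metrics report, and a run manifest (every
parameter, the seed, and SHA-256 checksums of the inputs) sufficient to
reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .distance import DistanceMatrix, cd_distance_matrix
from .graph_io import (
    GOAnnotationMap,
    PPINGraph,
    read_edge_list,
    read_go_annotations,
    write_modules,
)
from .metrics import EvaluationResult, evaluate
from .modules import (
    ModuleSet,
    PostprocessParams,
    filter_by_density,
    merge_by_function,
    segment_tour,
)
from .tour import LKParams, Tour, lk_improve, nn_initial_tour

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "validate_config",
    "detect_modules",
    "run_pipeline",
]


class PipelineStageError(RuntimeError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed to run and reproduce one pipeline invocation."""

    edges: str | Path
    edges_dialect: str = "tsv"
    go: str | Path | None = None
    go_dialect: str = "tsv"
    lk: LKParams = field(default_factory=LKParams)
    post: PostprocessParams = field(default_factory=PostprocessParams)
    outdir: str | Path | None = None
    log_level: str = "INFO"


def validate_config(config: PipelineConfig) -> None:
    if not Path(config.edges).is_file():
        raise FileNotFoundError(f"edge list not found: {config.edges}")
    if config.go is not None and not Path(config.go).is_file():
        raise FileNotFoundError(f"annotation file not found: {config.go}")
    if config.edges_dialect not in ("tsv", "mitab"):
        raise ValueError(f"unknown edges dialect {config.edges_dialect!r}")
    if config.go_dialect not in ("tsv", "gaf"):
        raise ValueError(f"unknown GO dialect {config.go_dialect!r}")


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc
        logger.info("stage %-12s done in %.3f s", name, time.perf_counter() - t0)
        return out

    return wrap


def detect_modules(
    graph: PPINGraph,
    go: GOAnnotationMap | None = None,
    lk: LKParams | None = None,
    post: PostprocessParams | None = None,
) -> tuple[ModuleSet, dict[str, object]]:
    """Run the in-memory pipeline on an already-loaded graph.

    Returns the final module set and a dict of intermediate artifacts
    (``distance``, ``tour``, ``segments``, ``merged``) for inspection.
    """
    go = go or GOAnnotationMap()
    lk = lk or LKParams()
    post = post or PostprocessParams()
    dist = _stage("distance")(cd_distance_matrix, graph)
    tour0 = _stage("nn_tour")(nn_initial_tour, dist)
    tour = _stage("lk_improve")(lk_improve, tour0, dist, lk)
    segments = _stage("segment")(segment_tour, tour, dist, post.cut_threshold)
    merged = _stage("merge")(merge_by_function, segments, go, post.merge_threshold)
    final = _stage("filter")(
        filter_by_density, merged, graph, post.density_min, post.keep_singletons
    )
    logger.info(
        "modules: %d segments -> %d merged -> %d final (+%d unassigned)",
        len(segments),
        len(merged),
        len(final),
        len(final.unassigned),
    )
    return final, {
        "distance": dist,
        "initial_tour": tour0,
        "tour": tour,
        "segments": segments,
        "merged": merged,
    }


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> tuple[ModuleSet, EvaluationResult]:
    """Run the full file-to-file pipeline described by ``config``."""
    validate_config(config)
    graph = _stage("read_edges")(read_edge_list, config.edges, config.edges_dialect)
    go = (
        _stage("read_go")(read_go_annotations, config.go, config.go_dialect)
        if config.go is not None
        else GOAnnotationMap()
    )
    final, artifacts = detect_modules(graph, go, config.lk, config.post)
    result = _stage("evaluate")(evaluate, final, go, artifacts["distance"])

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tour: Tour = artifacts["tour"]  # type: ignore[assignment]
        dist: DistanceMatrix = artifacts["distance"]  # type: ignore[assignment]
        tour.to_tsv(outdir / "tour.tsv", dist)
        write_modules(artifacts["segments"], outdir / "modules_segments.tsv")
        write_modules(artifacts["merged"], outdir / "modules_merged.tsv")
        write_modules(final, outdir / "modules_final.tsv")
        (outdir / "metrics.json").write_text(
            json.dumps(result.to_dict(), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )
        manifest = {
            "edges": str(config.edges),
            "edges_sha256": _sha256(config.edges),
            "edges_dialect": config.edges_dialect,
            "go": str(config.go) if config.go is not None else None,
            "go_sha256": _sha256(config.go) if config.go is not None else None,
            "go_dialect": config.go_dialect,
            "lk": asdict(config.lk),
            "post": asdict(config.post),
            "n_proteins": len(graph),
            "n_interactions": graph.edge_count,
            "tour_length": tour.length,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
    return final, result
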