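"""End-to-end wiring: annotation -> coverage -> matrix -> clustering -> outputs."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from metaclust import alignment_io, annotation_io, kmeans_clustering, metagene_core
from metaclust.kmeans_clustering import (
    DEFAULT_K_MAX,
    DEFAULT_MAX_ITER,
    DEFAULT_RESTARTS,
    DEFAULT_SEED,
    DEFAULT_THRESHOLD,
    KSelectionTrace,
)
from metaclust.outputs import (
    ClusterReport,
    render_plots,
    write_membership,
    write_run_report,
)

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """All knobs of one pipeline run; every paper-silent choice has a flag."""

    alignment: Path
    annotation: Path
    out_dir: Path
    control_alignment: Path | None = None
    feature_type: str = "CDS"
    bins: int = 100
    threshold: float = DEFAULT_THRESHOLD
    seed: int = DEFAULT_SEED
    k_max: int = DEFAULT_K_MAX
    restarts: int = DEFAULT_RESTARTS
    fixed_k: int | None = None
    distance: str = "squared"
    reverse_minus: bool = True
    scale_rows: bool = False
    pseudocount: float = 1.0
    max_iter: int = DEFAULT_MAX_ITER
    min_mapq: int = 0
    count_duplicates: bool = True
    log_level: str = "INFO"
    render_images: bool = True
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")
        if self.bins < 1:
            raise ValueError("bins must be >= 1")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        for name, path in (
            ("alignment", self.alignment),
            ("annotation", self.annotation),
            ("control alignment", self.control_alignment),
        ):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} file not found: {path}")

    def as_params(self) -> dict:
        return {
            "alignment": str(self.alignment),
            "control_alignment": (
                str(self.control_alignment) if self.control_alignment else None
            ),
            "annotation": str(self.annotation),
            "feature_type": self.feature_type,
            "bins": self.bins,
            "threshold": self.threshold,
            "seed": self.seed,
            "k_max": self.k_max,
            "restarts": self.restarts,
            "fixed_k": self.fixed_k,
            "distance": self.distance,
            "reverse_minus": self.reverse_minus,
            "scale_rows": self.scale_rows,
            "pseudocount": self.pseudocount,
        }


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def run_pipeline(config: RunConfig) -> ClusterReport:
    """Run all five stages and write every output; returns the ClusterReport."""
    try:
        config.validate()
    except (ValueError, FileNotFoundError) as exc:
        raise PipelineError("config", str(exc)) from exc

    try:
        with _stage("annotation"):
            features = annotation_io.parse_annotation(
                config.annotation, config.feature_type
            )
    except annotation_io.AnnotationError as exc:
        raise PipelineError("annotation", str(exc)) from exc

    try:
        with _stage("alignment"):
            track = alignment_io.build_coverage(
                config.alignment,
                min_mapq=config.min_mapq,
                count_duplicates=config.count_duplicates,
            )
            control = None
            if config.control_alignment is not None:
                control = alignment_io.build_coverage(
                    config.control_alignment,
                    min_mapq=config.min_mapq,
                    count_duplicates=config.count_duplicates,
                )
    except alignment_io.AlignmentError as exc:
        raise PipelineError("alignment", str(exc)) from exc

    try:
        with _stage("matrix"):
            known = [f for f in features if f.chrom in track.chrom_lengths]
            dropped = len(features) - len(known)
            if dropped:
                logger.warning(
                    "%d features on chromosomes absent from the alignment header "
                    "were dropped", dropped,
                )
            matrix = metagene_core.build_matrix(
                track,
                known,
                config.bins,
                control=control,
                reverse_minus=config.reverse_minus,
                scale_rows=config.scale_rows,
                pseudocount=config.pseudocount,
            )
    except metagene_core.MatrixError as exc:
        raise PipelineError("matrix", str(exc)) from exc

    with _stage("clustering"):
        rng = np.random.default_rng(config.seed)
        if config.fixed_k is not None:
            best = None
            for _ in range(config.restarts):
                model = kmeans_clustering.run_kmeans(
                    matrix, config.fixed_k, rng, config.max_iter,
                    distance=config.distance,
                )
                if best is None or model.total_distance < best.total_distance:
                    best = model
            model = best
            trace = KSelectionTrace(
                entries=[(config.fixed_k, model.total_distance, None)]
            )
        else:
            model, trace = kmeans_clustering.select_k(
                matrix,
                threshold=config.threshold,
                rng=rng,
                k_max=config.k_max,
                restarts=config.restarts,
                max_iter=config.max_iter,
                distance=config.distance,
            )
        logger.info(
            "selected k = %d with total distance %.4g", model.k, model.total_distance
        )

    try:
        with _stage("outputs"):
            report = ClusterReport.from_model(
                model,
                ids=matrix.ids,
                rows=matrix.rows,
                trace=trace,
                params=config.as_params(),
                skipped_features=len(features) - matrix.n,
            )
            report.validate_partition()
            write_membership(report, config.out_dir)
            render_plots(report, config.out_dir, images=config.render_images)
            write_run_report(report, config.out_dir)
    except OSError as exc:
        raise PipelineError("outputs", str(exc)) from exc

    return report
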