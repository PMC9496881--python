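"""End-to-end orchestration: skull-strip -> swarm block search -> K-means.

Both images are stripped with the *shared* brain mask (intersection of
their individual masks) so candidate and reference blocks compare tissue to
tissue, and the swarm's search domain is restricted to blocks fully inside
that mask — blocks straddling the stripped boundary compare padding zeros,
not tissue, and on sharp boundaries the variance-ratio fitness would
otherwise blow up there.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import __version__
from .blocksearch import SearchResult, SwarmConfig, pso_search
from .io import save_image, save_mask
from .metrics import MetricsReport, evaluate_masks
from .preprocess import PreprocessConfig, skull_strip
from .segment import SegmentationResult, segment_roi

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full run; ``seed`` overrides every stage seed."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    tumor_polarity: str = "bright"
    seed: int | None = None
    output_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "swarm" in d and isinstance(d["swarm"], dict):
            d["swarm"] = SwarmConfig(**d["swarm"])
        return cls(**d)


@dataclass
class PipelineResult:
    segmentation: SegmentationResult
    search: SearchResult
    report: MetricsReport | None
    brain_mask: np.ndarray


def _stage(name: str):
    """Decorator-free stage context: re-raise with the failing stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(diseased: np.ndarray, reference: np.ndarray,
                 config: PipelineConfig | None = None,
                 truth: np.ndarray | None = None) -> PipelineResult:
    """Run the three-stage segmentation on a co-registered image pair.

    Stages: skull-strip both images (shared mask), swarm search for the
    lesion block over that mask, K-means segmentation of the block, and —
    when a ground-truth mask is given — metric evaluation.  Artifacts and a
    manifest are written to ``config.output_dir`` when set.
    """
    config = config or PipelineConfig()
    if reference is None:
        raise ValueError("the disease-free reference image is required")
    d = np.asarray(diseased, dtype=float)
    r = np.asarray(reference, dtype=float)
    if d.shape != r.shape:
        raise ValueError(f"diseased and reference differ in shape: {d.shape} vs {r.shape}")

    seed = config.seed
    swarm = config.swarm if seed is None else replace(config.swarm, random_seed=seed)

    with _stage("preprocess"):
        _, mask_d = skull_strip(d, config.preprocess)
        _, mask_r = skull_strip(r, config.preprocess)
        brain_mask = mask_d & mask_r
        if not brain_mask.any():
            raise ValueError("shared brain mask is empty")
        stripped_d = d * brain_mask
        stripped_r = r * brain_mask

    with _stage("blocksearch"):
        search = pso_search(stripped_d, stripped_r, swarm, valid_mask=brain_mask)

    with _stage("segment"):
        segmentation = segment_roi(stripped_d, search.best_block,
                                   seed=seed if seed is not None else 0,
                                   tumor_polarity=config.tumor_polarity)

    report = None
    if truth is not None:
        with _stage("evaluate"):
            report = evaluate_masks(segmentation.tumor_mask, truth)

    if config.output_dir is not None:
        _write_artifacts(Path(config.output_dir), config, stripped_d, stripped_r,
                         brain_mask, search, segmentation, report)

    return PipelineResult(segmentation=segmentation, search=search,
                          report=report, brain_mask=brain_mask)


def _write_artifacts(out: Path, config, stripped_d, stripped_r, brain_mask,
                     search, segmentation, report) -> None:
    out.mkdir(parents=True, exist_ok=True)
    save_image(out / "stripped_diseased.png", stripped_d)
    save_image(out / "stripped_reference.png", stripped_r)
    save_mask(out / "brain_mask.png", brain_mask)
    save_mask(out / "tumor_mask.png", segmentation.tumor_mask)

    with open(out / "trace.csv", "w") as fh:
        fh.write("iteration,best_fitness\n")
        for i, f in enumerate(search.fitness_trace, start=1):
            fh.write(f"{i},{f!r}\n")

    roi = segmentation.roi
    result = {
        "roi": {"top": roi.top, "left": roi.left,
                "height": roi.height, "width": roi.width},
        "best_fitness": search.best_fitness,
        "evaluations": search.evaluations,
        "cache_hits": search.cache_hits,
        "cluster_centers": list(segmentation.cluster_centers),
        "kmeans_iterations": segmentation.iterations_used,
    }
    if report is not None:
        result["metrics"] = report.to_dict()
    (out / "result.json").write_text(json.dumps(result, indent=2))

    manifest = {
        "config": config.to_dict(),
        "versions": {"blockseg": __version__, "python": platform.python_version(),
                     "numpy": np.__version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("artifacts written to %s", out)
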