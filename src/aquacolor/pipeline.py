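"""End-to-end orchestration: correct -> mask -> extract -> classify -> vote.

``run_pipeline`` executes the four stages on one frame and returns a
JSON-serializable :class:`PipelineReport`; failures at any stage are
captured as a structured error (stage tag + cause) instead of a partial
color.  ``run_batch`` maps the pipeline over a directory of paired
``<stem>.png`` / ``<stem>.mask.png`` files and writes a per-frame color
time series.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .checkerboard import CheckerboardLayout
from .classifier import (
    NearestCentroidWaterColorClassifier,
    PaletteConfig,
    representative_color,
)
from .correction import LabColorCorrector
from .errors import AquacolorError
from .fuzzy import FISConfig, RuleBase
from .patches import ExtractionConfig, extract_candidates, rank_candidates
from .segmentation import ClassMask, load_mask

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "run_batch"]

logger = logging.getLogger("aquacolor.pipeline")


@dataclass
class PipelineConfig:
    """All tunables of the four stages in one place."""

    layout: CheckerboardLayout = field(default_factory=CheckerboardLayout)
    fis: FISConfig = field(default_factory=FISConfig)
    rules: RuleBase = field(default_factory=RuleBase)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    palette: PaletteConfig = field(default_factory=PaletteConfig)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        kwargs = {}
        if "layout" in d:
            kwargs["layout"] = CheckerboardLayout.from_dict(d["layout"])
        if "fis" in d:
            kwargs["fis"] = FISConfig.from_dict(d["fis"])
        if "rules" in d:
            kwargs["rules"] = RuleBase.from_dict(d["rules"])
        if "extraction" in d:
            kwargs["extraction"] = ExtractionConfig(**d["extraction"])
        if "palette" in d:
            kwargs["palette"] = PaletteConfig(
                centroids={k: np.asarray(v["lab"]) for k, v in d["palette"].items()},
                radii={
                    k: float(v["radius"]) for k, v in d["palette"].items()
                    if "radius" in v
                },
            )
        return cls(**kwargs)


@dataclass
class PipelineReport:
    """Everything one frame produced, or a tagged error if a stage failed."""

    input_path: str
    seed: int | None
    success: bool
    correction_residual: float | None = None
    candidates: list = field(default_factory=list)  # N dicts (rect, p1, p2, q)
    selected: list = field(default_factory=list)  # N1 dicts incl. probabilities
    representative_code: str | None = None
    error_stage: str | None = None
    error_message: str | None = None
    timestamp: float = 0.0
    config_echo: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "PipelineReport":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


def _load_image(image) -> np.ndarray:
    if isinstance(image, (str, Path)):
        with Image.open(image) as img:
            return np.asarray(img.convert("RGB"))
    return np.asarray(image)


def run_pipeline(
    image,
    mask,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> PipelineReport:
    """Run the four stages on one frame.

    ``image`` and ``mask`` may be paths or in-memory arrays/:class:`ClassMask`.
    The candidate patches are extracted from, and classified on, the
    color-corrected frame.  The returned report carries the representative
    code on success, or the failing stage and cause otherwise.
    """
    config = config or PipelineConfig()
    report = PipelineReport(
        input_path=str(image) if isinstance(image, (str, Path)) else "<array>",
        seed=seed,
        success=False,
        timestamp=time.time(),
        config_echo={
            "n_candidates": config.extraction.n_candidates,
            "n_selected": config.extraction.n_selected,
            "threshold": config.extraction.threshold,
        },
    )
    stage = "input"
    try:
        frame = _load_image(image)
        if isinstance(mask, ClassMask):
            class_mask = mask
        else:
            class_mask = load_mask(mask, expected_shape=frame.shape[:2])

        stage = "correction"
        t0 = time.perf_counter()
        corrector = LabColorCorrector(layout=config.layout).fit(frame)
        corrected = corrector.transform(frame)
        report.correction_residual = corrector.residual_
        logger.info(
            "correction: residual %.3f Lab (%.2fs)",
            corrector.residual_,
            time.perf_counter() - t0,
        )

        stage = "extraction"
        t0 = time.perf_counter()
        extraction = config.extraction
        if seed is not None:
            rng = np.random.default_rng(seed)
        else:
            rng = np.random.default_rng(extraction.seed)
        cands = extract_candidates(
            corrected, class_mask, extraction, config.fis, config.rules, rng=rng
        )
        report.candidates = [c.to_dict() for c in cands]
        selected = rank_candidates(cands, extraction.n_selected)
        logger.info(
            "extraction: %d candidates, kept %d (%.2fs)",
            len(cands),
            len(selected),
            time.perf_counter() - t0,
        )

        stage = "classification"
        clf = NearestCentroidWaterColorClassifier(config.palette).fit()
        outputs = []
        for cand in selected:
            x1, y1, x2, y2 = cand.rect
            out = clf.predict_output(corrected[y1:y2, x1:x2])
            outputs.append(out)
            record = cand.to_dict()
            record.update(out.to_dict())
            report.selected.append(record)

        stage = "voting"
        report.representative_code = representative_color(outputs).full_code
        report.success = True
    except AquacolorError as exc:
        report.error_stage = stage
        report.error_message = str(exc)
        logger.warning("pipeline failed at stage %s: %s", stage, exc)
    return report


def run_batch(
    directory,
    config: PipelineConfig | None = None,
    seed: int | None = None,
    summary_csv=None,
) -> list:
    """Run the pipeline over every ``<stem>.png`` with a ``<stem>.mask.png``.

    Per-file failures are recorded in their reports and the batch
    continues.  When ``summary_csv`` is given, a per-frame (file,
    code-or-error) table is written.
    """
    directory = Path(directory)
    frames = sorted(
        p
        for p in directory.glob("*.png")
        if not p.name.endswith(".mask.png")
        and (directory / f"{p.name[: -len('.png')]}.mask.png").exists()
    )
    reports = []
    for i, frame in enumerate(frames):
        mask_path = directory / f"{frame.name[: -len('.png')]}.mask.png"
        frame_seed = None if seed is None else seed + i
        try:
            report = run_pipeline(frame, mask_path, config, seed=frame_seed)
        except Exception as exc:  # unexpected: record and continue
            report = PipelineReport(
                input_path=str(frame),
                seed=frame_seed,
                success=False,
                error_stage="input",
                error_message=str(exc),
                timestamp=time.time(),
            )
        reports.append(report)
    if summary_csv is not None:
        with open(summary_csv, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["file", "representative_code", "error_stage"])
            for r in reports:
                writer.writerow(
                    [r.input_path, r.representative_code or "", r.error_stage or ""]
                )
    return reports
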