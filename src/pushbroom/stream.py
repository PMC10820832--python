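"""Real-time classification loop.

Each incoming detector frame is smile-remapped, converted to per-position
reflectance against the in-frame white reference panel, reduced to 50
binned features, filtered for bare ground, and classified by the trained
perceptron — producing one :class:`ClassifiedLine` record per frame
(one label per spatial position: ``class_A``, ``class_B``, or ``ground``).
Records are emitted as JSON lines, one per frame, so the stream can be
consumed incrementally without a message broker.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import numpy as np

from .calibrate import CalibrationFit, remap_frame
from .classify import CLASS_NAMES, MLPModel
from .reflectance import bin_features, compute_reflectance, ground_filter

__all__ = ["ClassifiedLine", "PipelineConfig", "StreamSummary",
           "classify_frame", "run_stream"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the per-frame pipeline needs."""

    calibration: CalibrationFit
    model: MLPModel
    white_rows: tuple[int, int]
    ground_threshold: float = 0.10
    n_bins: int = 50
    bin_range_nm: tuple[float, float] = (450.0, 950.0)
    reference_floor: float = 5.0
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.ground_threshold <= 1.0:
            raise ValueError("ground threshold must lie in [0, 1]")
        if not 0.0 <= self.decision_threshold <= 1.0:
            raise ValueError("decision threshold must lie in [0, 1]")

    @classmethod
    def from_files(cls, calibration_path, model_path, white_rows,
                   **kwargs) -> "PipelineConfig":
        from .io import read_calibration, read_model
        return cls(calibration=read_calibration(calibration_path),
                   model=read_model(model_path),
                   white_rows=tuple(white_rows), **kwargs)


@dataclass
class ClassifiedLine:
    """Per-position classification of one frame's ground line."""

    frame_id: int
    timestamp: float
    positions: np.ndarray            # spatial row indices
    labels: list[str]                # class_A | class_B | ground per position
    scores: list[float | None]       # logistic output; None for ground

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.scores) == self.positions.size):
            raise ValueError("one label and score per position required")
        for lab, s in zip(self.labels, self.scores):
            if lab == "ground" and s is not None:
                raise ValueError("ground positions carry no score")

    def to_record(self) -> dict:
        return {
            "frame_id": self.frame_id,
            "timestamp": self.timestamp,
            "positions": self.positions.tolist(),
            "labels": self.labels,
            "scores": self.scores,
        }


def classify_frame(frame: np.ndarray, cfg: PipelineConfig, frame_id: int = 0,
                   timestamp: float | None = None) -> ClassifiedLine:
    """Run the full per-frame pipeline; deterministic for a given frame."""
    frame = np.asarray(frame)
    remapped = remap_frame(frame, cfg.calibration)
    line = compute_reflectance(remapped, cfg.calibration, cfg.white_rows,
                               floor=cfg.reference_floor)
    vectors = [ground_filter(v, cfg.ground_threshold)
               for v in bin_features(line, cfg.n_bins, cfg.bin_range_nm)]

    labels: list[str] = ["ground"] * len(vectors)
    scores: list[float | None] = [None] * len(vectors)
    live = [i for i, v in enumerate(vectors) if v.valid]
    if live:
        X = np.stack([vectors[i].features for i in live])
        proba = cfg.model.predict_proba(X)
        for i, p in zip(live, proba):
            labels[i] = CLASS_NAMES[int(p >= cfg.decision_threshold)]
            scores[i] = float(p)
    return ClassifiedLine(
        frame_id=frame_id,
        timestamp=time.time() if timestamp is None else timestamp,
        positions=line.positions,
        labels=labels,
        scores=scores,
    )


@dataclass
class StreamSummary:
    frames_processed: int = 0
    frames_skipped: int = 0
    positions_classified: int = 0
    class_counts: dict = field(default_factory=lambda: {
        CLASS_NAMES[0]: 0, CLASS_NAMES[1]: 0, "ground": 0})
    mean_latency_s: float = 0.0


def run_stream(
    source: Iterable[np.ndarray],
    cfg: PipelineConfig,
    sink: IO[str] | str | Path | None = None,
) -> StreamSummary:
    """Consume frames, classify each, emit one JSONL record per frame.

    Unreadable frames (wrong shape, decode errors) are skipped with a
    logged warning and the stream continues. An empty source yields an
    empty output and a zero summary. Memory use is bounded: one frame is
    held at a time.
    """
    close_sink = False
    out: IO[str] | None
    if sink is None:
        out = None
    elif isinstance(sink, (str, Path)):
        out = open(sink, "w")
        close_sink = True
    else:
        out = sink

    summary = StreamSummary()
    latencies: list[float] = []
    try:
        for frame_id, frame in enumerate(source):
            t0 = time.perf_counter()
            try:
                record = classify_frame(frame, cfg, frame_id=frame_id)
            except Exception as exc:  # corrupt frame: skip, keep streaming
                logger.warning("skipping frame %d: %s", frame_id, exc)
                summary.frames_skipped += 1
                continue
            latencies.append(time.perf_counter() - t0)
            summary.frames_processed += 1
            summary.positions_classified += record.positions.size
            for lab in record.labels:
                summary.class_counts[lab] += 1
            if out is not None:
                out.write(json.dumps(record.to_record()) + "\n")
    finally:
        if out is not None and close_sink:
            out.close()
    if latencies:
        summary.mean_latency_s = float(np.mean(latencies))
    return summary
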