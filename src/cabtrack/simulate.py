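"""Synthetic transplanting-pass generator.

Emulates the statistics of a camera mounted on a moving transplanter filming
row-planted seedlings: targets sit on a regular row grid (35 cm within-row,
45 cm between rows at the default ~4 px/cm scale), translate downward
through a fixed image frame at near-constant speed, carry one of three
transplant states drawn with field-realistic imbalance, and emit detections
corrupted by misses, box jitter and false positives, plus identity-
conditioned appearance embeddings. Everything derives from a single seeded
generator, so a (config, seed) pair is a reproducible scene.

The generator produces the coordinate streams and appearance vectors of a
field pass, not images: leaf texture, illumination, mulch reflections and
occlusion structure of real video are out of its reach, so results on these
scenes exercise the tracking/counting logic rather than any detector.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .appearance import EMBED_DIM, synthetic_embedder
from .counting import CountReport, CountingLine, CrossingLedger, default_line
from .evaluation import CountTable, EvalReport, evaluate_count_table
from .formats import (
    AnnotationRecord,
    BoundingBox,
    Detection,
    TransplantState,
    write_darklabel_csv,
    write_detections,
)
from .tracking import Tracker, TrackerConfig

STATES = tuple(TransplantState)


@dataclass(frozen=True)
class SceneConfig:
    """Generative description of one synthetic field pass.

    Defaults model a quarter-scale 3840x2160 video at ~4 px/cm: 35 cm plant
    spacing -> 140 px, 45 cm row spacing -> 180 px, 0.35 m/s machine speed at
    30 fps -> 5 px/frame. State proportions follow the ~82/11/7% imbalance
    of manually scored field passes.
    """

    n_plants: int = 20
    plant_spacing_px: float = 140.0
    row_spacing_px: float = 180.0
    camera_speed_px_per_frame: float = 5.0
    frame_size: tuple[int, int] = (960, 540)  # (width, height)
    state_proportions: tuple[float, float, float] = (0.82, 0.11, 0.07)
    box_side_mean: float = 64.0
    box_side_sd: float = 6.0
    aspect_sd: float = 0.05
    miss_prob: float = 0.0
    fp_rate_per_frame: float = 0.0
    jitter_sd: float = 0.0
    embed_noise_sd: float = 0.05
    embed_dim: int = EMBED_DIM
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.state_proportions) - 1.0) > 1e-9:
            raise ValueError("state_proportions must sum to 1")
        if not all(0.0 <= p <= 1.0 for p in self.state_proportions):
            raise ValueError("state_proportions must lie in [0, 1]")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must lie in [0, 1]")
        if self.fp_rate_per_frame < 0 or self.jitter_sd < 0 or self.embed_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        # boxes larger than the grid pitch would overlap and break the layout
        if self.box_side_mean + 4 * self.box_side_sd >= min(
            self.plant_spacing_px, self.row_spacing_px
        ):
            raise ValueError("infeasible geometry: boxes larger than grid spacing")


@dataclass
class SimulatedScene:
    config: SceneConfig
    n_frames: int
    truth: list[AnnotationRecord]
    detections: list[Detection]
    embeddings: list[np.ndarray]  # aligned with detections
    identities: list[int]  # true identity per detection; negative = false positive
    true_counts: dict[TransplantState, int]

    def detections_by_frame(self) -> dict[int, list[int]]:
        by_frame: dict[int, list[int]] = {}
        for i, d in enumerate(self.detections):
            by_frame.setdefault(d.frame, []).append(i)
        return by_frame


def _plants_per_row(config: SceneConfig) -> int:
    width = config.frame_size[0]
    margin = config.box_side_mean
    return max(1, int((width - 2 * margin) // config.plant_spacing_px) + 1)


def layout_plants(
    config: SceneConfig, rng: np.random.Generator
) -> list[tuple[int, float, float, float, float, TransplantState]]:
    """Place plants on the row grid: (id, cx, y_start, w, h, state) tuples.

    Rows start above the image and translate downward through the view as
    frames advance.
    """
    per_row = _plants_per_row(config)
    margin = config.box_side_mean
    probs = np.array(config.state_proportions)
    plants = []
    for pid in range(config.n_plants):
        row, col = divmod(pid, per_row)
        side = max(8.0, rng.normal(config.box_side_mean, config.box_side_sd))
        aspect = max(0.5, rng.normal(1.0, config.aspect_sd))
        w, h = side * aspect, side / aspect
        cx = margin + col * config.plant_spacing_px + rng.normal(0.0, 2.0)
        y_start = -(row * config.row_spacing_px) - h
        state = STATES[rng.choice(3, p=probs)]
        plants.append((pid, cx, y_start, w, h, state))
    return plants


def simulate_scene(config: SceneConfig) -> SimulatedScene:
    """Realize a scene: ground-truth trajectories, detections, embeddings."""
    rng = np.random.default_rng(config.seed)
    # independent substreams so that toggling one noise source leaves the
    # others' draws untouched
    rng_layout = np.random.default_rng(rng.integers(2**31))
    rng_miss = np.random.default_rng(rng.integers(2**31))
    rng_jitter = np.random.default_rng(rng.integers(2**31))
    rng_fp = np.random.default_rng(rng.integers(2**31))
    rng_embed = np.random.default_rng(rng.integers(2**31))

    width, height = config.frame_size
    per_row = _plants_per_row(config)
    plants = layout_plants(config, rng_layout)

    n_rows = (config.n_plants + per_row - 1) // per_row
    travel = n_rows * config.row_spacing_px + height + 2 * config.box_side_mean
    n_frames = int(np.ceil(travel / config.camera_speed_px_per_frame))

    truth: list[AnnotationRecord] = []
    detections: list[Detection] = []
    embeddings: list[np.ndarray] = []
    identities: list[int] = []
    next_fp_id = -1

    for frame in range(n_frames):
        dy = frame * config.camera_speed_px_per_frame
        for pid, cx, y0, w, h, state in plants:
            cy = y0 + dy
            box = BoundingBox(cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
            visible = box.x2 > 0 and box.x1 < width and box.y2 > 0 and box.y1 < height
            if not visible:
                continue
            truth.append(AnnotationRecord(frame, state, pid, box))
            if rng_miss.random() < config.miss_prob:
                continue
            if config.jitter_sd > 0:
                j = rng_jitter.normal(0.0, config.jitter_sd, size=4)
            else:
                j = np.zeros(4)
            try:
                jbox = BoundingBox(box.x1 + j[0], box.y1 + j[1],
                                   box.x2 + j[2], box.y2 + j[3])
            except ValueError:
                jbox = box  # jitter collapsed the box; keep the clean one
            conf = float(np.clip(rng_jitter.normal(0.92, 0.04), 0.55, 1.0))
            detections.append(Detection(frame, state, jbox, conf))
            embeddings.append(
                synthetic_embedder(pid, config.embed_noise_sd, config.seed,
                                   dim=config.embed_dim, rng=rng_embed)
            )
            identities.append(pid)
        # clutter: spurious boxes with throwaway identities; the tracker's
        # tentative-track filter is the mechanism expected to suppress them
        for _ in range(rng_fp.poisson(config.fp_rate_per_frame)):
            side = max(8.0, rng_fp.normal(config.box_side_mean, config.box_side_sd))
            cx = rng_fp.uniform(side, width - side)
            cy = rng_fp.uniform(side, height - side)
            state = STATES[rng_fp.choice(3)]
            box = BoundingBox(cx - side / 2, cy - side / 2, cx + side / 2, cy + side / 2)
            conf = float(rng_fp.uniform(0.5, 0.85))
            detections.append(Detection(frame, state, box, conf))
            embeddings.append(
                synthetic_embedder(next_fp_id, config.embed_noise_sd, config.seed,
                                   dim=config.embed_dim, rng=rng_embed)
            )
            identities.append(next_fp_id)
            next_fp_id -= 1

    true_counts = {s: 0 for s in STATES}
    for pid, cx, y0, w, h, state in plants:
        true_counts[state] += 1
    return SimulatedScene(config, n_frames, truth, detections,
                          embeddings, identities, true_counts)


@dataclass
class PipelineResult:
    count_report: CountReport
    eval_report: EvalReport
    track_records: list[AnnotationRecord]
    id_switches: int


def run_pipeline(
    scene: SimulatedScene,
    tracker_config: TrackerConfig | None = None,
    line: CountingLine | None = None,
) -> PipelineResult:
    """Track the scene's detections, count line crossings, score vs truth."""
    from .evaluation import count_id_switches

    width, height = scene.config.frame_size
    line = line or default_line(width, height)
    tracker = Tracker(tracker_config or TrackerConfig())
    ledger = CrossingLedger(line)
    track_records: list[AnnotationRecord] = []

    by_frame = scene.detections_by_frame()
    for frame in range(scene.n_frames):
        idx = by_frame.get(frame, [])
        dets = [scene.detections[i] for i in idx]
        embs = [scene.embeddings[i] for i in idx]
        active = tracker.step(frame, dets, embs)
        at_frame = []
        for t in active:
            box = t.to_box()
            label = t.state_label
            at_frame.append((t.id, box.center, label))
            track_records.append(AnnotationRecord(frame, label, t.id, box))
        report = ledger.update(at_frame)

    table = CountTable({
        "sim": {s: (scene.true_counts[s], report.counts[s]) for s in STATES}
    })
    eval_report = evaluate_count_table(table)
    switches = count_id_switches(scene.truth, track_records)
    return PipelineResult(report, eval_report, track_records, switches)


def write_scene(scene: SimulatedScene, out_dir: str | Path) -> dict[str, Path]:
    """Write truth CSV, detections CSV, embeddings CSV and a config manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "truth": out / "truth.csv",
        "detections": out / "detections.csv",
        "embeddings": out / "embeddings.csv",
        "manifest": out / "manifest.json",
    }
    write_darklabel_csv(scene.truth, paths["truth"])
    write_detections(scene.detections, paths["detections"])
    with open(paths["embeddings"], "w", encoding="utf-8") as fh:
        for det, emb in zip(scene.detections, scene.embeddings):
            vals = ",".join(f"{v:.6f}" for v in emb)
            fh.write(f"{det.frame},{vals}\n")
    manifest = dataclasses.asdict(scene.config)
    manifest["n_frames"] = scene.n_frames
    manifest["true_counts"] = {str(s): c for s, c in scene.true_counts.items()}
    with open(paths["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return paths
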