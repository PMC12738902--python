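"""cabtrack: tracking-by-detection, virtual-line counting and quality metrics
for row-crop transplanting video.

The package chains per-frame transplant-state detections (normal / buried
seedling / bare root) into identities with a Kalman + Hungarian tracker
augmented by an appearance re-identification gallery, tallies each identity
once as it crosses a virtual counting line, and scores the resulting counts
against manual ground truth with MCA / MAE / RMSE. A seeded scene simulator
provides reproducible synthetic field passes for end-to-end testing, and a
small numerics layer implements the imbalance-aware classification loss and
triplet-attention forward math used on the detection side.
"""

from importlib.resources import files as _files

from .counting import CountingLine, CountReport, CrossingLedger, compute_rates
from .evaluation import CountTable, EvalReport, evaluate_count_table, mca
from .formats import (
    AnnotationRecord,
    BoundingBox,
    Detection,
    TransplantState,
    iou,
    read_darklabel_csv,
    read_detections,
    write_darklabel_csv,
    write_detections,
)
from .simulate import SceneConfig, SimulatedScene, run_pipeline, simulate_scene
from .tracking import Tracker, TrackerConfig

__version__ = "0.1.0"


def field_trial_count_table() -> CountTable:
    """Manual vs automated counts from a four-video cabbage field trial.

    Shipped as package data; the worked example every metric in
    :mod:`cabtrack.evaluation` is exercised against.
    """
    path = _files("cabtrack").joinpath("data/field_trial_counts.csv")
    return CountTable.from_csv(str(path))
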