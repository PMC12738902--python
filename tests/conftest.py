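import numpy as np
import pytest

from cabtrack.formats import AnnotationRecord, BoundingBox, TransplantState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, lo=0.0, hi=500.0, min_side=1.0, max_side=80.0) -> BoundingBox:
    x1 = rng.uniform(lo, hi)
    y1 = rng.uniform(lo, hi)
    w = rng.uniform(min_side, max_side)
    h = rng.uniform(min_side, max_side)
    return BoundingBox(x1, y1, x1 + w, y1 + h)


def random_records(rng, n) -> list[AnnotationRecord]:
    states = list(TransplantState)
    records = []
    for i in range(n):
        records.append(
            AnnotationRecord(
                frame=int(rng.integers(0, 50)),
                state=states[rng.integers(0, 3)],
                id=i,  # (frame, id) uniqueness by construction
                box=random_box(rng),
            )
        )
    return records
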