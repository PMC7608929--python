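import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pragmascore.annotation_model import CellLabel, GridAnnotation, LABEL_CODES

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_annotation(
    counts: dict[CellLabel, int],
    patient_id: str = "P0",
    visit: str = "SOS",
    grid: tuple[int, int] = (10, 10),
    n_slices: int = 10,
    seed: int = 0,
) -> GridAnnotation:
    """Build an annotation with exact per-label cell counts, shuffled."""
    rows, cols = grid
    total = rows * cols * n_slices
    n_labelled = sum(counts.values())
    assert n_labelled <= total
    codes = np.full(total, LABEL_CODES[CellLabel.NON_LUNG], dtype=np.uint8)
    start = 0
    for label, k in counts.items():
        codes[start : start + k] = LABEL_CODES[label]
        start += k
    np.random.default_rng(seed).shuffle(codes)
    per = rows * cols
    slices = [codes[i * per : (i + 1) * per].reshape(rows, cols).copy() for i in range(n_slices)]
    return GridAnnotation(patient_id, visit, slices)


@pytest.fixture
def hand_count_annotation() -> GridAnnotation:
    """1,000 lung cells: 100 BE, 20 MP, 5 AWT, 10 ATL, 865 normal."""
    return make_annotation(
        {
            CellLabel.BRONCHIECTASIS: 100,
            CellLabel.MUCUS_PLUGGING: 20,
            CellLabel.AWT: 5,
            CellLabel.ATELECTASIS: 10,
            CellLabel.NORMAL: 865,
        }
    )
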