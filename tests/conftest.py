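import numpy as np
import pytest

from coralcasa import CasaSettings, FieldGeometry, GroundTruth, MotilityMixture
from coralcasa.simulator import TruthCell


@pytest.fixture
def settings() -> CasaSettings:
    return CasaSettings()


@pytest.fixture
def geometry() -> FieldGeometry:
    return FieldGeometry()


def make_truth(
    cells_spec: list[tuple[str, float, np.ndarray]],
    geometry: FieldGeometry | None = None,
    frame_rate_hz: float = 60.0,
    n_frames: int | None = None,
) -> GroundTruth:
    """Hand-build a ground truth from (class, head_area, positions) triples."""
    geometry = geometry or FieldGeometry()
    cells = []
    for cell_id, (cls, area, positions) in enumerate(cells_spec):
        positions = np.asarray(positions, dtype=float)
        cells.append(
            TruthCell(
                cell_id=cell_id,
                motility_class=cls,
                head_area_um2=area,
                frames=np.arange(len(positions)),
                positions=positions,
            )
        )
    if n_frames is None:
        n_frames = max(len(c.positions) for c in cells)
    return GroundTruth(
        cells=cells, geometry=geometry, frame_rate_hz=frame_rate_hz, n_frames=n_frames
    )


@pytest.fixture
def static_truth_one_cell(geometry) -> GroundTruth:
    positions = np.tile([[100.0, 80.0]], (45, 1))
    return make_truth([("static", 20.0, positions)], geometry)
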