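import numpy as np
import pytest

from gliamorph import segmentation, simulate


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def standard_scene():
    """The standard recovery fixture: 30 cells, 512×512, SNR 8, seed 0."""
    return simulate.render_scene(simulate.resting_preset(seed=0))


@pytest.fixture(scope="session")
def standard_segmentation(standard_scene):
    accepted, log, mip = segmentation.segment_stack(standard_scene.stack)
    return accepted, log, mip


@pytest.fixture(scope="session")
def random_cells():
    """A batch of generated cells (masks + generator truth) for oracle tests."""
    rng = np.random.default_rng(202)
    cells = []
    for i in range(60):
        spec = simulate.draw_cell_spec(
            simulate.resting_preset(seed=0) if i % 2 == 0
            else simulate.activated_preset(seed=0),
            rng,
        )
        cells.append(simulate.generate_cell(spec, rng))
    return cells
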