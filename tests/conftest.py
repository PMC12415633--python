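import numpy as np
import pytest

import edpat as ep


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Rendered two-cell dataset (V = 1000 Å³, 150 orientations each)."""
    out = tmp_path_factory.mktemp("smallds")
    cells = [ep.random_unit_cell(1000.0,
                                 seed=np.random.SeedSequence([0, 7, i]),
                                 cell_id=f"c{i}") for i in range(2)]
    return ep.simulate_dataset(cells, 150, ep.PhysicsConfig(), ep.RenderSpec(),
                               output_dir=out, seed=0)


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    return ep.train(small_dataset,
                    ep.TrainConfig(epochs=7, image_size=128, seed=0))


@pytest.fixture()
def random_cells():
    return [ep.random_unit_cell(1000.0,
                                seed=np.random.SeedSequence([11, i]),
                                cell_id=f"r{i}") for i in range(5)]
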