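import numpy as np
import pytest

from gicanet.design import Event, TaskDesign
from gicanet.simulate import Grid, GroundTruth, make_templates, simulate_dataset


@pytest.fixture(scope="session")
def grid20() -> Grid:
    return Grid((20, 20, 20))


@pytest.fixture(scope="session")
def two_block_design() -> TaskDesign:
    """Two 18 s blocks per condition in one 120-volume run at TR 2 s."""
    events = [
        Event("run-1", "taskA", 10.0, 18.0),
        Event("run-1", "taskB", 50.0, 18.0),
        Event("run-1", "taskA", 100.0, 18.0),
        Event("run-1", "taskB", 150.0, 18.0),
    ]
    return TaskDesign(events, {"run-1": 120}, ["taskA", "taskB"])


@pytest.fixture(scope="session")
def planted_networks(grid20):
    masks, fields = make_templates(grid20, n_networks=4, smoothness=2.0, seed=7)
    return masks, fields


@pytest.fixture(scope="session")
def noiseless_dataset(grid20, planted_networks, two_block_design):
    """Four planted networks, no voxel noise: exact outer-product data."""
    masks, fields = planted_networks
    truth = GroundTruth(
        planted_maps=fields,
        template_masks=masks,
        condition_weights=np.array(
            [[-0.8, -0.8], [1.0, 0.2], [0.2, 1.0], [0.0, 0.0]]
        ),
        condition_labels=["taskA", "taskB"],
        noise_sd=0.0,
        seed=123,
    )
    runs, tcs = simulate_dataset(
        truth, two_block_design, n_subjects=4, n_runs=1, n_volumes=120, tr=2.0,
        grid=grid20,
    )
    return truth, runs, tcs
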