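import numpy as np
import pytest

import hdspace as h


@pytest.fixture(scope="session")
def arena():
    return h.ArenaSpec()


@pytest.fixture(scope="session")
def wake_traj(arena):
    """600 s wall-biased foraging trajectory shared across tests."""
    return h.simulate_trajectory(arena, h.TrajectoryParams(duration=600.0, seed=1))


@pytest.fixture(scope="session")
def wake_mask(wake_traj):
    return h.speed_filter(wake_traj)


@pytest.fixture(scope="session")
def short_traj(arena):
    return h.simulate_trajectory(arena, h.TrajectoryParams(duration=120.0, seed=2))


@pytest.fixture(scope="session")
def short_mask(short_traj):
    return h.speed_filter(short_traj)


@pytest.fixture(scope="session")
def small_session(arena):
    """Compact mixed session (wake + sleep) reused by pipeline-level tests."""
    rng = np.random.default_rng(42)
    models = [
        h.CellModel(kind="pure_hd", preferred_direction=rng.uniform(0, 2 * np.pi))
        for _ in range(4)
    ]
    models.append(
        h.CellModel(kind="hd_border", preferred_direction=2.0,
                    gain_per_wall=(3.0, 1.0, 1.0, 1.0))
    )
    models.append(h.CellModel(kind="homogeneous", baseline_rate=5.0))
    wf = {f"cell{i:03d}": (1.1, 0.6) for i in range(5)}
    wf["cell005"] = (0.8, 0.3)
    return h.simulate_session(
        models, arena, h.TrajectoryParams(duration=240.0),
        h.SleepParams(duration=120.0), seed=11, waveforms=wf,
    )
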