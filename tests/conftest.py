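import numpy as np
import pytest

import flyseize as fz


@pytest.fixture(scope="session")
def arena():
    return fz.ArenaSpec()


@pytest.fixture(scope="session")
def big_arena():
    """Large rectangular arena for long constructed straight-line paths."""
    return fz.ArenaSpec(shape="rectangular", width_mm=4000.0, height_mm=4000.0)


@pytest.fixture(scope="session")
def protocol():
    return fz.ProtocolSchedule.default()


def make_traj(x, y, fps=30.0, fly_id="fly", gap_mask=None):
    x = np.asarray(x, float)
    t = np.arange(len(x)) / fps
    return fz.Trajectory(fly_id, fps, t, x, np.asarray(y, float), gap_mask)


def line_traj(speed_mm_s=5.0, duration_s=120.0, fps=30.0, angle_rad=0.0,
              start=(0.0, 0.0)):
    """Constant-velocity straight-line trajectory."""
    n = int(round(duration_s * fps))
    d = speed_mm_s / fps * np.arange(n)
    x = start[0] + d * np.cos(angle_rad)
    y = start[1] + d * np.sin(angle_rad)
    return make_traj(x, y, fps=fps)


@pytest.fixture(scope="session")
def mixed_cohort(arena, protocol):
    """Control-like + seizure-like cohort under the full 10-min protocol,
    mirroring a classifier training corpus drawn from both genotypes."""
    return fz.generate_cohort(
        {"control": fz.scenario("control_like"),
         "glial": fz.scenario("glial_oe_like")},
        n_per_group=20, seed=7, duration_s=600.0,
        arena=arena, protocol=protocol, with_spikes=False)


@pytest.fixture(scope="session")
def mixed_model(mixed_cohort):
    trajs = [r.labeled.trajectory for r in mixed_cohort.records]
    return fz.train_behavior_classifier(trajs, seed=0, n_restarts=5)


@pytest.fixture(scope="session")
def decoded_mixed(mixed_cohort, mixed_model):
    model, fm = mixed_model
    return {r.fly_id: fz.decode_states(model, r.labeled.trajectory, fm)
            for r in mixed_cohort.records}


@pytest.fixture(scope="session")
def separated_cohort(arena):
    """Well-separated kinematics scoring cohort (n = 20 flies)."""
    scen = fz.scenario("well_separated")
    return [fz.generate_trajectory(scen, 180.0, arena, seed=100 + i)
            for i in range(20)]


@pytest.fixture(scope="session")
def separated_model(separated_cohort):
    trajs = [l.trajectory for l in separated_cohort]
    return fz.train_behavior_classifier(trajs, seed=0, n_restarts=5)
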