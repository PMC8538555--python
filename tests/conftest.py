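import warnings

import numpy as np
import pytest

import colonmotion as cm
from colonmotion.experiments import SEGMENT_ALIGNED_TAG_POSITIONS


@pytest.fixture(scope="session")
def geometry():
    return cm.DCMGeometry()


@pytest.fixture(scope="session")
def filled_geometry():
    return cm.DCMGeometry(fill_fraction=0.69, fill_volume=200)


@pytest.fixture(scope="session")
def slow_program():
    return cm.WallMotionProgram(wave_speed=0.4)


@pytest.fixture(scope="session")
def slow_flow(filled_geometry, slow_program):
    """Continuity flow of the slower CPPW with light (LOVIS-like) damping."""
    return cm.continuity_flow(filled_geometry, slow_program,
                              damping_tau=0.1, dt=0.1, t_max=62.0)


@pytest.fixture(scope="session")
def slow_tagged_seq(slow_flow, filled_geometry):
    """Trimmed-resolution tagged rendering of the slow-CPPW phantom."""
    acq = cm.TagAcquisition(voxel_size=1.964, n_frames=100, seed=3,
                            nominal_tag_positions=SEGMENT_ALIGNED_TAG_POSITIONS)
    return cm.render_tagged_sequence(slow_flow, filled_geometry, acq)


@pytest.fixture(scope="session")
def slow_lumen_roi(filled_geometry, slow_tagged_seq):
    return cm.neutral_lumen_roi(filled_geometry, slow_tagged_seq.x_coords,
                                slow_tagged_seq.z_coords)


@pytest.fixture(scope="session")
def slow_tracks(slow_tagged_seq, slow_lumen_roi):
    return cm.track_tags(slow_tagged_seq, slow_lumen_roi)


@pytest.fixture(scope="session")
def factorial_result():
    """2 wave speeds x 2 damping levels, 4 seeded replicates each."""
    conds = [
        cm.Condition(label=f"{p}-{v}", wave_speed=(0.4 if p == "slower" else 0.8),
                     viscosity=v)
        for p in ("slower", "faster") for v in ("LOVIS", "HIVIS")
    ]
    plan = cm.ExperimentPlan.with_seed(conds, replicates=4, base_seed=1,
                                       track_probes=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return cm.run_experiment(plan)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
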