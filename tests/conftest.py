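import warnings

import numpy as np
import pytest

import pufakit as pk

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


def make_volume(intensity, labels, voxel_dims=(1.0, 1.0, 1.0)):
    """Build a (VoxelGrid, TissueLabelVolume) pair from plain arrays."""
    return (
        pk.VoxelGrid(np.asarray(intensity, dtype=float), voxel_dims),
        pk.TissueLabelVolume(np.asarray(labels, dtype=np.int64)),
    )


def all_wm(shape, fill=100.0):
    """All-WM grid at a constant intensity (callers overwrite voxels)."""
    return np.full(shape, fill, dtype=float), np.full(shape, pk.WM, dtype=np.int64)


@pytest.fixture(scope="session")
def eligible_cohort_100():
    """100 screened-eligible participants drawn from the default cohort model."""
    cohort = pk.generate_cohort(pk.CohortSpec(n=140, seed=2))
    report = pk.apply_eligibility(cohort)
    eligible = cohort[cohort["id"].isin(report.eligible_ids)].head(100)
    assert len(eligible) == 100
    return eligible.reset_index(drop=True)


@pytest.fixture(scope="session")
def assigned_cohort(eligible_cohort_100):
    """The eligible cohort with minimization-randomized arms."""
    state = pk.RandomizationState(seed=5)
    assigned = pk.assign_cohort(eligible_cohort_100, state)
    return assigned


@pytest.fixture(scope="session")
def arm_map(assigned_cohort):
    return dict(zip(assigned_cohort["id"], assigned_cohort["arm"]))
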