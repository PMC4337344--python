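import numpy as np
import pytest

from cycleconn import GroundTruth, simulate_study
from cycleconn.pipeline import RunConfig, StudyData, run_ecm_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def coupled_bundle():
    """One default coupled synthetic study, shared across tests."""
    return simulate_study(rng_seed=7)


@pytest.fixture(scope="session")
def null_bundle():
    return simulate_study(truth=GroundTruth(beta=0.0), rng_seed=7)


def roi_rows(bundle, mask):
    """Map ROI name -> in-mask voxel row indices for a study bundle."""
    return {
        name: np.flatnonzero(grid.ravel(order="F")[mask.ordering])
        for name, grid in bundle.rois.items()
    }


def roi_center_mm(bundle, name):
    """World-mm center of an ROI box."""
    grid = bundle.rois[name]
    ijk = np.array(np.nonzero(grid)).mean(axis=1)
    aff = bundle.design.affine
    return (aff @ np.r_[ijk, 1.0])[:3]


@pytest.fixture(scope="session")
def coupled_results(coupled_bundle):
    """Full pipeline run on the coupled study, seed at coupled ROI A center."""
    ctr = roi_center_mm(coupled_bundle, "dlpfc_L")
    cfg = RunConfig(seeds=(("roiA", float(ctr[0]), float(ctr[1]), float(ctr[2])),))
    return run_ecm_study(StudyData.from_bundle(coupled_bundle), cfg)
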