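import numpy as np
import pytest

from voxelfs.phantom import PhantomConfig, generate_dataset
from voxelfs.pipeline import build_cohort_matrix
from voxelfs.volume_io import SubjectVolume, extract_roi, make_folds, normalize_intensity


@pytest.fixture(scope="session")
def cohort():
    """Six phantom subjects under the default study conditions, featurized.

    Returns (X, y, groups, folds): the stacked per-voxel feature matrix, the
    binary labels, per-row subject ids and a 3-fold subject-level split.
    Session-scoped because extraction is the expensive step.
    """
    ds = generate_dataset(6, PhantomConfig(seed=7))
    subjects = [
        SubjectVolume(sid, vol, msk)
        for sid, vol, msk in zip(ds.subject_ids, ds.volumes, ds.masks)
    ]
    X, y, groups = build_cohort_matrix(subjects, roi_margin=2, levels=8)
    folds = make_folds(np.unique(groups), 3, seed=7)
    return X, y, groups, folds


@pytest.fixture(scope="session")
def small_roi():
    """One normalized phantom ROI (SubjectVolume), small enough for per-voxel checks."""
    ds = generate_dataset(1, PhantomConfig(seed=3, shape=(20, 18, 16), semiaxes=(5.0, 4.5, 4.0)))
    sv = SubjectVolume("sub-000", ds.volumes[0], ds.masks[0])
    return normalize_intensity(extract_roi(sv, margin=2))
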