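import numpy as np
import pytest

from geonorm.io import StructureVolumeTable, normalize_by_icv
from geonorm.simulate import CohortSpec, generate_controls


@pytest.fixture(scope="session")
def small_table() -> StructureVolumeTable:
    """3 subjects x 5 structures with hand-checkable values."""
    return StructureVolumeTable(
        subject_id=np.array(["a", "b", "c"]),
        age=np.array([10.0, 40.0, 70.0]),
        sex=np.array(["F", "M", "unknown"]),
        icv=np.array([1.5e6, 1.4e6, 1.6e6]),
        volumes=np.array(
            [
                [15000.0, 7500.0, 30000.0, 1500.0, 150.0],
                [14000.0, 7000.0, 28000.0, 1400.0, 140.0],
                [16000.0, 8000.0, 32000.0, 1600.0, 160.0],
            ]
        ),
        structure_names=("s1", "s2", "s3", "s4", "s5"),
    )


@pytest.fixture(scope="session")
def control_matrix():
    """Normalized percent matrix of a 500-subject synthetic cohort (20
    structures), used by the heavier assessor tests."""
    spec = CohortSpec(n_subjects=500, n_structures=20, seed=11, atlas_seed=1)
    table = generate_controls(spec)
    return normalize_by_icv(table), table
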