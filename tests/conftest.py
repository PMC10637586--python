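import pandas as pd
import pytest

import habitatomics as hb
from habitatomics.preprocess import Volume
from habitatomics.voxel_maps import EntropyConfig, VoxelScaler, build_voxel_table, entropy_map


@pytest.fixture(scope="session")
def default_phantom():
    """One default 3-habitat phantom (volume, mask, truth, spec)."""
    spec = hb.PhantomSpec(seed=7)
    volume, mask, truth = hb.generate_phantom(spec)
    return volume, mask, truth, spec


@pytest.fixture(scope="session")
def phantom_tables(default_phantom):
    """Normalised volume, entropy map and voxel table for the default phantom."""
    volume, mask, truth, spec = default_phantom
    vol = Volume(volume, spec.voxel_spacing)
    msk = Volume(mask, spec.voxel_spacing)
    norm = hb.normalize_grayscale(vol, msk)
    ent = entropy_map(norm, msk, EntropyConfig())
    table = build_voxel_table(norm, ent, msk, "p0")
    return norm, ent, msk, table, truth


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded phantom cohort shared across tests."""
    return hb.generate_cohort(hb.CohortSpec(n_train=12, n_test=6, seed=11))


@pytest.fixture(scope="session")
def cohort_scaler(small_cohort):
    tables = {}
    masks = {}
    for case in small_cohort:
        vol = Volume(case.volume, case.spacing)
        msk = Volume(case.mask, case.spacing)
        norm = hb.normalize_grayscale(vol, msk)
        ent = entropy_map(norm, msk, EntropyConfig())
        tables[case.patient_id] = build_voxel_table(norm, ent, msk, case.patient_id)
        masks[case.patient_id] = msk
    pooled = pd.concat(
        [t.sample(min(200, len(t)), random_state=0) for t in tables.values()],
        ignore_index=True,
    )
    scaler = VoxelScaler().fit(pooled)
    return tables, masks, scaler
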