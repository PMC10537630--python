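import importlib.resources

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from mnqsar import (
    MoleculeRecord,
    PlantedChemotype,
    SyntheticSpec,
    curation,
    generate_feature_dataset,
)


@pytest.fixture(scope="session")
def demo_csv_path(tmp_path_factory):
    ref = importlib.resources.files("mnqsar.data") / "curation_demo.csv"
    with importlib.resources.as_file(ref) as path:
        yield str(path)


@pytest.fixture(scope="session")
def demo_records(demo_csv_path):
    return curation.read_records_csv(demo_csv_path)


@pytest.fixture
def record_factory():
    def make(record_id, smiles, label=1, endpoint="mn_in_vitro", **kw):
        rec = MoleculeRecord(record_id=record_id, smiles=smiles, label=label,
                             endpoint=endpoint, **kw)
        std = curation.standardize_structure(smiles)
        if isinstance(std, curation.Standardized):
            rec.canonical_smiles = std.canonical_smiles
            rec.inchikey = std.inchikey
        return rec

    return make


@pytest.fixture(scope="session")
def planted_dataset():
    """n=1000 in-vitro-like feature dataset with one enriched and one
    label-independent chemotype."""
    spec = SyntheticSpec(
        n_compounds=1000,
        positive_fraction=0.70,
        planted=[
            PlantedChemotype("enriched_ct", 0.30, 0.05),
            PlantedChemotype("balanced_ct", 0.10, 0.10),
        ],
        n_noise_features=10,
        seed=42,
    )
    return generate_feature_dataset(spec)


@pytest.fixture
def fast_rf_factory():
    """Small forest for tests that only need a working learner."""
    return lambda seed: RandomForestClassifier(n_estimators=25, random_state=seed,
                                               n_jobs=1)
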