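import numpy as np
import pandas as pd
import pytest

from lipidflow.core_model import FeatureTable, parse_lipid_name
from lipidflow.simulate import SimConfig, generate_batch


def make_table(intensities, roles, groups=None, names=None, protein=None,
               state="raw"):
    """Build a FeatureTable from a plain intensity matrix and role labels."""
    intensities = np.asarray(intensities, dtype=float)
    n_feat, n_inj = intensities.shape
    assert len(roles) == n_inj
    groups = groups or ["" for _ in roles]
    if protein is None:
        protein = [10.0 if r == "sample" else None for r in roles]
    names = names or [f"PC {32 + 2 * i}:1" for i in range(n_feat)]
    features = pd.DataFrame({
        "feature_id": [f"F{i + 1:03d}" for i in range(n_feat)],
        "mz": np.linspace(500, 900, n_feat),
        "rt": np.linspace(1, 15, n_feat),
        "name": names,
        "id_score": [90.0] * n_feat,
    })
    features["annotation"] = [parse_lipid_name(n) for n in names]
    injections = pd.DataFrame({
        "injection_id": [f"inj{j + 1:02d}" for j in range(n_inj)],
        "role": roles,
        "group": groups,
        "order": np.arange(1, n_inj + 1),
        "protein_ug": protein,
    })
    return FeatureTable(features=features, injections=injections,
                        intensities=intensities, normalization_state=state)


@pytest.fixture
def small_ft():
    """3 features x 8 injections: 1 blank, 3 QCs, 2+2 samples."""
    roles = ["blank", "qc", "sample", "sample", "qc", "sample", "sample", "qc"]
    groups = ["", "", "CF", "CF", "", "H", "H", ""]
    rng = np.random.default_rng(0)
    intensities = rng.uniform(100, 1000, size=(3, 8))
    return make_table(intensities, roles, groups)


@pytest.fixture
def sim_batch():
    cfg = SimConfig(seed=11, n_case=6, n_control=6, n_random_spikes=10,
                    random_spike_fc=4.0, noise_cv=0.1)
    return generate_batch(cfg)
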