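import numpy as np
import pandas as pd
import pytest

from chemstack import (
    CompoundRecord,
    CuratedDataset,
    StackConfig,
    SyntheticSpec,
    fit_stack,
    generate_smiles_dataset,
)
from chemstack.featurize import compute_descriptor_block

SMILES_SAMPLE = [
    "c1ccccc1", "Cc1ccccc1", "CCO", "CC(=O)Oc1ccccc1C(=O)O",
    "c1ccncc1", "C1CCNCC1", "OCC1CCCO1", "Nc1ccc(Cl)cc1",
]


@pytest.fixture
def toy_activity_table(tmp_path):
    """5-row ChEMBL-style table with one row per relation symbol."""
    df = pd.DataFrame(
        {
            "Molecule ChEMBL ID": [f"C{i}" for i in range(5)],
            "Smiles": ["CCO", "CCC", "CCN", "CCCl", "CCBr"],
            "Standard Relation": ["'='", "'<'", "'='", "'>'", "'/'"],
            "Standard Value": [100.0, 200.0, 300.0, 400.0, 500.0],
            "Standard Units": ["nM"] * 5,
            "Assay Type": ["B"] * 5,
        }
    )
    path = tmp_path / "activity.csv"
    df.to_csv(path, index=False)
    return path


def make_records(pic50s, labels=None, smiles=None):
    """Distinct-structure records with the given pIC50 values."""
    base = ["C", "CC", "CCC", "CCCC", "CCCCC", "CCO", "CCCO", "CCCCO",
            "CCN", "CCCN", "CCCCN", "CCOC", "CCCOC", "CCSC"]
    smiles = smiles or base[: len(pic50s)]
    return [
        CompoundRecord(f"R{i}", smi, "=", pic50=p)
        for i, (smi, p) in enumerate(zip(smiles, pic50s))
    ]


@pytest.fixture(scope="session")
def synthetic_dataset() -> CuratedDataset:
    """Small clean synthetic SMILES dataset shared across tests."""
    return generate_smiles_dataset(
        SyntheticSpec(n_active=60, n_inactive=12, marker_effect=1.0,
                      label_noise=0.0, seed=11)
    )


@pytest.fixture(scope="session")
def smiles_model(synthetic_dataset):
    """A small trained SMILES-level stack (fast algorithms only)."""
    families = ("FP4C", "MACCS")
    blocks = {
        fam: compute_descriptor_block(synthetic_dataset.smiles, fam).matrix
        for fam in families
    }
    config = StackConfig(
        algorithms=("KNN", "PLS"), families=families, k=5,
        base_folds=3, selection_folds=3, seed=11,
    )
    model, pfv = fit_stack(blocks, synthetic_dataset.labels, config)
    return model, pfv, synthetic_dataset
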