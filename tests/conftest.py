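"""Shared fixtures: small deterministic synthetic datasets."""
import numpy as np
import pandas as pd
import pytest

from methdmr.datatypes import MethylationDataset
from methdmr.simulate import generate_manifest, simulate_dataset


@pytest.fixture(scope="session")
def small_manifest():
    return generate_manifest(400, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_manifest):
    ds, _ = simulate_dataset(small_manifest, n_cases=20, n_controls=20, seed=11)
    return ds


@pytest.fixture(scope="session")
def medium_dataset():
    man = generate_manifest(2000, seed=7)
    ds, _ = simulate_dataset(man, n_cases=30, n_controls=30, seed=7)
    return ds


def make_dataset(beta: np.ndarray, detection_p=None, status=None) -> MethylationDataset:
    """Wrap a raw beta matrix in a minimal valid dataset."""
    n_probes, n_samples = beta.shape
    manifest = pd.DataFrame(
        {
            "probe_id": [f"p{i:05d}" for i in range(n_probes)],
            "chrom": "chr1",
            "pos": np.arange(1, n_probes + 1) * 100,
            "island_relation": "Sea",
            "gene_feature": "Body",
            "nearest_gene": [f"G{i // 10}" for i in range(n_probes)],
            "dnase_hs": False,
        }
    )
    if status is None:
        status = ["case"] * (n_samples // 2) + ["control"] * (n_samples - n_samples // 2)
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in range(n_samples)],
            "status": status,
            "cohort": ["adult" if i % 2 else "adolescent" for i in range(n_samples)],
            "age": 30.0 + np.arange(n_samples) % 7,
            "sex": ["F" if i % 3 else "M" for i in range(n_samples)],
            "chip": [f"chip{i // 12:02d}" for i in range(n_samples)],
            "chip_position": [f"R{i % 12:02d}C01" for i in range(n_samples)],
        }
    )
    ids = manifest["probe_id"].to_numpy()
    sids = samples["sample_id"].to_numpy()
    det = None
    if detection_p is not None:
        det = pd.DataFrame(detection_p, index=ids, columns=sids)
    return MethylationDataset(
        manifest=manifest,
        samples=samples,
        beta=pd.DataFrame(beta, index=ids, columns=sids),
        detection_p=det,
    )
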