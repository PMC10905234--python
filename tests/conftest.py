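import numpy as np
import pandas as pd
import pytest

from scatdiet.io import ReadCountTable
from scatdiet.simulate import CONTAMINANT_TAXA, SimConfig, simulate_experiment


def make_table(counts, sample_ids, otu_ids, rookery=None, is_control=None, assay=None,
               scat_id=None):
    """Small helper to assemble a ReadCountTable from plain lists."""
    n = len(sample_ids)
    meta = pd.DataFrame(
        {
            "rookery": rookery if rookery is not None else ["R1"] * n,
            "is_negative_control": is_control if is_control is not None else [False] * n,
            "assay": assay if assay is not None else ["pooled"] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if scat_id is not None:
        meta["scat_id"] = scat_id
    counts = pd.DataFrame(
        np.asarray(counts, dtype=np.int64), index=meta.index, columns=otu_ids
    )
    return ReadCountTable(counts, meta)


@pytest.fixture(scope="session")
def default_blacklist():
    return tuple(lineage[0] for lineage in CONTAMINANT_TAXA)


@pytest.fixture(scope="session")
def synthetic_experiment():
    """One study-shaped synthetic experiment shared across tests."""
    cfg = SimConfig(seed=42)
    return cfg, simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noise_free_experiment():
    """Experiment with every contamination channel switched off."""
    cfg = SimConfig(
        seed=7,
        tag_switch_rate=0.0,
        contaminant_read_fraction=0.0,
        control_predator_fraction=0.0,
        n_low_identity_otus=0,
        n_no_hit_otus=0,
    )
    return cfg, simulate_experiment(cfg)
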