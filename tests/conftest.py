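import numpy as np
import pandas as pd
import pytest

from erphagyquant import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_proteins=60, replicates_per_genotype=3, seed=11)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """No QC failures: the PSM table rolls up to the protein matrix exactly."""
    return SimConfig(n_proteins=80, frac_fail_snr=0.0, frac_fail_purity=0.0, seed=21)


@pytest.fixture(scope="session")
def clean_experiment(clean_config):
    return simulate_experiment(clean_config)


@pytest.fixture
def toy_psms():
    """Two proteins, three channels, hand-enumerable QC attributes."""
    return pd.DataFrame({
        "protein_id": ["P1", "P1", "P2", "P2", "P2"],
        "peptide": ["P1.a", "P1.b", "P2.a", "P2.b", "P2.c"],
        "channel_001": [10.0, 5.0, 8.0, 1.0, 1.0],
        "channel_002": [20.0, 10.0, 16.0, 2.0, 2.0],
        "channel_003": [30.0, 15.0, 24.0, 3.0, 3.0],
        "summed_snr": [500.0, 300.0, 250.0, 400.0, 600.0],
        "isolation_purity": [0.9, 0.8, 0.7, 0.6, 0.95],
    })


@pytest.fixture
def five_genotype_design():
    """One plex: 5 genotypes x 3 replicates, channels in series order."""
    rows = []
    ch = 1
    for g in ("WT", "DKO", "TKO", "QKO", "PKO"):
        for r in (1, 2, 3):
            rows.append({"channel": f"channel_{ch:03d}", "genotype": g,
                         "replicate": r, "condition": "day12"})
            ch += 1
    return pd.DataFrame(rows).set_index("channel")


def staircase_matrix(genotype_means, design, proteins=("P1",)):
    """Noise-free centred matrix with given per-genotype values."""
    vals = {ch: genotype_means[design.loc[ch, "genotype"]] for ch in design.index}
    return pd.DataFrame([list(vals.values())] * len(proteins),
                        index=pd.Index(proteins, name="protein_id"),
                        columns=design.index, dtype=float)
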