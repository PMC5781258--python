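import numpy as np
import pytest

from coreshift import OtuTable, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic experiment (50 OTUs, 4 x 8 samples), shared."""
    return simulate_dataset(SimConfig(seed=42))


@pytest.fixture
def tiny_table():
    """5 OTUs x 4 samples with taxonomy and metadata, hand-sized."""
    counts = np.array([
        [10, 0, 3, 7],
        [5, 5, 5, 5],
        [0, 20, 1, 0],
        [2, 2, 0, 9],
        [8, 1, 6, 4],
    ])
    otus = [f"OTU_{i}" for i in range(5)]
    samples = ["s1", "s2", "s3", "s4"]
    taxonomy = {
        "OTU_0": "k__Bacteria; p__Proteobacteria; c__Alphaproteobacteria",
        "OTU_1": "k__Bacteria; p__Bacteroidetes; c__Cytophagia",
        "OTU_2": "k__Bacteria; p__Chloroplast; c__Chloroplast",
        "OTU_3": "k__Bacteria; p__Firmicutes; c__Bacilli",
        "OTU_4": "k__Bacteria; p__Actinobacteria; c__Actinobacteria",
    }
    metadata = {s: {"treatment": t, "compartment": "root"}
                for s, t in zip(samples, ["control", "control", "copper", "copper"])}
    return OtuTable(counts, otus, samples, taxonomy, metadata)
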