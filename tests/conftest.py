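import numpy as np
import pytest

from eqdtu.formats_io import SampleTable, TranscriptAnnotation, TranscriptRecord
from eqdtu.simulate import SimConfig, simulate_experiment_design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_annotation():
    """Two genes: gA with two isoforms sharing exon 1, gB single-isoform."""
    return TranscriptAnnotation(
        records=[
            TranscriptRecord("tA1", "gA", "chr1", "+", ((0, 100), (200, 300))),
            TranscriptRecord("tA2", "gA", "chr1", "+", ((0, 100), (400, 500))),
            TranscriptRecord("tB1", "gB", "chr1", "+", ((1000, 1150),)),
        ]
    )


@pytest.fixture
def tiny_config():
    """A small but fully featured simulated design (fast to generate)."""
    return SimConfig(n_genes=8, depth=20_000, seed=7, k=15)


@pytest.fixture
def tiny_design(tiny_config):
    return simulate_experiment_design(tiny_config)


@pytest.fixture
def sample_table_3v3():
    return SampleTable(
        rows=[
            ("S1_rep1", "S1", ""),
            ("S1_rep2", "S1", ""),
            ("S1_rep3", "S1", ""),
            ("S2_rep1", "S2", ""),
            ("S2_rep2", "S2", ""),
            ("S2_rep3", "S2", ""),
        ]
    )


def random_sequences(rng, n, length_range=(60, 200)):
    """Random ACGT transcript sequences keyed t1..tn."""
    bases = np.array(list("ACGT"))
    return {
        f"t{i + 1}": "".join(
            rng.choice(bases, size=rng.integers(length_range[0], length_range[1] + 1))
        )
        for i in range(n)
    }
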