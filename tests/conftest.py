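import numpy as np
import pandas as pd
import pytest

from metscreen.io import build_library, build_sample_meta, CountMatrix


@pytest.fixture
def toy_library():
    """Two genes x two guides plus two controls."""
    df = pd.DataFrame(
        {
            "guide_id": ["gA1", "gA2", "gB1", "gB2", "c1", "c2"],
            "gene": ["GENEA", "GENEA", "GENEB", "GENEB", "CONTROL", "CONTROL"],
            "protospacer": [
                "ACGTACGTACGTACGTACGT",
                "TTTTACGTACGTACGTACGT",
                "GGGGACGTACGTACGTACGT",
                "CCCCACGTACGTACGTACGT",
                "AAAAAAAAAACCCCCCCCCC",
                "GGGGGGGGGGTTTTTTTTTT",
            ],
        }
    )
    return build_library(df)


@pytest.fixture
def toy_meta():
    return build_sample_meta(
        pd.DataFrame(
            {
                "sample_id": ["T0", "lung_m1", "lung_m2", "brain_m1", "brain_m2"],
                "mouse_id": ["pool", "m1", "m2", "m1", "m2"],
                "tissue": ["T0", "lung", "lung", "brain", "brain"],
            }
        )
    )


@pytest.fixture
def toy_counts(toy_library):
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(
        rng.integers(10, 200, size=(6, 5)),
        index=toy_library.guide_ids,
        columns=["T0", "lung_m1", "lung_m2", "brain_m1", "brain_m2"],
    ).astype(np.int64)
    return CountMatrix(counts=counts)


def write_fastq(path, seqs):
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@read{i}\n{s}\n+\n{'I' * len(s)}\n")
    return path
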