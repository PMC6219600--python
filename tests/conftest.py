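import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from polydart.io import MarkerMatrix, SamplePanel, SnpMatrix

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_panel(records):
    """Build a SamplePanel from (sample_id, species, ploidy, formula, role) tuples."""
    df = pd.DataFrame(records, columns=["sample_id", "species", "ploidy",
                                        "genome_formula", "role"])
    return SamplePanel(df.set_index("sample_id"))


def make_markers(rows, samples, chromosome=None):
    """MarkerMatrix from a {marker_id: [scores...]} dict (None = missing)."""
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=samples,
                                    dtype=float)
    scores.index.name = "marker_id"
    chrom = pd.Series(chromosome) if chromosome is not None else None
    return MarkerMatrix(scores, chrom)


def make_snps(rows, samples, chromosome=None):
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=samples,
                                    dtype=float)
    scores.index.name = "marker_id"
    chrom = pd.Series(chromosome) if chromosome is not None else None
    return SnpMatrix(scores, chrom)


def random_marker_matrix(rng, n_markers, samples, missing_rate=0.1):
    scores = rng.integers(0, 2, size=(n_markers, len(samples))).astype(float)
    mask = rng.random(scores.shape) < missing_rate
    scores[mask] = np.nan
    df = pd.DataFrame(scores, columns=samples,
                      index=pd.Index([f"m{i:04d}" for i in range(n_markers)],
                                     name="marker_id"))
    return MarkerMatrix(df)


@pytest.fixture
def three_sample_panel():
    return make_panel([
        ("s1", "spA", 2, "A", "diploid_analyzer"),
        ("s2", "spB", 2, "B", "diploid_analyzer"),
        ("s3", "spC", 2, "C", "diploid_analyzer"),
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
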