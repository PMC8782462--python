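import numpy as np
import pandas as pd
import pytest

from introflow import CountMatrix, FixtureConfig, TFSpec, generate_fixture


@pytest.fixture
def toy_counts() -> CountMatrix:
    """Four genes (one intronless) x three samples, hand-sized counts."""
    genes = ["g1", "g2", "g3", "g4"]
    intron = pd.DataFrame(
        {"s1": [10, 5, 0, 20], "s2": [4, 8, 0, 2], "s3": [7, 1, 0, 6]}, index=genes
    )
    exon = pd.DataFrame(
        {"s1": [90, 45, 30, 100], "s2": [36, 60, 12, 18], "s3": [63, 9, 21, 54]},
        index=genes,
    )
    has_intron = pd.Series([True, True, False, True], index=genes)
    return CountMatrix(intron=intron, exon=exon, has_intron=has_intron)


@pytest.fixture(scope="session")
def small_fixture():
    """One rhythmic TF (peak 6 h, long-lived targets) and one flat TF."""
    cfg = FixtureConfig(
        tf_specs=(
            TFSpec("TF1", rhythmic=True, phase=6.0, halflife_min=600.0, module=1),
            TFSpec("TF2", rhythmic=False, phase=0.0, halflife_min=100.0),
        ),
        targets_per_tf=6,
        intronless_per_tf=1,
        n_offtarget_genes=20,
        replicates=4,
        seed=11,
    )
    return generate_fixture(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
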