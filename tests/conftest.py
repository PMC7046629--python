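import numpy as np
import pandas as pd
import pytest

from astrotf.expression import CountMatrix
from astrotf.motifs import Pwm
from astrotf.pipeline import PipelineConfig, analyze
from astrotf.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study (seed 42): counts, annotation, sequences,
    motif library and ground truth."""
    cfg = SimConfig(seed=42)
    cm, annotation, contigs, motifs, truth = simulate_dataset(cfg)
    return {"cfg": cfg, "cm": cm, "annotation": annotation, "contigs": contigs,
            "motifs": motifs, "truth": truth}


@pytest.fixture(scope="session")
def default_result(default_dataset):
    """Full pipeline result on the default synthetic study."""
    d = default_dataset
    return analyze(d["cm"], d["contigs"], d["annotation"], d["motifs"],
                   PipelineConfig(seed=42), truth=d["truth"])


@pytest.fixture
def small_cm():
    """Tiny 6-gene, 2-region count matrix with hand-set values."""
    counts = pd.DataFrame(
        {
            "A_rep1": [10, 30, 60, 0, 5, 100],
            "A_rep2": [12, 28, 55, 0, 6, 90],
            "B_rep1": [11, 29, 58, 0, 50, 10],
            "B_rep2": [9, 31, 62, 0, 55, 12],
        },
        index=[f"g{i}" for i in range(1, 7)],
    )
    return CountMatrix(counts=counts,
                       sample_region={s: s.split("_")[0] for s in counts.columns})


@pytest.fixture
def sharp_pwm():
    """Near-deterministic 8-mer PWM with non-palindromic consensus AACGTGAC."""
    matrix = np.full((8, 4), 0.01)
    for i, base in enumerate("AACGTGAC"):
        matrix[i, "ACGT".index(base)] = 0.97
    return Pwm(name="sharp", matrix=matrix)


@pytest.fixture(scope="session")
def default_promoters(default_result):
    return default_result.promoters


@pytest.fixture(scope="session")
def default_hits(default_dataset, default_promoters):
    """Consensus-mode hit map of the full motif library over the 2 kb windows."""
    from astrotf.motifs import library_hits
    return library_hits(default_dataset["motifs"], default_promoters, mode="consensus")
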