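import numpy as np
import pandas as pd
import pytest

from nutrinet.pipeline import PipelineConfig, run_contrast
from nutrinet.simulate import SimulationConfig, simulate_dataset, write_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset under the default study conditions."""
    cfg = SimulationConfig(seed=11)
    matrix, truth, phen = simulate_dataset(cfg)
    return cfg, matrix, truth, phen


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, default_dataset):
    cfg, matrix, truth, phen = default_dataset
    d = tmp_path_factory.mktemp("synthetic")
    write_dataset(d, matrix, truth, phen, cfg)
    return d


def make_pipeline_config(d, outdir) -> PipelineConfig:
    return PipelineConfig(
        counts=str(d / "counts.tsv"),
        biotypes=str(d / "biotypes.tsv"),
        groups=str(d / "groups.tsv"),
        utr_fasta=str(d / "utrs.fa"),
        mirna_fasta=str(d / "mirna_mature.fa"),
        phenotypes=str(d / "phenotypes.csv"),
        outdir=str(outdir),
    )


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory, dataset_dir):
    """Full contrast run on the default synthetic dataset."""
    out = tmp_path_factory.mktemp("run")
    return run_contrast(make_pipeline_config(dataset_dir, out))


@pytest.fixture
def toy_matrix():
    """Tiny valid expression matrix for preprocessing unit tests."""
    from nutrinet.matrix import ExpressionMatrix

    counts = pd.DataFrame(
        {"s1": [10, 20, 5, 0], "s2": [12, 18, 6, 1]},
        index=["g1", "g2", "g3", "g4"],
    )
    biotype = pd.Series(["mRNA", "mRNA", "miRNA", "lincRNA"], index=counts.index)
    group = pd.Series(["a", "b"], index=counts.columns)
    return ExpressionMatrix(counts=counts, biotype=biotype, group=group)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
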