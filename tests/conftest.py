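import numpy as np
import pandas as pd
import pytest

from batchrank import Experiment, MetaExperiment, SimConfig, merge_experiments
from batchrank.simulate import simulate_microarray_meta, simulate_count_meta


def make_meta(values, batch_labels, bio_labels=None, technology="microarray",
              strict=True) -> MetaExperiment:
    """Build a MetaExperiment from a plain array and label lists."""
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    if bio_labels is None:
        bio_labels = ["x"] * values.shape[1]
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    if technology == "rnaseq":
        matrix = matrix.round().astype(np.int64)
    return MetaExperiment(
        matrix=matrix,
        batch=pd.Series(batch_labels, index=samples),
        bio=pd.Series(bio_labels, index=samples),
        technology=technology,
        strict=strict,
    )


@pytest.fixture(scope="session")
def micro_sim():
    """Two-batch microarray simulation with a clear batch effect."""
    cfg = SimConfig(n_genes=300, seed=11,
                    batches=[{"id": "A", "n_samples": 10}, {"id": "B", "n_samples": 10}])
    experiments, gt = simulate_microarray_meta(cfg)
    meta = merge_experiments(experiments, "disease")
    return experiments, gt, meta


@pytest.fixture(scope="session")
def count_sim():
    """Two-batch RNA-seq simulation (2-fold batch shift on 10% of genes)."""
    cfg = SimConfig(technology="rnaseq", n_genes=400, seed=7,
                    batches=[{"id": "A", "n_samples": 10}, {"id": "B", "n_samples": 10}])
    experiments, gt = simulate_count_meta(cfg)
    meta = merge_experiments(experiments, "stimulant")
    return experiments, gt, meta


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
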