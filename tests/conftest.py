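import numpy as np
import pandas as pd
import pytest

import polysomely as pl


@pytest.fixture(scope="session")
def small_experiment():
    """One-cell-line synthetic experiment with all regulation classes."""
    cfg = pl.SimConfig(
        n_genes=800,
        cell_lines=("MCF10A",),
        treatments=("N", "H"),
        replicates=3,
        class_proportions={
            "null": 0.7, "transcriptional": 0.1, "translational": 0.1, "buffered": 0.1
        },
        dispersion=0.05,
        library_size_mean=4e5,
        seed=42,
    )
    return pl.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def small_pipeline_inputs(small_experiment, tmp_path_factory):
    """Counts + design + GMT files for the small experiment, on disk."""
    d = tmp_path_factory.mktemp("fixture")
    pl.write_counts(small_experiment.counts, d / "counts.tsv")
    pl.write_design(small_experiment.design, d / "design.tsv")
    genes = list(small_experiment.counts.gene_ids)
    rng = np.random.default_rng(7)
    with open(d / "sets.gmt", "w") as fh:
        for i in range(5):
            members = rng.choice(genes, size=30, replace=False)
            fh.write(f"SET{i}\tsynthetic set {i}\t" + "\t".join(members) + "\n")
    return {"counts": d / "counts.tsv", "design": d / "design.tsv", "gmt": d / "sets.gmt"}


@pytest.fixture
def toy_counts():
    df = pd.DataFrame(
        {
            "s1": [10, 200, 30, 0, 5, 120],
            "s2": [12, 180, 25, 1, 7, 130],
            "s3": [95, 210, 28, 0, 6, 110],
        },
        index=pd.Index([f"g{i}" for i in range(6)], name="gene_id"),
    )
    return pl.CountMatrix(df)
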