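import numpy as np
import pandas as pd
import pytest

from polyshock.iolayer import ExpressionDataset
from polyshock.synthetic_data import (
    HomeologSimConfig,
    SimConfig,
    simulate_expression,
    simulate_homeolog,
)


def make_dataset(gene_ids, group_values, tissue="leaf"):
    """Build a small ExpressionDataset from {(role, generation): genes x reps}."""
    columns = {}
    rows = []
    for (role, gen), mat in group_values.items():
        mat = np.asarray(mat, dtype=float)
        for r in range(mat.shape[1]):
            gen_part = f"_{gen}" if gen else ""
            sid = f"{role}_{tissue}{gen_part}_r{r + 1}"
            columns[sid] = mat[:, r]
            rows.append(
                {
                    "sample_id": sid,
                    "role": role,
                    "tissue": tissue,
                    "generation": gen,
                    "replicate": r + 1,
                }
            )
    values = pd.DataFrame(columns, index=pd.Index(list(gene_ids), name="gene_id"))
    manifest = pd.DataFrame(rows).set_index("sample_id", drop=False)
    manifest.index.name = None
    return ExpressionDataset(values=values, manifest=manifest)


@pytest.fixture(scope="session")
def noisy_sim():
    """One realistic-noise simulated study (leaf only) shared across tests."""
    cfg = SimConfig(n_genes=800, tissues=("leaf",), seed=101)
    dataset, truth = simulate_expression(cfg)
    homeo = simulate_homeolog(cfg, truth)
    return cfg, dataset, truth, homeo


@pytest.fixture(scope="session")
def zero_sim():
    """A noise-free simulated study: classification must be exact."""
    cfg = SimConfig(
        n_genes=300,
        tissues=("leaf",),
        replicate_sd=0.0,
        homeolog=HomeologSimConfig(noise_sd=0.0),
        seed=7,
    )
    dataset, truth = simulate_expression(cfg)
    homeo = simulate_homeolog(cfg, truth)
    return cfg, dataset, truth, homeo
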