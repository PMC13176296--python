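"""Shared fixtures: a small planted cohort carried through the pipeline stages."""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import twascell as tc


def adata_from_dense(x, genes=None, cells=None, layer="lognorm", obs=None) -> ad.AnnData:
    """Build a minimal AnnData from a dense array for oracle tests."""
    x = np.asarray(x, dtype=float)
    n, g = x.shape
    genes = list(genes) if genes is not None else [f"g{i:03d}" for i in range(g)]
    cells = list(cells) if cells is not None else [f"c{i:03d}" for i in range(n)]
    obs_df = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    if obs is not None:
        for k, v in obs.items():
            obs_df[k] = v
    adata = ad.AnnData(X=sp.csr_matrix(x), obs=obs_df,
                       var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    adata.uns["layer"] = layer
    return adata


SMALL_CONFIG = tc.SimConfig(
    n_patients_case=4,
    n_patients_control=4,
    cells_per_patient=150,
    n_genes=400,
    n_risk_genes=30,
    n_signature_genes=6,
    seed=11,
)


@pytest.fixture(scope="session")
def small_sim() -> tc.SimulatedDataset:
    return tc.simulate_dataset(SMALL_CONFIG)


@pytest.fixture(scope="session")
def lognorm_sim(small_sim) -> ad.AnnData:
    return tc.lognormalize(small_sim.adata)


@pytest.fixture(scope="session")
def panel_sim(small_sim, lognorm_sim) -> tc.ActivityPanel:
    return tc.score_panel(lognorm_sim, small_sim.truth_risk_genes, seed=11)


@pytest.fixture(scope="session")
def labeling_sim(panel_sim) -> tc.ActivityLabeling:
    return tc.stratify_quartiles(panel_sim.scoring)


@pytest.fixture(scope="session")
def task_sim(small_sim, lognorm_sim, labeling_sim) -> tc.ClassificationTask:
    return tc.build_task(lognorm_sim, labeling_sim, small_sim.truth_risk_genes)
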