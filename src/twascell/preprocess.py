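"""Quality control, normalization, HVG selection, and PCA.

QC keeps cells with min_genes <= detected genes <= max_genes and
mitochondrial fraction <= max_mito — the boundary values themselves
survive, matching strict "<"/">" filter wording. Normalization is the
usual per-cell total scaling followed by ln(1+x).
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA


class MissingCovariateError(KeyError):
    pass


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_genes: int = 6000,
    max_mito: float = 0.15,
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Filter cells on detected-gene count and mitochondrial fraction.

    Returns the filtered dataset and a per-criterion report of how many
    cells each rule removed (a cell can fail several rules).
    """
    for col in ("n_genes_detected", "pct_mito"):
        if col not in adata.obs.columns:
            raise MissingCovariateError(f"cell metadata lacks required column {col!r}")
    detected = adata.obs["n_genes_detected"].to_numpy()
    mito = adata.obs["pct_mito"].to_numpy()

    too_few = detected < min_genes
    too_many = detected > max_genes
    high_mito = mito > max_mito
    keep = ~(too_few | too_many | high_mito)

    report = pd.DataFrame(
        {
            "criterion": ["n_genes_detected < min", "n_genes_detected > max", "pct_mito > max"],
            "threshold": [min_genes, max_genes, max_mito],
            "cells_removed": [int(too_few.sum()), int(too_many.sum()), int(high_mito.sum())],
        }
    )
    report.attrs["cells_in"] = adata.n_obs
    report.attrs["cells_out"] = int(keep.sum())
    return adata[keep].copy(), report


def lognormalize(adata: ad.AnnData, scale_total: float = 1e4) -> ad.AnnData:
    """Per-cell total-count scaling to ``scale_total`` then ln(1 + x)."""
    if adata.uns.get("layer") != "counts":
        raise ValueError(f"expected a raw-count layer, found {adata.uns.get('layer')!r}")
    x = sp.csr_matrix(adata.X, dtype=float)
    totals = np.asarray(x.sum(axis=1)).ravel()
    if np.any(totals == 0):
        bad = adata.obs_names[np.flatnonzero(totals == 0)[0]]
        raise ValueError(f"cell {bad!r} has zero total counts; remove it in QC first")
    scaled = sp.diags(scale_total / totals) @ x
    scaled.data = np.log1p(scaled.data)
    out = adata.copy()
    out.X = scaled.tocsr()
    out.uns["layer"] = "lognorm"
    return out


def select_hvg(adata: ad.AnnData, n: int = 2000) -> list[str]:
    """Top-n highly variable genes by variance of log-normalized expression.

    Deterministic: ties broken by gene id. Operates on the log-normalized
    layer (raw counts are normalized on a copy first).
    """
    if n > adata.n_vars:
        raise ValueError(f"requested {n} HVGs but only {adata.n_vars} genes present")
    data = adata if adata.uns.get("layer") == "lognorm" else lognormalize(adata)
    x = sp.csr_matrix(data.X)
    mean = np.asarray(x.mean(axis=0)).ravel()
    meansq = np.asarray(x.multiply(x).mean(axis=0)).ravel()
    var = meansq - mean**2
    order = pd.DataFrame({"gene": data.var_names, "var": var}).sort_values(
        ["var", "gene"], ascending=[False, True], kind="stable"
    )
    return order["gene"].head(n).tolist()


def pca_embed(adata: ad.AnnData, genes: list[str], d: int = 50) -> np.ndarray:
    """PCA of standardized (clipped at ±10) expression over ``genes``.

    Component signs are fixed so each component's largest-magnitude gene
    loading is positive, making the embedding reproducible.
    """
    if d > min(adata.n_obs, len(genes)):
        raise ValueError(
            f"d={d} exceeds min(n_cells={adata.n_obs}, n_genes={len(genes)})"
        )
    sub = adata[:, genes]
    x = np.asarray(sp.csr_matrix(sub.X).todense(), dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    x = np.clip((x - mu) / sd, -10.0, 10.0)
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(x)
    flip = np.sign(pca.components_[np.arange(d), np.abs(pca.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return coords * flip
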