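"""Readers and writers for the pipeline's on-disk formats.

Expression travels as Matrix Market (cells x genes) plus barcodes.tsv /
features.tsv / cells.tsv metadata, or as a single dense TSV. Gene sets use
GMT. TWAS fixtures are three TSVs (weights, LD, GWAS z-scores).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .genesets import GeneSet

CELL_META_COLUMNS = ("patient", "group", "cell_type", "n_genes_detected", "pct_mito")


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


# ---------------------------------------------------------------- expression


def write_expression(adata: ad.AnnData, outdir: str | Path) -> Path:
    """Write an expression dataset as matrix.mtx + barcodes/features/cells TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    x = sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), x)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.var_names).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    meta = adata.obs.reset_index(names="cell_id")
    meta.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    return outdir


def read_expression(
    path: str | Path,
    layer: str = "counts",
) -> ad.AnnData:
    """Read a dataset written by :func:`write_expression`, or a dense TSV.

    ``path`` is either a directory holding matrix.mtx/barcodes.tsv/
    features.tsv/cells.tsv, or a dense TSV file (cells in rows, first
    column ``cell_id``, remaining columns gene identifiers; an optional
    sibling cells.tsv provides metadata).
    """
    path = Path(path)
    if path.is_dir():
        try:
            x = scipy.io.mmread(str(path / "matrix.mtx"))
        except Exception as exc:  # scipy raises ValueError on bad headers
            raise FormatError(f"malformed Matrix Market file {path / 'matrix.mtx'}: {exc}") from exc
        x = sp.csr_matrix(x)
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
        if len(barcodes) != x.shape[0]:
            raise FormatError(
                f"barcodes count ({len(barcodes)}) != matrix rows ({x.shape[0]})"
            )
        if len(features) != x.shape[1]:
            raise FormatError(
                f"features count ({len(features)}) != matrix columns ({x.shape[1]})"
            )
        meta_path = path / "cells.tsv"
        obs = pd.read_csv(meta_path, sep="\t").set_index("cell_id") if meta_path.exists() else None
        adata = _assemble(x, barcodes, features, obs, layer)
    else:
        dense = pd.read_csv(path, sep="\t")
        if dense.columns[0] != "cell_id":
            raise FormatError("dense TSV must have 'cell_id' as its first column")
        dense = dense.set_index("cell_id")
        barcodes = pd.Series(dense.index.astype(str))
        features = pd.Series(dense.columns.astype(str))
        meta_path = path.parent / "cells.tsv"
        obs = pd.read_csv(meta_path, sep="\t").set_index("cell_id") if meta_path.exists() else None
        adata = _assemble(sp.csr_matrix(dense.to_numpy(dtype=float)), barcodes, features, obs, layer)
    return adata


def _assemble(x, barcodes, features, obs, layer) -> ad.AnnData:
    if features.duplicated().any():
        dup = features[features.duplicated()].iloc[0]
        raise FormatError(f"duplicate gene ids in features (e.g. {dup!r})")
    if barcodes.duplicated().any():
        dup = barcodes[barcodes.duplicated()].iloc[0]
        raise FormatError(f"duplicate cell barcodes (e.g. {dup!r})")
    adata = ad.AnnData(X=x, obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
                       var=pd.DataFrame(index=pd.Index(features, name="gene")))
    if obs is not None:
        if len(obs) != adata.n_obs:
            raise FormatError(
                f"cell metadata rows ({len(obs)}) != matrix rows ({adata.n_obs})"
            )
        obs.index = obs.index.astype(str)
        missing = set(adata.obs_names) - set(obs.index)
        if missing:
            raise FormatError(f"cell metadata missing barcodes, e.g. {sorted(missing)[:3]}")
        adata.obs = obs.loc[adata.obs_names]
    adata.uns["layer"] = layer
    return adata


def write_dense_tsv(adata: ad.AnnData, path: str | Path) -> Path:
    path = Path(path)
    dense = pd.DataFrame(
        np.asarray(sp.csr_matrix(adata.X).todense()),
        index=pd.Index(adata.obs_names, name="cell_id"),
        columns=adata.var_names,
    )
    dense.to_csv(path, sep="\t")
    return path


# ----------------------------------------------------------------------- GMT


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Parse a GMT file: one set per line, name <tab> description <tab> genes."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            seen: dict[str, None] = {}
            for g in genes:
                if g in seen:
                    warnings.warn(f"{path}:{lineno}: duplicate gene {g!r} in set {name!r} dropped")
                seen[g] = None
            sets.append(GeneSet(name, tuple(seen), desc))
    return sets


def write_gmt(sets: list[GeneSet] | GeneSet, path: str | Path) -> Path:
    if isinstance(sets, GeneSet):
        sets = [sets]
    path = Path(path)
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.genes]) + "\n")
    return path


# -------------------------------------------------------------- TWAS fixture


def write_twas_fixture(fixture, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fixture.weights.to_csv(outdir / "weights.tsv", sep="\t", index=False)
    fixture.ld.to_csv(outdir / "ld.tsv", sep="\t", index_label="snp")
    fixture.gwas.to_csv(outdir / "gwas.tsv", sep="\t", index=False)
    return outdir


def read_twas_fixture(outdir: str | Path):
    from .simulate import TwasFixture

    outdir = Path(outdir)
    weights = pd.read_csv(outdir / "weights.tsv", sep="\t")
    ld = pd.read_csv(outdir / "ld.tsv", sep="\t", index_col="snp")
    gwas = pd.read_csv(outdir / "gwas.tsv", sep="\t")
    if list(ld.index) != list(ld.columns):
        raise FormatError("LD matrix rows and columns disagree")
    unknown = set(weights["snp"]) - set(ld.index)
    if unknown:
        raise FormatError(f"weights reference SNPs absent from LD, e.g. {sorted(unknown)[:3]}")
    return TwasFixture(weights=weights, ld=ld, gwas=gwas, truth_causal_genes=())
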