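"""Synthetic data with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial counts with log-normal library sizes over
patients in two groups, a planted "active" subpopulation with elevated
expression of a designated risk-gene set, a small signature subset with
larger effects, per-cell QC covariates, and summary-statistics TWAS
fixtures (per-gene eQTL weights, block AR(1) LD, GWAS z-scores) with
planted causal genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genesets import GeneSet


class SimConfigError(ValueError):
    """A SimConfig field violates its constraint; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    Defaults describe a 10 case + 10 control cohort at desk scale: 200
    cells per patient, 3000 genes of which 125 form the risk set and 6 of
    those the strong-effect signature. ``active_fraction_*`` are the
    per-patient prevalences of the high-activity subpopulation;
    ``effect_log2fc`` / ``signature_log2fc`` the log2 fold-changes applied
    to risk / signature genes inside active cells.
    """

    n_patients_case: int = 10
    n_patients_control: int = 10
    cells_per_patient: int = 200
    n_genes: int = 3000
    n_risk_genes: int = 125
    n_signature_genes: int = 6
    active_fraction_case: float = 0.35
    active_fraction_control: float = 0.15
    effect_log2fc: float = 0.5
    signature_log2fc: float = 2.0
    nb_dispersion: float = 0.4
    libsize_sigma: float = 0.35
    mito_mean: float = 0.06
    mito_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_patients_case", "n_patients_control", "cells_per_patient",
                     "n_genes", "n_risk_genes", "n_signature_genes"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 1):
                raise SimConfigError(f"{name} must be an integer >= 1, got {v!r}")
        if not self.n_signature_genes <= self.n_risk_genes <= self.n_genes:
            raise SimConfigError(
                "require n_signature_genes <= n_risk_genes <= n_genes, got "
                f"n_signature_genes={self.n_signature_genes}, "
                f"n_risk_genes={self.n_risk_genes}, n_genes={self.n_genes}"
            )
        for name in ("active_fraction_case", "active_fraction_control",
                     "mito_mean", "mito_sd"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1], got {v!r}")
        for name in ("nb_dispersion", "libsize_sigma"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive, got {getattr(self, name)!r}")


@dataclass
class SimulatedDataset:
    """A simulated cohort plus its planted truth."""

    adata: ad.AnnData
    truth_active_cells: frozenset[str]
    truth_risk_genes: GeneSet
    truth_signature_genes: GeneSet
    config: SimConfig


@dataclass
class TwasFixture:
    """Inputs of a summary-statistics TWAS run.

    ``weights``: long table (gene, snp, weight) of per-SNP eQTL weights;
    ``ld``: symmetric SNP correlation matrix with unit diagonal (DataFrame
    indexed by SNP id); ``gwas``: table (snp, z) of GWAS z-scores.
    """

    weights: pd.DataFrame
    ld: pd.DataFrame
    gwas: pd.DataFrame
    truth_causal_genes: tuple[str, ...] = ()


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Draw a synthetic cohort with a planted active subpopulation.

    Counts are gene-wise negative binomial (variance mu + phi*mu^2) around
    log-normal baseline means scaled by a per-cell log-normal library
    factor. Within each patient exactly round(active_fraction *
    cells_per_patient) cells are active; active cells' risk-gene means are
    multiplied by 2**effect_log2fc (signature genes by
    2**signature_log2fc). Identical seeds give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    genes = np.array([f"G{i:04d}" for i in range(config.n_genes)])
    risk = genes[: config.n_risk_genes]
    signature = risk[: config.n_signature_genes]

    # baseline per-gene mean counts: log-normal, mostly sub-count like scRNA-seq;
    # risk genes are expressed in the tissue by construction (they carry eQTL
    # weights there), so their baselines are drawn from a moderate-expression law
    mu = rng.lognormal(mean=-1.0, sigma=1.0, size=config.n_genes)
    mu[: config.n_risk_genes] = rng.lognormal(mean=0.0, sigma=0.5, size=config.n_risk_genes)

    patients = [f"case{i + 1:02d}" for i in range(config.n_patients_case)] + [
        f"ctrl{i + 1:02d}" for i in range(config.n_patients_control)
    ]
    groups = ["case"] * config.n_patients_case + ["control"] * config.n_patients_control

    rows = []
    active_flags = []
    cell_ids = []
    for pat, grp in zip(patients, groups):
        n = config.cells_per_patient
        frac = config.active_fraction_case if grp == "case" else config.active_fraction_control
        quota = int(round(frac * n))
        act = np.zeros(n, dtype=bool)
        act[rng.choice(n, size=quota, replace=False)] = True
        active_flags.append(act)
        cell_ids.extend(f"{pat}_c{i:04d}" for i in range(n))
        rows.append((pat, grp, n))

    active = np.concatenate(active_flags)
    n_cells = len(active)

    libsize = rng.lognormal(mean=0.0, sigma=config.libsize_sigma, size=n_cells)
    mean = libsize[:, None] * mu[None, :]
    fold = np.ones((n_cells, config.n_genes))
    risk_idx = np.arange(config.n_risk_genes)
    fold[np.ix_(active, risk_idx)] = 2.0 ** config.effect_log2fc
    fold[np.ix_(active, risk_idx[: config.n_signature_genes])] = 2.0 ** config.signature_log2fc
    mean = mean * fold

    r = 1.0 / config.nb_dispersion  # NB shape; var = mu + dispersion * mu^2
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p).astype(np.int64)

    obs = pd.DataFrame(
        {
            "patient": np.repeat(patients, config.cells_per_patient),
            "group": np.repeat(groups, config.cells_per_patient),
            "cell_type": "monocyte",
            "n_genes_detected": (counts > 0).sum(axis=1),
            "pct_mito": np.clip(rng.normal(config.mito_mean, config.mito_sd, n_cells), 0.0, 1.0),
            "truth_active": active,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = pd.DataFrame(
        {
            "truth_risk": np.isin(genes, risk),
            "truth_signature": np.isin(genes, signature),
        },
        index=pd.Index(genes, name="gene"),
    )
    adata = ad.AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)
    adata.uns["layer"] = "counts"

    return SimulatedDataset(
        adata=adata,
        truth_active_cells=frozenset(np.array(cell_ids)[active]),
        truth_risk_genes=GeneSet("truth_risk", tuple(risk)),
        truth_signature_genes=GeneSet("truth_signature", tuple(signature)),
        config=config,
    )


def _ar1_block(k: int, rho: float) -> np.ndarray:
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_twas_fixture(
    n_genes: int,
    snps_per_gene: int = 3,
    n_causal: int = 0,
    causal_z_shift: float = 0.0,
    seed: int = 0,
    rho: float = 0.5,
) -> TwasFixture:
    """Simulate eQTL weights, block AR(1) LD, and GWAS z-scores.

    Each gene owns an independent cis block of ``snps_per_gene`` SNPs with
    AR(1) correlation ``rho``. Non-causal genes' z-scores are multivariate
    normal under the LD; for the first ``n_causal`` genes the block mean is
    shifted along LD·w / sqrt(w'LDw), so the gene-level association
    statistic is N(causal_z_shift, 1).
    """
    if n_causal > n_genes:
        raise ValueError(f"n_causal ({n_causal}) exceeds n_genes ({n_genes})")
    if not -1.0 < rho < 1.0:
        raise ValueError(f"AR(1) rho must lie in (-1, 1) for a PSD block, got {rho}")
    rng = np.random.default_rng(seed)

    block = _ar1_block(snps_per_gene, rho)
    chol = np.linalg.cholesky(block)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    causal = set(genes[:n_causal])

    weight_rows = []
    z_all = np.empty(n_genes * snps_per_gene)
    snp_ids = []
    for gi, gene in enumerate(genes):
        snps = [f"{gene}_snp{j}" for j in range(snps_per_gene)]
        snp_ids.extend(snps)
        w = rng.normal(size=snps_per_gene)
        weight_rows.append(pd.DataFrame({"gene": gene, "snp": snps, "weight": w}))
        z = chol @ rng.normal(size=snps_per_gene)
        if gene in causal:
            bw = block @ w
            z = z + causal_z_shift * bw / np.sqrt(w @ bw)
        z_all[gi * snps_per_gene : (gi + 1) * snps_per_gene] = z

    n_snps = len(snp_ids)
    ld = np.zeros((n_snps, n_snps))
    for gi in range(n_genes):
        sl = slice(gi * snps_per_gene, (gi + 1) * snps_per_gene)
        ld[sl, sl] = block
    ld_df = pd.DataFrame(ld, index=pd.Index(snp_ids, name="snp"), columns=snp_ids)

    return TwasFixture(
        weights=pd.concat(weight_rows, ignore_index=True),
        ld=ld_df,
        gwas=pd.DataFrame({"snp": snp_ids, "z": z_all}),
        truth_causal_genes=tuple(sorted(causal)),
    )


def qc_ladder_fixture() -> ad.AnnData:
    """A fixed 30-cell dataset crossing QC covariate levels.

    Detected-gene counts {100, 199, 200, 300, 6000, 6001} x mitochondrial
    fractions {0, 0.10, 0.15, 0.151, 0.30}; the expression matrix itself is
    a 30 x 4 constant placeholder — only the covariates matter to QC.
    """
    gene_levels = [100, 199, 200, 300, 6000, 6001]
    mito_levels = [0.0, 0.10, 0.15, 0.151, 0.30]
    rows = [(g, m) for g in gene_levels for m in mito_levels]
    obs = pd.DataFrame(
        {
            "patient": "p1",
            "group": "control",
            "cell_type": "monocyte",
            "n_genes_detected": [g for g, _ in rows],
            "pct_mito": [m for _, m in rows],
        },
        index=pd.Index([f"cell_g{g}_m{int(m * 1000):03d}" for g, m in rows], name="cell_id"),
    )
    x = sp.csr_matrix(np.ones((len(rows), 4)))
    adata = ad.AnnData(X=x, obs=obs,
                       var=pd.DataFrame(index=pd.Index([f"G{i}" for i in range(4)], name="gene")))
    adata.uns["layer"] = "counts"
    return adata
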