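"""Summary-statistics TWAS association and FDR control.

For each gene with eQTL weights w over its cis-SNPs, GWAS z-scores z and
SNP correlation (LD) matrix V, the association statistic is

    z_gene = w'z / sqrt(w'Vw)

(the canonical summary-statistic TWAS test), with a two-sided normal
p-value. P-values are Benjamini–Hochberg adjusted across all testable
genes and the risk set is defined by q < alpha (strict).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet
from .simulate import TwasFixture

#: genes whose predictive variance w'Vw falls at or below this are untestable
VARIANCE_TOL = 1e-12


class UntestableGeneError(ValueError):
    """Zero predictive variance: w'Vw <= tolerance."""


def twas_zscore(weights: np.ndarray, gwas_z: np.ndarray, ld: np.ndarray) -> float:
    """Gene-level association z-score w'z / sqrt(w'Vw).

    Raises :class:`UntestableGeneError` when the predictive variance is
    numerically zero; callers exclude such genes from multiple testing.
    """
    w = np.asarray(weights, dtype=float)
    z = np.asarray(gwas_z, dtype=float)
    v = np.asarray(ld, dtype=float)
    if not (w.shape[0] == z.shape[0] == v.shape[0] == v.shape[1]):
        raise ValueError(
            f"dimension mismatch: weights {w.shape}, gwas_z {z.shape}, ld {v.shape}"
        )
    denom = float(w @ v @ w)
    if denom <= VARIANCE_TOL:
        raise UntestableGeneError(f"predictive variance w'Vw = {denom:.3g} <= {VARIANCE_TOL}")
    return float(w @ z) / np.sqrt(denom)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def twas_associate(fixture: TwasFixture, alpha: float = 0.05) -> pd.DataFrame:
    """Run the TWAS test for every gene in a fixture.

    Returns a DataFrame (gene, z, p, q, significant, testable) sorted by
    gene id. Genes with degenerate predictive variance are kept in the
    table with ``testable=False`` and NaN statistics; BH adjustment runs
    across testable genes only.
    """
    snp_pos = {s: i for i, s in enumerate(fixture.ld.index)}
    gwas = fixture.gwas.set_index("snp")["z"]
    ld_values = fixture.ld.to_numpy()

    records = []
    for gene, grp in fixture.weights.groupby("gene", sort=True):
        snps = grp["snp"].to_numpy()
        missing = [s for s in snps if s not in snp_pos]
        if missing:
            raise ValueError(f"gene {gene}: SNPs absent from LD matrix: {missing[:3]}")
        idx = np.array([snp_pos[s] for s in snps])
        w = grp["weight"].to_numpy(dtype=float)
        z = gwas.loc[snps].to_numpy(dtype=float)
        v = ld_values[np.ix_(idx, idx)]
        try:
            zg = twas_zscore(w, z, v)
            records.append((gene, zg, 2.0 * stats.norm.sf(abs(zg)), True))
        except UntestableGeneError:
            records.append((gene, np.nan, np.nan, False))

    res = pd.DataFrame(records, columns=["gene", "z", "p", "testable"])
    res["q"] = np.nan
    mask = res["testable"].to_numpy()
    if mask.any():
        res.loc[mask, "q"] = bh_adjust(res.loc[mask, "p"])
    res["significant"] = mask & (res["q"] < alpha)
    return res[["gene", "z", "p", "q", "significant", "testable"]]


def select_risk_genes(results: pd.DataFrame, alpha: float = 0.05,
                      name: str = "twas_risk") -> GeneSet:
    """Genes with q < alpha (strict), ordered by q ascending, gene id tiebreak."""
    tested = results.dropna(subset=["q"])
    hits = tested[tested["q"] < alpha].sort_values(["q", "gene"], kind="stable")
    return GeneSet(name, tuple(hits["gene"]), description=f"TWAS q<{alpha}")


def write_twas_results(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False)
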