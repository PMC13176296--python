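"""Per-cell gene-set activity scores and the composite activity Scoring.

Five independent statistics score every cell for the composite activity of
one gene set (here, the TWAS risk genes):

* module_mean — mean set expression minus the mean of expression-matched
  control genes (module-score style);
* aucell — area under the set-recovery curve within the cell's top-ranked
  genes (AUCell style);
* ucell — Mann–Whitney-U rank statistic of set genes against the clipped
  complement (UCell style);
* singscore — centered mean of rank-normalized set-gene positions
  (singscore style);
* ssgsea — integrated weighted Kolmogorov–Smirnov running sum for a single
  sample (ssGSEA style).

Each raw column is z-scored then min-max rescaled to [0, 1] (the two steps
compose to plain min-max on non-constant columns) and the composite
Scoring is the row sum of the five normalized columns, in [0, 5].

All rankings order genes by descending expression with ties broken by gene
identifier, so every score is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .genesets import GeneSet

SCORE_COLUMNS = ("module_mean", "aucell", "ucell", "singscore", "ssgsea")


@dataclass
class ActivityPanel:
    """Per-cell raw scores, normalized scores, and the composite Scoring."""

    raw: pd.DataFrame          # cells x 5
    normalized: pd.DataFrame   # cells x 5, each column in [0, 1]
    scoring: pd.Series         # row sum of normalized, in [0, 5]

    def to_frame(self) -> pd.DataFrame:
        norm = self.normalized.add_suffix("_norm")
        out = pd.concat([self.raw, norm, self.scoring.rename("scoring")], axis=1)
        out.index.name = "cell_id"
        return out


def _dense_lognorm(adata: ad.AnnData) -> np.ndarray:
    if adata.uns.get("layer") != "lognorm":
        raise ValueError(
            f"activity scores require the log-normalized layer, found {adata.uns.get('layer')!r}"
        )
    return np.asarray(sp.csr_matrix(adata.X).todense(), dtype=float)


def _set_columns(adata: ad.AnnData, gene_set: GeneSet) -> np.ndarray:
    present = set(adata.var_names)
    hit = [g for g in gene_set.genes if g in present]
    if not hit:
        missing = list(gene_set.genes)[:10]
        raise ValueError(
            f"gene set {gene_set.name!r} shares no genes with the data; missing e.g. {missing}"
        )
    lookup = {g: i for i, g in enumerate(adata.var_names)}
    return np.array([lookup[g] for g in hit])


def _descending_ranks(adata: ad.AnnData) -> np.ndarray:
    """Cell x gene matrix of 1-based ranks, descending expression.

    Ties are broken by gene identifier (ascending), giving each gene a
    distinct rank in every cell.
    """
    x = _dense_lognorm(adata)
    id_order = np.argsort(np.asarray(adata.var_names, dtype=object), kind="stable")
    xs = x[:, id_order]
    order = np.argsort(-xs, axis=1, kind="stable")  # positions in descending order
    ranks_sorted = np.empty_like(order)
    np.put_along_axis(ranks_sorted, order, np.arange(1, xs.shape[1] + 1)[None, :], axis=1)
    ranks = np.empty_like(ranks_sorted)
    ranks[:, id_order] = ranks_sorted
    return ranks


# ----------------------------------------------------------- the five scores


def score_module_mean(
    adata: ad.AnnData,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Mean set expression minus the mean of bin-matched control genes.

    Genes are binned by average expression across cells into ``n_bins``
    equal-size bins; for each set gene, up to ``n_ctrl`` non-set genes are
    sampled (without replacement, seeded) from its bin, and the pooled
    control genes' mean is subtracted from the set genes' mean per cell.
    """
    x = _dense_lognorm(adata)
    set_idx = _set_columns(adata, gene_set)
    g = adata.n_vars

    avg = x.mean(axis=0)
    gene_ids = np.asarray(adata.var_names, dtype=object)
    order = np.lexsort((gene_ids, avg))  # ascending mean, gene-id tiebreak
    bin_of = np.empty(g, dtype=int)
    bin_of[order] = (np.arange(g) * n_bins) // g

    rng = np.random.default_rng(seed)
    in_set = np.zeros(g, dtype=bool)
    in_set[set_idx] = True
    ctrl: set[int] = set()
    for gi in set_idx:
        pool = np.flatnonzero((bin_of == bin_of[gi]) & ~in_set)
        if pool.size == 0:
            continue
        take = min(n_ctrl, pool.size)
        ctrl.update(rng.choice(pool, size=take, replace=False).tolist())
    ctrl_idx = np.array(sorted(ctrl), dtype=int) if ctrl else set_idx

    score = x[:, set_idx].mean(axis=1) - x[:, ctrl_idx].mean(axis=1)
    return pd.Series(score, index=adata.obs_names, name="module_mean")


def score_aucell(
    adata: ad.AnnData, gene_set: GeneSet, top_fraction: float = 0.05
) -> pd.Series:
    """Area under the set-recovery curve within the cell's top-ranked genes.

    The recovery step curve counts set genes among the top k ranks for
    k = 1..R with R = ceil(top_fraction * G); the integral is normalized by
    the maximal achievable area (all set genes at the very top).
    """
    ranks = _descending_ranks(adata)
    set_idx = _set_columns(adata, gene_set)
    g = adata.n_vars
    r_max = math.ceil(top_fraction * g)
    if r_max < 1:
        raise ValueError(f"top rank ceil({top_fraction} * {g}) < 1")
    n_s = set_idx.size

    set_ranks = ranks[:, set_idx]
    # a set gene at rank r <= R contributes (R - r + 1) to the step integral
    contrib = np.clip(r_max - set_ranks + 1, 0, None)
    area = contrib.sum(axis=1).astype(float)
    max_area = float(sum(min(k, n_s) for k in range(1, r_max + 1)))
    return pd.Series(area / max_area, index=adata.obs_names, name="aucell")


def score_ucell(
    adata: ad.AnnData, gene_set: GeneSet, max_rank: int = 1500
) -> pd.Series:
    """Mann–Whitney-U rank score of set genes with rank clipping.

    Ranks beyond ``max_rank`` are clipped; U' = sum(clipped set ranks) −
    n_s(n_s+1)/2 and the score is 1 − U'/(n_s·(max_rank − n_s)), clamped to
    [0, 1]. A cell whose set genes all sit at the top scores 1; set genes
    entirely below ``max_rank`` score 0.
    """
    set_idx = _set_columns(adata, gene_set)
    n_s = set_idx.size
    if n_s >= max_rank:
        raise ValueError(f"gene set size ({n_s}) must be < max_rank ({max_rank})")
    ranks = _descending_ranks(adata)
    clipped = np.minimum(ranks[:, set_idx], max_rank)
    u = clipped.sum(axis=1) - n_s * (n_s + 1) / 2.0
    score = 1.0 - u / (n_s * (max_rank - n_s))
    return pd.Series(np.clip(score, 0.0, 1.0), index=adata.obs_names, name="ucell")


def score_singscore(adata: ad.AnnData, gene_set: GeneSet) -> pd.Series:
    """Centered mean of rank-normalized set-gene positions.

    Ascending ranks are normalized to (rank − 0.5)/G; the score is the set
    mean minus 0.5 (its expectation under no enrichment), symmetric about 0.
    """
    set_idx = _set_columns(adata, gene_set)
    ranks_desc = _descending_ranks(adata)
    g = adata.n_vars
    ranks_asc = g - ranks_desc + 1
    norm = (ranks_asc[:, set_idx] - 0.5) / g
    return pd.Series(norm.mean(axis=1) - 0.5, index=adata.obs_names, name="singscore")


def score_ssgsea(
    adata: ad.AnnData, gene_set: GeneSet, alpha: float = 0.25
) -> pd.Series:
    """Integrated weighted KS running-sum enrichment for a single cell.

    Walking the cell's descending ranking, the running sum rises by
    w^alpha (rank weight w = G − position + 1, normalized over set genes)
    at set genes and falls by 1/(G − n_s) otherwise; the score integrates
    the running sum over all positions. A set concentrated at the top
    yields a large positive score, at the bottom a negative one.
    """
    set_idx = _set_columns(adata, gene_set)
    g = adata.n_vars
    n_s = set_idx.size
    if n_s == g:
        raise ValueError("gene set covers every gene: the complement is empty")
    ranks = _descending_ranks(adata)
    set_ranks = ranks[:, set_idx]  # positions 1..G in the descending walk

    weights = (g - set_ranks + 1).astype(float) ** alpha
    weights /= weights.sum(axis=1, keepdims=True)

    inc = np.full((adata.n_obs, g), -1.0 / (g - n_s))
    np.put_along_axis(inc, set_ranks - 1, weights, axis=1)
    running = np.cumsum(inc, axis=1)
    return pd.Series(running.sum(axis=1), index=adata.obs_names, name="ssgsea")


# --------------------------------------------------- panel assembly & algebra


def normalize_panel(raw: pd.DataFrame) -> pd.DataFrame:
    """Per column: z-score then min-max to [0, 1]; constant columns -> 0.5.

    The composition equals plain min-max on non-constant columns (z-scoring
    is affine); both steps are applied for fidelity to the stated recipe.
    """
    if len(raw) < 2:
        raise ValueError("panel normalization needs at least 2 cells")
    out = {}
    for col in raw.columns:
        v = raw[col].to_numpy(dtype=float)
        sd = v.std()
        if sd == 0:
            out[col] = np.full(v.shape, 0.5)
            continue
        z = (v - v.mean()) / sd
        out[col] = (z - z.min()) / (z.max() - z.min())
    return pd.DataFrame(out, index=raw.index)


def composite_score(normalized: pd.DataFrame) -> pd.Series:
    """Row sum of the normalized score columns; range [0, n_columns]."""
    return normalized.sum(axis=1).rename("scoring")


def score_correlation(raw: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations of the raw score columns.

    Constant columns have undefined correlation and are reported as NaN.
    """
    if len(raw) < 3:
        raise ValueError("need at least 3 cells for a meaningful correlation")
    cols = list(raw.columns)
    k = len(cols)
    corr = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = raw[cols[i]].to_numpy(), raw[cols[j]].to_numpy()
            if a.std() == 0 or b.std() == 0:
                corr[i, j] = corr[j, i] = np.nan
            else:
                corr[i, j] = corr[j, i] = stats.spearmanr(a, b).statistic
    return pd.DataFrame(corr, index=cols, columns=cols)


def score_panel(adata: ad.AnnData, gene_set: GeneSet, seed: int = 0) -> ActivityPanel:
    """Compute all five scores, normalize them, and form the composite."""
    raw = pd.concat(
        [
            score_module_mean(adata, gene_set, seed=seed),
            score_aucell(adata, gene_set),
            score_ucell(adata, gene_set, max_rank=min(1500, max(adata.n_vars - 1,
                                                               len(gene_set) + 1))),
            score_singscore(adata, gene_set),
            score_ssgsea(adata, gene_set),
        ],
        axis=1,
    )
    normalized = normalize_panel(raw)
    return ActivityPanel(raw=raw, normalized=normalized, scoring=composite_score(normalized))
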