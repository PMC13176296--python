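"""Quartile stratification of the composite score and Ro/e enrichment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

STRATA = ("low", "median", "high")


@dataclass
class ActivityLabeling:
    """Per-cell activity stratum and the quartile cutpoints that defined it."""

    strata: pd.Series  # values in {"low", "median", "high"}, indexed by cell id
    q25: float
    q75: float


def stratify_quartiles(scoring: pd.Series) -> ActivityLabeling:
    """Assign activity strata by composite-score quartiles.

    low if score <= 25th percentile, high if score >= 75th percentile,
    median otherwise (boundaries inclusive); percentiles use the
    linear-interpolation definition. When every score is identical the
    quartiles are degenerate and all cells are labeled median.
    """
    if len(scoring) < 4:
        raise ValueError(f"quartile stratification needs >= 4 cells, got {len(scoring)}")
    v = scoring.to_numpy(dtype=float)
    q25, q75 = np.percentile(v, [25, 75])
    if v.std() == 0:
        warnings.warn("all composite scores identical; labeling every cell 'median'")
        labels = np.full(v.shape, "median", dtype=object)
    else:
        labels = np.where(v <= q25, "low", np.where(v >= q75, "high", "median"))
    strata = pd.Series(pd.Categorical(labels, categories=list(STRATA)),
                       index=scoring.index, name="twas_activity")
    return ActivityLabeling(strata=strata, q25=float(q25), q75=float(q75))


def roe_enrichment(labels: ActivityLabeling | pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Ratio of observed to expected cell counts per stratum x group.

    Expected counts are the chi-square expectations
    row_total * col_total / grand_total; Ro/e > 1 marks enrichment of a
    stratum in a group. Entries whose stratum or group is empty are NaN.
    """
    strata = labels.strata if isinstance(labels, ActivityLabeling) else labels
    if not strata.index.equals(groups.index):
        groups = groups.reindex(strata.index)
        if groups.isna().any():
            raise ValueError("every labeled cell needs a group label")
    obs = pd.crosstab(strata, groups, dropna=False)
    row = obs.sum(axis=1).to_numpy(dtype=float)[:, None]
    col = obs.sum(axis=0).to_numpy(dtype=float)[None, :]
    grand = obs.to_numpy().sum()
    expected = row * col / grand
    with np.errstate(divide="ignore", invalid="ignore"):
        roe = obs.to_numpy(dtype=float) / expected
    roe[expected == 0] = np.nan
    return pd.DataFrame(roe, index=obs.index, columns=obs.columns)
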