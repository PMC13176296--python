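"""High-vs-low activity classification task and consensus feature selection.

Cells in the median activity stratum are excluded; high cells are labeled
1, low cells 0, and the features are the risk genes present in the data.
Seven selectors each nominate genes — lasso (non-zero coefficients at a
CV-chosen penalty), random forest (top 10 by impurity importance),
XGBoost and LightGBM (top 20 by gain), Boruta (confirmed features, top 20
by importance), a decision tree (top 20 by impurity importance), and a
best-subset (ABESS-type) search — and the consensus signature is the exact
intersection of all seven lists, ordered by mean rank.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .genesets import GeneSet
from .stratify import ActivityLabeling

SELECTOR_METHODS = ("lasso", "rf", "xgb", "gbm", "boruta", "dtree", "abess")


@dataclass
class ClassificationTask:
    """Cells x risk-gene feature matrix with a binary high/low outcome."""

    X: pd.DataFrame            # log-normalized expression, cells x features
    y: pd.Series               # 1 = high activity, 0 = low activity
    patient: pd.Series         # per-cell patient identifier
    missing_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (self.X.index.equals(self.y.index) and self.X.index.equals(self.patient.index)):
            raise ValueError("X, y and patient must share one cell index")

    @property
    def n_cells(self) -> int:
        return len(self.X)

    def subset(self, cells) -> "ClassificationTask":
        return ClassificationTask(self.X.loc[cells], self.y.loc[cells],
                                  self.patient.loc[cells], self.missing_genes)


@dataclass
class SelectionReport:
    """Per-selector ranked feature lists, importances, and the consensus."""

    selections: dict[str, list[str]]
    importances: dict[str, pd.Series]
    params: dict[str, dict] = field(default_factory=dict)
    seed: int = 0

    @property
    def consensus(self) -> list[str]:
        return consensus_intersection(self)


def build_task(
    adata: ad.AnnData, labels: ActivityLabeling, risk_genes: GeneSet
) -> ClassificationTask:
    """Drop median-stratum cells and encode high=1 / low=0 over risk genes."""
    if adata.uns.get("layer") != "lognorm":
        raise ValueError("build_task expects log-normalized expression")
    strata = labels.strata.reindex(adata.obs_names)
    keep = strata.isin(["high", "low"]).to_numpy()
    present = [g for g in risk_genes.genes if g in set(adata.var_names)]
    missing = tuple(g for g in risk_genes.genes if g not in set(adata.var_names))
    if missing:
        warnings.warn(f"{len(missing)} risk genes absent from the matrix, e.g. {missing[:5]}")
    sub = adata[keep, present]
    y = (strata[keep] == "high").astype(int)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError(
            f"need >= 2 cells per class, got {int(y.sum())} high / {int((1 - y).sum())} low"
        )
    X = pd.DataFrame(
        np.asarray(sp.csr_matrix(sub.X).todense(), dtype=float),
        index=sub.obs_names, columns=present,
    )
    return ClassificationTask(X=X, y=pd.Series(y.to_numpy(), index=X.index, name="high"),
                              patient=sub.obs["patient"].astype(str), missing_genes=missing)


# ------------------------------------------------------------------- Boruta


def boruta_select(
    task: ClassificationTask,
    max_iter: int = 100,
    alpha: float = 0.01,
    seed: int = 0,
    n_estimators: int = 100,
) -> pd.DataFrame:
    """All-relevant feature selection against permuted shadow features.

    Every iteration permutes each feature into a "shadow" copy, fits a
    random forest on real + shadow columns, and scores a "hit" for a real
    feature whose importance exceeds the best shadow importance. Features
    are confirmed or rejected by a two-sided binomial test (p = 0.5) at
    ``alpha`` with Bonferroni correction over the still-tentative
    features; iteration stops early once nothing is tentative.

    Returns a DataFrame (feature, status, hits, n_iter, mean_importance)
    with status in {confirmed, rejected, tentative}.
    """
    if max_iter < 5:
        raise ValueError(f"max_iter must be >= 5, got {max_iter}")
    rng = np.random.default_rng(seed)
    X = task.X.to_numpy(dtype=float)
    y = task.y.to_numpy()
    n, p = X.shape
    feats = list(task.X.columns)

    hits = np.zeros(p, dtype=int)
    imp_sum = np.zeros(p)
    status = np.array(["tentative"] * p, dtype=object)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        shadow = X.copy()
        for j in range(p):
            shadow[:, j] = shadow[rng.permutation(n), j]
        forest = RandomForestClassifier(
            n_estimators=n_estimators, max_depth=5,
            random_state=int(rng.integers(2**31 - 1)), n_jobs=1,
        )
        forest.fit(np.hstack([X, shadow]), y)
        imp = forest.feature_importances_
        real, sh = imp[:p], imp[p:]
        hits += real > sh.max()
        imp_sum += real

        tentative = status == "tentative"
        m = int(tentative.sum())
        if m == 0:
            break
        # two-sided exact binomial test of hits vs Binomial(n_iter, 1/2)
        for j in np.flatnonzero(tentative):
            res = stats.binomtest(int(hits[j]), n_iter, 0.5, alternative="two-sided")
            if res.pvalue * m < alpha:
                status[j] = "confirmed" if hits[j] > n_iter / 2 else "rejected"
        if not (status == "tentative").any():
            break

    return pd.DataFrame(
        {
            "feature": feats,
            "status": status,
            "hits": hits,
            "n_iter": n_iter,
            "mean_importance": imp_sum / max(n_iter, 1),
        }
    )


# -------------------------------------------------------------- best subset


def _bic_ols(X: np.ndarray, y: np.ndarray, support: tuple[int, ...]) -> float:
    n = len(y)
    if support:
        design = np.column_stack([np.ones(n), X[:, support]])
    else:
        design = np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(((y - design @ beta) ** 2).sum())
    rss = max(rss, 1e-12)
    return n * np.log(rss / n) + (len(support) + 1) * np.log(n)


def best_subset_select(
    task: ClassificationTask,
    max_size: int | None = None,
    exhaustive_limit: int = 15,
) -> list[str]:
    """Best-subset (ABESS-type) selection with a BIC-chosen support size.

    An ordinary-least-squares working model on the 0/1 outcome is scored
    by BIC. With p <= ``exhaustive_limit`` features, every subset up to
    ``max_size`` is enumerated (an exact search); otherwise a forward
    search per support size is refined by single-swap splicing, and the
    size minimizing BIC wins. Deterministic.
    """
    X = task.X.to_numpy(dtype=float)
    y = task.y.to_numpy(dtype=float)
    p = X.shape[1]
    if max_size is None:
        max_size = min(p, 20)
    max_size = min(max_size, p, len(y) - 2)

    best: tuple[float, tuple[int, ...]] = (_bic_ols(X, y, ()), ())
    if p <= exhaustive_limit:
        for s in range(1, max_size + 1):
            for support in itertools.combinations(range(p), s):
                bic = _bic_ols(X, y, support)
                if bic < best[0]:
                    best = (bic, support)
    else:
        support: list[int] = []
        for s in range(1, max_size + 1):
            remaining = [j for j in range(p) if j not in support]
            scores = [_bic_ols(X, y, tuple(support + [j])) for j in remaining]
            support.append(remaining[int(np.argmin(scores))])
            # splicing refinement: try swapping each member for each outsider
            improved = True
            while improved:
                improved = False
                cur = _bic_ols(X, y, tuple(support))
                for out_pos in range(len(support)):
                    for j in range(p):
                        if j in support:
                            continue
                        cand = support.copy()
                        cand[out_pos] = j
                        if _bic_ols(X, y, tuple(cand)) < cur:
                            support = cand
                            cur = _bic_ols(X, y, tuple(support))
                            improved = True
            bic = _bic_ols(X, y, tuple(support))
            if bic < best[0]:
                best = (bic, tuple(support))

    cols = list(task.X.columns)
    chosen = sorted(best[1])
    # order by marginal correlation with the outcome, strongest first
    if chosen:
        strength = [abs(np.corrcoef(X[:, j], y)[0, 1]) for j in chosen]
        chosen = [c for _, c in sorted(zip(strength, chosen), key=lambda t: (-t[0], t[1]))]
    return [cols[j] for j in chosen]


# ----------------------------------------------------------------- selectors


def _importance_series(values, index) -> pd.Series:
    s = pd.Series(values, index=index, dtype=float)
    return s.sort_values(ascending=False, kind="stable")


def select_features(
    task: ClassificationTask, method: str, seed: int = 0, **params
) -> pd.Series:
    """Run one selector; returns importances indexed by the chosen features.

    The series is ordered by decreasing importance and truncated at the
    method's cutoff (lasso: non-zero coefficients; rf: top 10; xgb/gbm:
    top 20 by gain; boruta: confirmed then top 20; dtree: top 20 with
    non-zero impurity importance; abess: the BIC-chosen support).
    """
    if method not in SELECTOR_METHODS:
        raise ValueError(f"unknown selector {method!r}; expected one of {SELECTOR_METHODS}")
    X = task.X.to_numpy(dtype=float)
    y = task.y.to_numpy()
    cols = task.X.columns

    if method == "lasso":
        cs = params.pop("Cs", [0.01, 0.1, 1.0])
        cv = params.pop("cv", 3)
        # standardize so the penalty treats genes comparably
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - X.mean(axis=0)) / sd
        best_c, best_score = cs[0], -np.inf
        folds = list(StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
                     .split(Xs, y))
        for c in cs:
            aucs = []
            for tr, te in folds:
                m = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=c,
                                       random_state=seed, max_iter=2000)
                m.fit(Xs[tr], y[tr])
                prob = m.predict_proba(Xs[te])[:, 1]
                aucs.append(stats.rankdata(prob)[y[te] == 1].mean())
            score = float(np.mean(aucs))
            if score > best_score:
                best_c, best_score = c, score
        model = LogisticRegression(l1_ratio=1.0, solver="liblinear", C=best_c,
                                   random_state=seed, max_iter=2000, **params)
        model.fit(Xs, y)
        coef = pd.Series(model.coef_.ravel(), index=cols)
        chosen = coef[coef != 0]
        return chosen.abs().sort_values(ascending=False, kind="stable")

    if method == "rf":
        top = params.pop("top", 10)
        threshold = params.pop("importance_threshold", None)
        model = RandomForestClassifier(
            n_estimators=params.pop("n_estimators", 200), random_state=seed, n_jobs=1, **params
        )
        model.fit(X, y)
        imp = _importance_series(model.feature_importances_, cols)
        return imp[imp > threshold] if threshold is not None else imp.head(top)

    if method == "xgb":
        from xgboost import XGBClassifier

        top = params.pop("top", 20)
        model = XGBClassifier(
            n_estimators=params.pop("n_estimators", 100), max_depth=3,
            learning_rate=0.3, importance_type="gain",
            random_state=seed, n_jobs=1, verbosity=0, **params,
        )
        model.fit(X, y)
        imp = _importance_series(model.feature_importances_, cols)
        return imp[imp > 0].head(top)

    if method == "gbm":
        from lightgbm import LGBMClassifier

        top = params.pop("top", 20)
        model = LGBMClassifier(
            n_estimators=params.pop("n_estimators", 100),
            random_state=seed, deterministic=True, n_jobs=1, verbose=-1, **params,
        )
        model.fit(X, y)
        imp = _importance_series(
            model.booster_.feature_importance(importance_type="gain"), cols
        )
        return imp[imp > 0].head(top)

    if method == "boruta":
        top = params.pop("top", 20)
        table = boruta_select(task, seed=seed, **params)
        confirmed = table[table["status"] == "confirmed"]
        imp = _importance_series(confirmed["mean_importance"].to_numpy(),
                                 confirmed["feature"])
        return imp.head(top)

    if method == "dtree":
        top = params.pop("top", 20)
        model = DecisionTreeClassifier(random_state=seed, **params)
        model.fit(X, y)
        imp = _importance_series(model.feature_importances_, cols)
        return imp[imp > 0].head(top)

    # abess
    chosen = best_subset_select(task, **params)
    strength = [abs(np.corrcoef(task.X[c].to_numpy(), y)[0, 1]) for c in chosen]
    return pd.Series(strength, index=chosen, dtype=float)


def run_selectors(
    task: ClassificationTask, seed: int = 0,
    methods: tuple[str, ...] = SELECTOR_METHODS,
    params: dict[str, dict] | None = None,
) -> SelectionReport:
    """Run every selector and assemble a SelectionReport."""
    params = params or {}
    selections: dict[str, list[str]] = {}
    importances: dict[str, pd.Series] = {}
    for method in methods:
        imp = select_features(task, method, seed=seed, **params.get(method, {}))
        selections[method] = list(imp.index)
        importances[method] = imp
    return SelectionReport(selections=selections, importances=importances,
                           params=params, seed=seed)


def consensus_intersection(report: SelectionReport) -> list[str]:
    """Exact intersection of all selectors' lists, ordered by mean rank."""
    missing = [m for m in SELECTOR_METHODS if m not in report.selections]
    if missing:
        raise ValueError(f"selector lists missing: {missing}")
    lists = [report.selections[m] for m in SELECTOR_METHODS]
    common = set(lists[0]).intersection(*map(set, lists[1:]))
    mean_rank = {g: float(np.mean([lst.index(g) for lst in lists])) for g in common}
    return sorted(common, key=lambda g: (mean_rank[g], g))
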