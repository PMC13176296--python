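"""Patient-aware splitting, nested-CV benchmarking, and LOPO validation.

All splits keep every cell of a patient on one side, so performance
estimates reflect generalization to unseen individuals rather than to
held-out cells of the same person. The benchmark runs nested
cross-validation (inner folds tune each learner's small grid, outer
patient-grouped folds estimate AUC) and picks the learner with the highest
mean outer AUC; leave-one-patient-out (LOPO) validation refits a logistic
model on the candidate signature, holding out each patient once and
excluding patients whose cells are all one class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import GridSearchCV, GroupKFold, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import ClassificationTask


@dataclass
class BenchmarkReport:
    """Outer-fold AUCs per learner and the mean-AUC-optimal model."""

    fold_aucs: dict[str, list[float]]
    mean_aucs: dict[str, float]
    best_model: str
    best_params: dict[str, dict] = field(default_factory=dict)


@dataclass
class LopoReport:
    """Per-patient AUCs of leave-one-patient-out validation."""

    per_patient_auc: dict[str, float]
    excluded: dict[str, str]           # patient -> reason
    median_auc: float
    iqr: tuple[float, float]


@dataclass
class TestEvalReport:
    """Held-out test-set performance of the signature model."""

    auc: float
    roc: pd.DataFrame
    pr: pd.DataFrame
    coef: pd.Series


def compute_auc(scores, labels) -> tuple[float, pd.DataFrame, pd.DataFrame]:
    """AUC (ties count one half) plus ROC and PR point lists.

    The AUC is the probability that a random positive outscores a random
    negative, computed from midranks; ROC points come from a threshold
    sweep and PR points are uninterpolated steps.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = stats.rankdata(s)  # midranks handle ties as 1/2
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, s)
    prec, rec, _ = precision_recall_curve(y, s)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    pr = pd.DataFrame({"recall": rec, "precision": prec})
    return float(auc), roc, pr


def patient_grouped_split(
    task: ClassificationTask, train_fraction: float = 0.8, seed: int = 0
) -> tuple[ClassificationTask, ClassificationTask]:
    """Assign whole patients to train or test, targeting the cell fraction.

    Patients are visited in a seeded random order; each joins the training
    side while doing so moves the train cell count closer to
    ``train_fraction`` of all cells. Both sides always receive at least
    one patient. No cell appears on both sides.
    """
    patients = task.patient.unique()
    if len(patients) < 2:
        raise ValueError(f"need >= 2 patients to split, got {len(patients)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(np.sort(patients))
    sizes = task.patient.value_counts()
    target = train_fraction * task.n_cells

    train_patients: list[str] = []
    train_cells = 0
    for pat in order:
        k = int(sizes[pat])
        if abs(train_cells + k - target) <= abs(train_cells - target):
            train_patients.append(pat)
            train_cells += k
    if not train_patients:
        train_patients = [order[0]]
    if len(train_patients) == len(patients):
        train_patients = train_patients[:-1]

    in_train = task.patient.isin(train_patients)
    return task.subset(task.X.index[in_train]), task.subset(task.X.index[~in_train])


def default_learners(seed: int = 0) -> list[tuple[str, Pipeline, dict]]:
    """The benchmark panel, ordered simplest first (the mean-AUC tiebreak).

    Grids are deliberately tiny; the panel is representative, not
    exhaustive, and fully configurable by callers.
    """
    return [
        ("logistic",
         Pipeline([("scale", StandardScaler()),
                   ("clf", LogisticRegression(max_iter=2000, random_state=seed))]),
         {"clf__C": [0.1, 1.0, 10.0]}),
        ("naive_bayes",
         Pipeline([("clf", GaussianNB())]), {}),
        ("knn",
         Pipeline([("scale", StandardScaler()), ("clf", KNeighborsClassifier())]),
         {"clf__n_neighbors": [5, 15]}),
        ("random_forest",
         Pipeline([("clf", RandomForestClassifier(n_estimators=100, random_state=seed,
                                                  n_jobs=1))]),
         {"clf__max_depth": [3, None]}),
        ("grad_boost",
         Pipeline([("clf", GradientBoostingClassifier(n_estimators=50, random_state=seed))]),
         {"clf__learning_rate": [0.1, 0.3]}),
    ]


def _outer_folds(task: ClassificationTask, outer_folds: int):
    groups = task.patient.to_numpy()
    n_groups = len(np.unique(groups))
    splitter = GroupKFold(n_splits=min(outer_folds, n_groups))
    return list(splitter.split(task.X, task.y, groups)), min(outer_folds, n_groups)


def nested_cv_benchmark(
    task: ClassificationTask,
    learners: list[tuple[str, Pipeline, dict]] | None = None,
    inner_folds: int = 5,
    outer_folds: int = 10,
    seed: int = 0,
) -> BenchmarkReport:
    """Nested CV: inner folds tune each grid, outer patient folds score AUC.

    The best learner is the one with the highest mean outer AUC; ties go
    to the earlier (simpler) entry in the panel.
    """
    learners = learners if learners is not None else default_learners(seed)
    folds, k = _outer_folds(task, outer_folds)
    fold_aucs: dict[str, list[float]] = {name: [] for name, _, _ in learners}
    tuned: dict[str, dict] = {name: {} for name, _, _ in learners}

    X = task.X.to_numpy(dtype=float)
    y = task.y.to_numpy()
    groups = task.patient.to_numpy()

    for tr_idx, te_idx in folds:
        if y[tr_idx].min() == y[tr_idx].max() or y[te_idx].min() == y[te_idx].max():
            raise ValueError(
                "an outer fold contains a single class; use more patients or fewer folds"
            )
        inner_groups = groups[tr_idx]
        n_inner = len(np.unique(inner_groups))
        if n_inner >= inner_folds:
            inner_cv = list(GroupKFold(n_splits=inner_folds).split(
                X[tr_idx], y[tr_idx], inner_groups))
        else:
            inner_cv = list(StratifiedKFold(n_splits=inner_folds, shuffle=True,
                                            random_state=seed).split(X[tr_idx], y[tr_idx]))
        for name, pipe, grid in learners:
            if grid:
                search = GridSearchCV(pipe, grid, scoring="roc_auc", cv=inner_cv, n_jobs=1)
                search.fit(X[tr_idx], y[tr_idx])
                model = search.best_estimator_
                tuned[name] = search.best_params_
            else:
                model = pipe.fit(X[tr_idx], y[tr_idx])
            prob = model.predict_proba(X[te_idx])[:, 1]
            auc, _, _ = compute_auc(prob, y[te_idx])
            fold_aucs[name].append(auc)

    mean_aucs = {name: float(np.mean(v)) for name, v in fold_aucs.items()}
    best = max(mean_aucs, key=lambda name: (mean_aucs[name],
                                            -[n for n, _, _ in learners].index(name)))
    return BenchmarkReport(fold_aucs=fold_aucs, mean_aucs=mean_aucs,
                           best_model=best, best_params=tuned)


def evaluate_signature(
    train: ClassificationTask,
    test: ClassificationTask,
    signature: list[str],
    seed: int = 0,
) -> TestEvalReport:
    """Fit a logistic model on the signature genes (train only) and score test.

    Scaling and fitting see training cells exclusively, so perturbing the
    test set cannot alter the fitted model.
    """
    model = Pipeline([("scale", StandardScaler()),
                      ("clf", LogisticRegression(max_iter=2000, random_state=seed))])
    model.fit(train.X[signature].to_numpy(), train.y.to_numpy())
    prob = model.predict_proba(test.X[signature].to_numpy())[:, 1]
    auc, roc, pr = compute_auc(prob, test.y.to_numpy())
    coef = pd.Series(model.named_steps["clf"].coef_.ravel(), index=signature, name="coef")
    return TestEvalReport(auc=auc, roc=roc, pr=pr, coef=coef)


def lopo_cv(task: ClassificationTask, signature: list[str], seed: int = 0) -> LopoReport:
    """Leave-one-patient-out validation of the signature.

    Each patient is held out once; a logistic model on the signature genes
    is trained on all other patients and the held-out cells' AUC recorded.
    Patients whose cells are all one class are excluded with the reason
    "single class".
    """
    patients = sorted(task.patient.unique())
    if len(patients) < 3:
        raise ValueError(f"LOPO-CV needs >= 3 patients, got {len(patients)}")
    per_patient: dict[str, float] = {}
    excluded: dict[str, str] = {}
    for pat in patients:
        held = task.patient == pat
        y_te = task.y[held]
        if y_te.min() == y_te.max():
            excluded[pat] = "single class"
            continue
        train = task.subset(task.X.index[~held])
        test = task.subset(task.X.index[held])
        per_patient[pat] = evaluate_signature(train, test, signature, seed=seed).auc
    if not per_patient:
        raise ValueError("no patient has both classes; LOPO-CV is undefined")
    vals = np.array(list(per_patient.values()))
    return LopoReport(
        per_patient_auc=per_patient,
        excluded=excluded,
        median_auc=float(np.median(vals)),
        iqr=(float(np.percentile(vals, 25)), float(np.percentile(vals, 75))),
    )
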