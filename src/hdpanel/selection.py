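"""Permutation stability selection and classification over a biomarker panel.

Two-step pipelines over repeated stratified train/test splits: an
importance *ranker* (linear-kernel SVM weights or gradient-boosted-tree
split gain) orders the features on each training set, then a *classifier*
(3-nearest-neighbors with inverse-distance weighting, or a 200-tree random
forest) is fit on nested top-k subsets and scored on the held-out test
set. Aggregated over permutations this yields accuracy/precision/recall
curves versus feature count and a per-feature occurrence matrix: the
percentage of permutations in which the feature ranked in the top 15.

A one-shot ridge-penalized logistic regression on the z-scored panel
provides the coefficient ranking view of the same tasks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import precision_score, recall_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .cohort import BiomarkerTable

__all__ = [
    "ClassificationTask",
    "GENOTYPE_TASK",
    "TREATMENT_TASK",
    "ModelCombo",
    "COMBOS",
    "zscore_features",
    "logistic_rank",
    "rank_features",
    "evaluate_subsets",
    "StabilitySelection",
    "StabilityResults",
    "compare_models",
]

RANKERS = ("svm_linear", "xgb")
CLASSIFIERS = ("knn3_distance", "rfc200")

#: Fixed ranker/model hyperparameters (recorded in run reports).
SVM_PARAMS = {"kernel": "linear", "C": 1.0}
XGB_PARAMS = {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.3}
KNN_PARAMS = {"n_neighbors": 3, "weights": "distance"}
RFC_PARAMS = {"n_estimators": 200}
# ridge (L2) penalty at unit strength; lbfgs is deterministic
LOGISTIC_PARAMS = {"C": 1.0, "solver": "lbfgs", "tol": 1e-8, "max_iter": 5000}


@dataclass(frozen=True)
class ClassificationTask:
    """Binary task: ``group0`` is coded 0 and ``group1`` is coded 1."""

    name: str
    group0: str
    group1: str

    def __post_init__(self) -> None:
        if self.group0 == self.group1:
            raise ValueError("task groups must differ")


#: WT-Veh (0) vs R6/2-Veh (1): positive model weights associate with disease.
GENOTYPE_TASK = ClassificationTask("genotype", "WT-Veh", "R6/2-Veh")
#: R6/2-Veh (0) vs R6/2-C31 (1).
TREATMENT_TASK = ClassificationTask("treatment", "R6/2-Veh", "R6/2-C31")


@dataclass(frozen=True)
class ModelCombo:
    """One ranker/classifier pairing (SVM-KNN, SVM-RFC, XGB-KNN, XGB-RFC)."""

    ranker: str
    classifier: str

    def __post_init__(self) -> None:
        if self.ranker not in RANKERS:
            raise ValueError(f"unknown ranker {self.ranker!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")

    @property
    def label(self) -> str:
        r = {"svm_linear": "SVM", "xgb": "XGB"}[self.ranker]
        c = {"knn3_distance": "KNN", "rfc200": "RFC"}[self.classifier]
        return f"{r}-{c}"


COMBOS = tuple(ModelCombo(r, c) for r in RANKERS for c in CLASSIFIERS)


def zscore_features(X: pd.DataFrame, subjects: pd.Index | None = None) -> pd.DataFrame:
    """Standardize each column to mean 0, SD 1 over ``subjects``.

    The mean and SD are computed over ``subjects`` (default: all rows) and
    applied to every row, so with a train-only scope the test rows keep
    their offset. A zero-SD column raises, naming the feature.
    """
    ref = X if subjects is None else X.loc[subjects]
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=0)
    zero = sd.index[sd == 0].tolist()
    if zero:
        raise ValueError(f"zero standard deviation in feature(s): {zero}")
    return (X - mean) / sd


def _task_data(table: BiomarkerTable, task: ClassificationTask) -> tuple[pd.DataFrame, pd.Series]:
    labels = table.group_labels
    mask = labels.isin([task.group0, task.group1])
    X = table.data.loc[mask, table.features]
    if X.isna().any().any():
        bad = X.columns[X.isna().any()].tolist()
        raise ValueError(f"missing values in feature(s) {bad}; impute or drop first")
    y = (labels[mask] == task.group1).astype(int)
    for g, cls in ((task.group0, 0), (task.group1, 1)):
        if (y == cls).sum() == 0:
            raise ValueError(f"task group {g!r} has no subjects")
    return X, y


def logistic_rank(table: BiomarkerTable, task: ClassificationTask) -> pd.DataFrame:
    """Ridge-penalized logistic regression coefficients on z-scored features.

    One joint fit of all features; with the 0/1 class coding of the task,
    positive coefficients mark features positively associated with the
    class-1 group. Returns a frame (feature, coefficient) sorted by
    coefficient, descending, ties resolved by panel column order.
    """
    X, y = _task_data(table, task)
    if (y == 0).sum() < 6 or (y == 1).sum() < 6:
        raise ValueError("need >= 6 subjects per class")
    Z = zscore_features(X)
    model = LogisticRegression(**LOGISTIC_PARAMS)
    model.fit(Z.to_numpy(), y.to_numpy())
    coef = model.coef_[0]
    order = np.argsort(-coef, kind="stable")
    return pd.DataFrame(
        {"feature": Z.columns.to_numpy()[order], "coefficient": coef[order],
         "task": task.name}
    ).reset_index(drop=True)


def rank_features(
    X_train: pd.DataFrame, y_train: np.ndarray, ranker: str, seed: int = 0
) -> list[str]:
    """Order features most-to-least important on the training set.

    ``svm_linear`` ranks by |weight| of a linear-kernel maximum-margin
    classifier; ``xgb`` by total split gain of a gradient-boosted tree
    ensemble (features never split on get importance 0). Ties are broken
    by the table's column order (stable sort).
    """
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain both classes")
    if ranker == "svm_linear":
        model = SVC(**SVM_PARAMS)
        model.fit(X_train.to_numpy(), y_train)
        importance = np.abs(model.coef_[0])
    elif ranker == "xgb":
        model = XGBClassifier(
            **XGB_PARAMS, random_state=seed, n_jobs=1, verbosity=0,
            importance_type="total_gain",
        )
        model.fit(X_train.to_numpy(), y_train)
        gain = model.get_booster().get_score(importance_type="total_gain")
        importance = np.array(
            [gain.get(f"f{j}", 0.0) for j in range(X_train.shape[1])]
        )
    else:
        raise ValueError(f"unknown ranker {ranker!r}")
    order = np.argsort(-importance, kind="stable")
    return [X_train.columns[j] for j in order]


def _make_classifier(classifier: str, seed: int):
    if classifier == "knn3_distance":
        return KNeighborsClassifier(**KNN_PARAMS)
    if classifier == "rfc200":
        return RandomForestClassifier(**RFC_PARAMS, random_state=seed, n_jobs=1)
    raise ValueError(f"unknown classifier {classifier!r}")


def evaluate_subsets(
    ranking: list[str],
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    classifier: str,
    k_range: range | list[int] | None = None,
    seed: int = 0,
) -> dict[int, tuple[float, float, float]]:
    """Fit the classifier on nested top-k feature subsets; score the test set.

    For each k (default 2..n_features) the classifier is trained on the
    top-k ranked features and evaluated on the held-out subjects;
    precision and recall take class 1 as positive (zero when the class is
    never predicted).
    """
    y_test = np.asarray(y_test)
    if np.unique(y_test).size < 2:
        raise ValueError("test set is missing a class")
    ks = list(k_range) if k_range is not None else list(range(2, len(ranking) + 1))
    if any(k < 1 or k > len(ranking) for k in ks):
        raise ValueError("k out of range of the ranking")
    out: dict[int, tuple[float, float, float]] = {}
    for k in ks:
        cols = ranking[:k]
        model = _make_classifier(classifier, seed)
        model.fit(X_train[cols].to_numpy(), np.asarray(y_train))
        pred = model.predict(X_test[cols].to_numpy())
        acc = float((pred == y_test).mean())
        prec = float(precision_score(y_test, pred, pos_label=1, zero_division=0))
        rec = float(recall_score(y_test, pred, pos_label=1, zero_division=0))
        out[k] = (acc, prec, rec)
    return out


@dataclass
class PermutationResult:
    permutation_id: int
    train_ids: list[str]
    test_ids: list[str]
    ranking: list[str]
    metrics_by_k: dict[int, tuple[float, float, float]]


class StabilitySelection:
    """Permutation stability-selection model for one task and model combo.

    Each permutation draws a stratified split — exactly
    ``n_test_per_group`` (default 6) test subjects per class and at most
    ``max_train_per_group`` (default 7) training subjects per class —
    ranks the features on the training set, and evaluates nested top-k
    subsets with the classifier. Everything is reproducible from
    ``(seed, n_permutations)``: per-permutation seeds are derived from the
    master seed by counter.

    Parameters
    ----------
    zscore_scope : {'full', 'train'}
        Standardize from the full task table before splitting (default,
        matching a pre-processed z-score table) or from each training set
        only (leakage-free variant).
    refit_per_step : bool
        If True, re-rank after each elimination step (classic RFE) instead
        of ranking once per permutation.
    """

    def __init__(
        self,
        table: BiomarkerTable,
        task: ClassificationTask,
        combo: ModelCombo,
        n_permutations: int = 1000,
        seed: int = 0,
        k_range: range | list[int] | None = None,
        n_test_per_group: int = 6,
        max_train_per_group: int = 7,
        top_n_occurrence: int = 15,
        zscore_scope: str = "full",
        refit_per_step: bool = False,
    ) -> None:
        if zscore_scope not in ("full", "train"):
            raise ValueError("zscore_scope must be 'full' or 'train'")
        self.table = table
        self.task = task
        self.combo = combo
        self.n_permutations = int(n_permutations)
        self.seed = int(seed)
        self.k_range = list(k_range) if k_range is not None else None
        self.n_test_per_group = int(n_test_per_group)
        self.max_train_per_group = int(max_train_per_group)
        self.top_n_occurrence = int(top_n_occurrence)
        self.zscore_scope = zscore_scope
        self.refit_per_step = refit_per_step

    def _split(self, y: pd.Series, rng: np.random.Generator) -> tuple[pd.Index, pd.Index]:
        train, test = [], []
        for cls in (0, 1):
            ids = y.index[y == cls].to_numpy()
            perm = rng.permutation(ids)
            test.append(perm[: self.n_test_per_group])
            train.append(perm[self.n_test_per_group : self.n_test_per_group + self.max_train_per_group])
        return pd.Index(np.concatenate(train)), pd.Index(np.concatenate(test))

    def _rank(self, Xtr: pd.DataFrame, ytr: np.ndarray, seed: int) -> list[str]:
        if not self.refit_per_step:
            return rank_features(Xtr, ytr, self.combo.ranker, seed=seed)
        # Classic RFE: drop the least important feature and re-rank.
        remaining = list(Xtr.columns)
        eliminated: list[str] = []
        while len(remaining) > 1:
            order = rank_features(Xtr[remaining], ytr, self.combo.ranker, seed=seed)
            eliminated.append(order[-1])
            remaining.remove(order[-1])
        return remaining + eliminated[::-1]

    def fit(self) -> "StabilityResults":
        X, y = _task_data(self.table, self.task)
        need = self.n_test_per_group + 6
        for cls, g in ((0, self.task.group0), (1, self.task.group1)):
            n = int((y == cls).sum())
            if n < need:
                raise ValueError(
                    f"class {g!r} has {n} subjects; stability selection needs "
                    f">= {need} ({self.n_test_per_group} test + >= 6 train per group)"
                )
        if self.zscore_scope == "full":
            X = zscore_features(X)
        ks = self.k_range or list(range(2, X.shape[1] + 1))

        perms: list[PermutationResult] = []
        occ_counts = pd.Series(0, index=X.columns, dtype=int)
        metrics = np.empty((self.n_permutations, len(ks), 3))
        for i in range(self.n_permutations):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=self.seed, spawn_key=(i,))
            )
            train_idx, test_idx = self._split(y, rng)
            if self.zscore_scope == "train":
                Xz = zscore_features(X, subjects=train_idx)
            else:
                Xz = X
            Xtr, Xte = Xz.loc[train_idx], Xz.loc[test_idx]
            ytr, yte = y.loc[train_idx].to_numpy(), y.loc[test_idx].to_numpy()
            rank_seed = int(rng.integers(2**31))
            clf_seed = int(rng.integers(2**31))
            ranking = self._rank(Xtr, ytr, rank_seed)
            occ_counts[ranking[: min(self.top_n_occurrence, len(ranking))]] += 1
            by_k = evaluate_subsets(ranking, Xtr, ytr, Xte, yte,
                                    self.combo.classifier, ks, seed=clf_seed)
            metrics[i] = [by_k[k] for k in ks]
            perms.append(
                PermutationResult(i, list(train_idx), list(test_idx), ranking, by_k)
            )

        ddof = 1 if self.n_permutations > 1 else 0
        curves = pd.DataFrame(
            {
                "combo": self.combo.label, "task": self.task.name, "k": ks,
                "accuracy_mean": metrics[:, :, 0].mean(axis=0),
                "accuracy_sd": metrics[:, :, 0].std(axis=0, ddof=ddof),
                "precision_mean": metrics[:, :, 1].mean(axis=0),
                "precision_sd": metrics[:, :, 1].std(axis=0, ddof=ddof),
                "recall_mean": metrics[:, :, 2].mean(axis=0),
                "recall_sd": metrics[:, :, 2].std(axis=0, ddof=ddof),
            }
        )
        occurrence = 100.0 * occ_counts / self.n_permutations
        return StabilityResults(self, curves, occurrence, perms)


@dataclass
class StabilityResults:
    """Aggregated stability-selection output for one (task, combo)."""

    model: StabilitySelection
    curves: pd.DataFrame
    occurrence: pd.Series  # percent of permutations ranked in the top 15
    permutations: list[PermutationResult] = field(repr=False, default_factory=list)

    @property
    def combo(self) -> ModelCombo:
        return self.model.combo

    @property
    def task(self) -> ClassificationTask:
        return self.model.task

    def mean_accuracy(self, k_window: tuple[int, int]) -> float:
        """Mean accuracy averaged over k in [k_window[0], k_window[1]]."""
        lo, hi = k_window
        sel = self.curves[(self.curves["k"] >= lo) & (self.curves["k"] <= hi)]
        if sel.empty:
            raise ValueError(f"no curve points with k in [{lo}, {hi}]")
        return float(sel["accuracy_mean"].mean())

    def best_k(self) -> tuple[int, float]:
        """Feature count with the highest mean accuracy (smallest k on ties)."""
        i = int(self.curves["accuracy_mean"].to_numpy().argmax())
        row = self.curves.iloc[i]
        return int(row["k"]), float(row["accuracy_mean"])

    def summary(self) -> str:
        k, acc = self.best_k()
        top = self.occurrence.sort_values(ascending=False).head(5)
        lines = [
            f"Stability selection: {self.combo.label} on task '{self.task.name}' "
            f"({self.model.n_permutations} permutations, seed {self.model.seed})",
            f"best mean accuracy {acc:.3f} at k = {k}",
            "top occurrence (% of permutations in the top 15):",
        ]
        lines += [f"  {f}: {v:.1f}%" for f, v in top.items()]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Accuracy/precision/recall vs feature count (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for metric in ("accuracy", "precision", "recall"):
            ax.errorbar(
                self.curves["k"], self.curves[f"{metric}_mean"],
                yerr=self.curves[f"{metric}_sd"], label=metric, capsize=2,
            )
        ax.set_xlabel("number of features (k)")
        ax.set_ylabel("mean test metric")
        ax.set_title(f"{self.combo.label} / {self.task.name}")
        ax.legend()
        return ax


def compare_models(results: list[StabilityResults]) -> pd.DataFrame:
    """Rank model combos on one task by mean accuracy at each combo's best k."""
    if len(results) < 2:
        raise ValueError("need >= 2 StabilityResults to compare")
    tasks = {r.task.name for r in results}
    if len(tasks) > 1:
        raise ValueError(f"mismatched tasks: {sorted(tasks)}")
    rows = []
    for r in results:
        k, acc = r.best_k()
        at_k = r.curves[r.curves["k"] == k].iloc[0]
        rows.append(
            {"combo": r.combo.label, "task": r.task.name, "best_k": k,
             "accuracy": acc, "precision": float(at_k["precision_mean"]),
             "recall": float(at_k["recall_mean"])}
        )
    return (
        pd.DataFrame(rows)
        .sort_values("accuracy", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
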