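"""Subsampling x repetition x classifier x k-fold cross-validation protocol.

The protocol estimates a learning curve by repeated balanced subsampling:
for each total sample size in a schedule (doubling from 16 by default) a
balanced subsample is drawn, its average and grand effect sizes are
measured, and each classifier in a fixed bank of five families — linear
support-vector machine, L2 logistic regression, decision tree, one-hidden-
layer neural network, and Gaussian naive Bayes — is scored by stratified
k-fold cross-validation. Repeating the draw (100 times by default) yields
per-size distributions of accuracy and effect size, aggregated into mean,
SD and a normal-approximation 95% confidence interval, plus the relative
accuracy change between consecutive sizes.

Accuracy is pooled over folds: every sample is predicted exactly once by a
model that never saw it, and the accuracy of one repetition is the
proportion of correct out-of-fold predictions. When fewer than k samples
per class are available the fold count drops to the smaller class size
(stratified 10-fold is impossible with 8 samples per class).

Scale-sensitive families (SVM, logistic regression, neural network) are
wrapped in a pipeline that standardises features on the training fold
only, so no test information leaks into the fit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from joblib import Parallel, delayed
from sklearn.base import BaseEstimator, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .datasets import LabeledDataset
from .effect_size import average_effect_size, grand_effect_size
from .errors import (
    ClassTooSmallError,
    DegenerateFoldError,
    EmptyGroupError,
    InsufficientDataError,
)

__all__ = [
    "ClassifierSpec",
    "SubsampleSchedule",
    "EvaluationCurve",
    "SampleSizeEvaluator",
    "default_classifier_bank",
    "build_estimator",
    "build_schedule",
    "subsample_balanced",
    "effective_folds",
    "crossval_accuracy",
    "run_evaluation",
    "aggregate_curve",
    "accuracy_change",
]

#: Protocol constants: smallest evaluated total sample size and the default
#: number of random subsamples per size.
DEFAULT_START_SIZE = 16
DEFAULT_REPETITIONS = 100
DEFAULT_FOLDS = 10

#: z quantile for the normal-approximation 95% confidence interval.
Z_95 = 1.96

FAMILIES = (
    "support-vector",
    "logistic-regression",
    "decision-tree",
    "neural-network",
    "naive-bayes",
)

_SCALED_FAMILIES = {"support-vector", "logistic-regression", "neural-network"}

_DEFAULT_SETTINGS: dict[str, dict] = {
    "support-vector": {"kernel": "linear", "C": 1.0},
    # L2 regularisation is the sklearn default; left implicit because the
    # `penalty` kwarg is deprecated in recent sklearn
    "logistic-regression": {"C": 1.0, "max_iter": 1000},
    "decision-tree": {"max_depth": None},
    "neural-network": {"hidden_layer_sizes": (100,), "max_iter": 200},
    "naive-bayes": {},
}

_LABELS = {
    "support-vector": "SVM",
    "logistic-regression": "LR",
    "decision-tree": "DT",
    "neural-network": "NN",
    "naive-bayes": "NB",
}


@dataclass
class ClassifierSpec:
    """One classifier family with its recorded hyperparameters."""

    family: str
    settings: dict = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        merged = dict(_DEFAULT_SETTINGS[self.family])
        merged.update(self.settings)
        self.settings = merged
        if self.label is None:
            self.label = _LABELS[self.family]


def default_classifier_bank(families=FAMILIES) -> list[ClassifierSpec]:
    """The five-family bank at documented default settings."""
    return [ClassifierSpec(f) for f in families]


def build_estimator(spec: ClassifierSpec, random_state: int | None = None):
    """Instantiate the sklearn estimator for a spec, with per-fold scaling
    for the scale-sensitive families."""
    s = dict(spec.settings)
    if spec.family == "support-vector":
        clf = SVC(random_state=random_state, **s)
    elif spec.family == "logistic-regression":
        clf = LogisticRegression(random_state=random_state, **s)
    elif spec.family == "decision-tree":
        clf = DecisionTreeClassifier(random_state=random_state, **s)
    elif spec.family == "neural-network":
        s.setdefault("hidden_layer_sizes", (100,))
        s["hidden_layer_sizes"] = tuple(s["hidden_layer_sizes"])
        clf = MLPClassifier(random_state=random_state, **s)
    elif spec.family == "naive-bayes":
        clf = GaussianNB(**s)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(spec.family)
    if spec.family in _SCALED_FAMILIES:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return clf


@dataclass
class SubsampleSchedule:
    """Strictly increasing even total sample counts, plus a repetition count."""

    sizes: tuple[int, ...]
    repetitions: int = DEFAULT_REPETITIONS

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.sizes)
        if not sizes:
            raise ValueError("schedule needs at least one size")
        if any(s % 2 for s in sizes):
            raise ValueError(f"sizes must be even (balanced halves): {sizes}")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError(f"sizes must be strictly increasing: {sizes}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        self.sizes = sizes


def build_schedule(
    n_available_balanced: int,
    start: int = DEFAULT_START_SIZE,
    repetitions: int = DEFAULT_REPETITIONS,
    sizes=None,
) -> SubsampleSchedule:
    """Default doubling schedule from ``start`` capped at the available total.

    Doubles 16, 32, 64, ... up to the largest even count not exceeding
    ``n_available_balanced``, appending that cap when the doubling sequence
    does not land on it. An explicit ``sizes`` list bypasses the doubling
    rule but is validated against the same cap.
    """
    if n_available_balanced < start:
        raise InsufficientDataError(
            f"need at least {start} balanced samples, have {n_available_balanced}"
        )
    cap = n_available_balanced - (n_available_balanced % 2)
    if sizes is not None:
        sched = SubsampleSchedule(tuple(sizes), repetitions)
        if sched.sizes[-1] > cap:
            raise InsufficientDataError(
                f"largest requested size {sched.sizes[-1]} exceeds available balanced total {cap}"
            )
        return sched
    out = []
    s = start
    while s <= cap:
        out.append(s)
        s *= 2
    if out[-1] != cap:
        out.append(cap)
    return SubsampleSchedule(tuple(out), repetitions)


def subsample_balanced(
    dataset: LabeledDataset, n_total: int, rng: np.random.Generator
) -> LabeledDataset:
    """Draw ``n_total/2`` samples per class uniformly without replacement."""
    if n_total % 2:
        raise ValueError(f"n_total must be even, got {n_total}")
    m1, m2 = dataset.require_two_classes()
    half = n_total // 2
    idx = []
    for mask in (m1, m2):
        pool = np.nonzero(mask)[0]
        if len(pool) < half:
            raise ClassTooSmallError(
                f"class has {len(pool)} samples, need {half} for a balanced draw of {n_total}"
            )
        idx.append(rng.choice(pool, size=half, replace=False))
    return dataset.take(np.concatenate(idx))


def effective_folds(k: int, smaller_class_size: int) -> int:
    """Fold count actually used: stratified k-fold needs k samples per class,
    so the count drops to the smaller class size when necessary."""
    return min(k, smaller_class_size)


def crossval_accuracy(
    dataset: LabeledDataset,
    spec: ClassifierSpec,
    k: int = DEFAULT_FOLDS,
    rng: np.random.Generator | int | None = None,
    metrics: bool = False,
) -> tuple[float, dict | None]:
    """Stratified k-fold CV accuracy of one classifier on one dataset.

    The effective fold count is ``min(k, smaller class size)``. Accuracy is
    the pooled proportion of correct out-of-fold predictions; with
    ``metrics=True`` AUC-ROC, precision, recall and F1 are computed on the
    same pooled predictions (scores from ``predict_proba`` or
    ``decision_function``), with the larger sorted label as the positive
    class.
    """
    X, y = dataset.values, dataset.labels
    classes = dataset.classes
    counts = dataset.class_counts()
    k_eff = effective_folds(k, min(counts.values()))
    if k_eff < 2:
        raise DegenerateFoldError(
            f"smaller class has {min(counts.values())} samples; cannot build 2 folds"
        )
    seed = int(np.random.default_rng(rng).integers(2**31 - 1))
    cv = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    est = build_estimator(spec, random_state=seed)

    y_pred = np.empty(len(y), dtype=y.dtype)
    y_score = np.empty(len(y), dtype=float) if metrics else None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train, test in cv.split(X, y):
            if len(np.unique(y[train])) < 2:
                raise DegenerateFoldError("training fold contains a single class")
            model = clone(est)
            model.fit(X[train], y[train])
            y_pred[test] = model.predict(X[test])
            if metrics:
                if hasattr(model, "predict_proba"):
                    proba = model.predict_proba(X[test])
                    pos_col = list(model.classes_).index(classes[1])
                    y_score[test] = proba[:, pos_col]
                else:
                    y_score[test] = model.decision_function(X[test])

    acc = float(accuracy_score(y, y_pred))
    extra = None
    if metrics:
        pos = classes[1]
        extra = {
            "auc_roc": float(roc_auc_score(y == pos, y_score)),
            "precision": float(precision_score(y, y_pred, pos_label=pos, zero_division=0)),
            "recall": float(recall_score(y, y_pred, pos_label=pos, zero_division=0)),
            "f1": float(f1_score(y, y_pred, pos_label=pos, zero_division=0)),
        }
    return acc, extra


def _one_repetition(dataset, size, rep, specs, k, metrics, seed_seq):
    """All records of one (size, repetition) cell: one subsample, one effect
    measurement, one CV per classifier."""
    rng = np.random.default_rng(seed_seq)
    sub = subsample_balanced(dataset, size, rng)
    d_avg = average_effect_size(sub)
    d_g = grand_effect_size(sub)
    rows = []
    for spec in specs:
        acc, extra = crossval_accuracy(sub, spec, k=k, rng=rng, metrics=metrics)
        row = {
            "sample_size": size,
            "repetition": rep,
            "classifier": spec.label,
            "accuracy": acc,
            "d_average": d_avg,
            "d_grand": d_g,
        }
        if extra:
            row.update(extra)
        rows.append(row)
    return rows


def run_evaluation(
    dataset: LabeledDataset,
    schedule: SubsampleSchedule,
    specs: list[ClassifierSpec] | None = None,
    seed: int | None = None,
    k: int = DEFAULT_FOLDS,
    metrics: bool = False,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Run the full protocol; one row per (size, repetition, classifier).

    Repetitions are seeded independently from the master seed, so the result
    table is identical whatever the degree of parallelism.
    """
    if specs is None:
        specs = default_classifier_bank()
    cells = [(size, rep) for size in schedule.sizes for rep in range(schedule.repetitions)]
    children = np.random.SeedSequence(seed).spawn(len(cells))
    results = Parallel(n_jobs=n_jobs)(
        delayed(_one_repetition)(dataset, size, rep, specs, k, metrics, child)
        for (size, rep), child in zip(cells, children)
    )
    records = pd.DataFrame([row for rows in results for row in rows])
    records.attrs["dataset_fingerprint"] = dataset.fingerprint()
    return records


@dataclass
class EvaluationCurve:
    """Aggregated learning-curve tables.

    Attributes
    ----------
    accuracy : DataFrame
        One row per (classifier, sample_size): mean accuracy, SD, 95% CI.
    effect_sizes : DataFrame
        One row per sample_size: mean/SD of both aggregate effect sizes.
    changes : DataFrame
        One row per (classifier, consecutive size pair): relative accuracy
        change in percent of the smaller size's mean.
    """

    accuracy: pd.DataFrame
    effect_sizes: pd.DataFrame
    changes: pd.DataFrame
    dataset_fingerprint: str | None = None

    @property
    def sizes(self) -> list[int]:
        return sorted(self.accuracy["sample_size"].unique().tolist())

    @property
    def classifiers(self) -> list[str]:
        return sorted(self.accuracy["classifier"].unique().tolist())

    def mean_accuracy(self, size: int, classifier: str | None = None) -> float:
        """Mean accuracy at a size for one classifier, or the best family."""
        at = self.accuracy[self.accuracy["sample_size"] == size]
        if at.empty:
            raise KeyError(f"size {size} not in curve (sizes: {self.sizes})")
        if classifier is None:
            return float(at["mean_accuracy"].max())
        sel = at[at["classifier"] == classifier]
        if sel.empty:
            raise KeyError(f"classifier {classifier!r} not in curve")
        return float(sel["mean_accuracy"].iloc[0])

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy.to_dict(orient="records"),
            "effect_sizes": self.effect_sizes.to_dict(orient="records"),
            "changes": self.changes.to_dict(orient="records"),
            "dataset_fingerprint": self.dataset_fingerprint,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationCurve":
        return cls(
            accuracy=pd.DataFrame(d["accuracy"]),
            effect_sizes=pd.DataFrame(d["effect_sizes"]),
            changes=pd.DataFrame(d["changes"]),
            dataset_fingerprint=d.get("dataset_fingerprint"),
        )

    @classmethod
    def from_json(cls, path) -> "EvaluationCurve":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def aggregate_curve(records: pd.DataFrame) -> EvaluationCurve:
    """Aggregate a record table into an :class:`EvaluationCurve`.

    Per (classifier, size): mean, SD and the normal-approximation 95%
    confidence interval ``mean +/- 1.96 * SD / sqrt(reps)`` of accuracy.
    Per size: mean and SD of both effect sizes (measured once per
    subsample). Requires at least two repetitions per cell.
    """
    if records.empty:
        raise EmptyGroupError("no records to aggregate")
    grouped = records.groupby(["classifier", "sample_size"])["accuracy"]
    n_reps = grouped.size()
    if (n_reps < 2).any():
        bad = n_reps[n_reps < 2].index.tolist()
        raise EmptyGroupError(f"cells with < 2 repetitions: {bad}")
    acc = grouped.agg(mean_accuracy="mean", accuracy_sd="std", n_reps="size").reset_index()
    half = Z_95 * acc["accuracy_sd"] / np.sqrt(acc["n_reps"])
    acc["ci_low"] = acc["mean_accuracy"] - half
    acc["ci_high"] = acc["mean_accuracy"] + half

    per_sub = records.drop_duplicates(["sample_size", "repetition"])
    es = (
        per_sub.groupby("sample_size")[["d_average", "d_grand"]]
        .agg(["mean", "std"])
        .reset_index()
    )
    es.columns = ["sample_size", "d_average_mean", "d_average_sd", "d_grand_mean", "d_grand_sd"]

    curve = EvaluationCurve(
        accuracy=acc,
        effect_sizes=es,
        changes=pd.DataFrame(columns=["classifier", "from_size", "to_size", "change_pct"]),
        dataset_fingerprint=records.attrs.get("dataset_fingerprint"),
    )
    curve.changes = accuracy_change(curve)
    return curve


def accuracy_change(curve: EvaluationCurve) -> pd.DataFrame:
    """Relative change of mean accuracy between consecutive schedule sizes.

    ``change = 100 * |acc(next) - acc(size)| / acc(size)`` per classifier.
    A zero mean accuracy leaves the change undefined (NaN) with a warning.
    """
    rows = []
    sizes = curve.sizes
    for clf in curve.classifiers:
        for a, b in zip(sizes, sizes[1:]):
            acc_a = curve.mean_accuracy(a, clf)
            acc_b = curve.mean_accuracy(b, clf)
            if acc_a == 0:
                warnings.warn(
                    f"mean accuracy 0 at size {a} for {clf}; relative change undefined",
                    stacklevel=2,
                )
                change = np.nan
            else:
                change = 100.0 * abs(acc_b - acc_a) / acc_a
            rows.append(
                {"classifier": clf, "from_size": a, "to_size": b, "change_pct": change}
            )
    return pd.DataFrame(rows, columns=["classifier", "from_size", "to_size", "change_pct"])


class SampleSizeEvaluator(BaseEstimator):
    """Learning-curve evaluation of a two-class dataset, sklearn-style.

    ``fit(X, y)`` runs the whole subsampling protocol and exposes the
    record table and aggregated curve as fitted attributes.

    Parameters
    ----------
    sizes : list of int, optional
        Explicit total sample sizes; default doubles from ``start`` to the
        available balanced total.
    start : int, default=16
        Smallest total sample size of the default schedule.
    repetitions : int, default=100
        Random subsamples per size.
    families : tuple of str, optional
        Subset of the five classifier families; all five by default.
    k : int, default=10
        Cross-validation folds (reduced to the smaller class size when
        needed).
    metrics : bool, default=False
        Also record AUC-ROC, precision, recall and F1.
    random_state : int, optional
        Master seed for subsampling, fold shuffling and stochastic fits.
    n_jobs : int, default=1
        Parallelism over repetitions (result order is seed-determined, not
        execution-order-determined).

    Attributes
    ----------
    schedule_ : SubsampleSchedule
    records_ : DataFrame
    curve_ : EvaluationCurve
    """

    def __init__(
        self,
        sizes=None,
        start: int = DEFAULT_START_SIZE,
        repetitions: int = DEFAULT_REPETITIONS,
        families=None,
        k: int = DEFAULT_FOLDS,
        metrics: bool = False,
        random_state: int | None = None,
        n_jobs: int = 1,
    ):
        self.sizes = sizes
        self.start = start
        self.repetitions = repetitions
        self.families = families
        self.k = k
        self.metrics = metrics
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, y=None):
        dataset = X if isinstance(X, LabeledDataset) else LabeledDataset(np.asarray(X), np.asarray(y))
        counts = dataset.class_counts()
        if len(counts) != 2:
            dataset.require_two_classes()
        available = 2 * min(counts.values())
        self.schedule_ = build_schedule(
            available, start=self.start, repetitions=self.repetitions, sizes=self.sizes
        )
        specs = default_classifier_bank(self.families or FAMILIES)
        self.specs_ = specs
        self.records_ = run_evaluation(
            dataset,
            self.schedule_,
            specs,
            seed=self.random_state,
            k=self.k,
            metrics=self.metrics,
            n_jobs=self.n_jobs,
        )
        self.curve_ = aggregate_curve(self.records_)
        return self
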