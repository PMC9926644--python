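"""Average and grand Cohen's d for two-class feature tables.

Two aggregate statistics summarise the separation between classes:

* the **average effect size** ``d̄`` — the mean magnitude of per-variable
  Cohen's d over all variables — and
* the **grand effect size** ``d_g`` — Cohen's d computed from the *grand*
  mean (mean over variables of the per-variable class means) and the
  averaged per-variable class SDs.

The two coincide when every variable separates the classes the same way,
and diverge when variable-level effects point in opposite directions:
opposite-signed shifts cancel in the grand means but not in the average of
magnitudes. Per-variable d uses the standard two-group pooled SD with
weights ``(n_c - 1)`` and denominator ``(n_1 + n_2 - 2)``; all SDs are
sample SDs (``ddof=1``).

Sign convention: classes are ordered by sorted label value and per-variable
d is signed as (class 1 mean - class 2 mean) / pooled SD. The aggregate
statistics are magnitudes: ``d̄`` averages |d_j| and ``d_g`` is reported as
an absolute value, so both are >= 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datasets import LabeledDataset
from .errors import DegenerateVarianceError

__all__ = [
    "EffectSizeSummary",
    "EffectSizeEstimator",
    "per_variable_cohens_d",
    "average_effect_size",
    "grand_effect_size",
    "classify_effect_size",
    "compute_summary",
]

#: Cohen's-scale cut points: d <= 0.2 is a trivial difference, d >= 0.5 a
#: significant one; values strictly between are intermediate.
TRIVIAL_BOUND = 0.2
SIGNIFICANT_BOUND = 0.5


@dataclass
class EffectSizeSummary:
    """Per-variable and aggregate effect sizes of one two-class dataset."""

    per_variable_d: np.ndarray
    d_average: float
    d_grand: float
    n_class1: int
    n_class2: int
    n_variables: int
    classes: tuple = ("1", "2")
    variable_names: list[str] | None = None
    dataset_fingerprint: str | None = field(default=None)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["per_variable_d"] = np.asarray(self.per_variable_d).tolist()
        d["classes"] = [str(c) for c in self.classes]
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_frame(self) -> pd.DataFrame:
        """One row per variable with its signed Cohen's d."""
        names = self.variable_names or [f"var_{j}" for j in range(self.n_variables)]
        return pd.DataFrame({"variable": names, "cohens_d": np.asarray(self.per_variable_d)})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_json(cls, path) -> "EffectSizeSummary":
        with open(path) as fh:
            d = json.load(fh)
        # tolerate stamped extras (version, config hash, seed) in bundles
        d = {k: d[k] for k in (
            "per_variable_d", "d_average", "d_grand", "n_class1", "n_class2",
            "n_variables", "classes", "variable_names", "dataset_fingerprint",
        ) if k in d}
        d["per_variable_d"] = np.asarray(d["per_variable_d"], dtype=float)
        d["classes"] = tuple(d.get("classes", ("1", "2")))
        return cls(**d)


def _class_stats(dataset: LabeledDataset):
    """Per-class, per-variable means and sample SDs plus class counts."""
    x1, x2 = dataset.split_classes()
    return (
        x1.mean(axis=0),
        x2.mean(axis=0),
        x1.std(axis=0, ddof=1),
        x2.std(axis=0, ddof=1),
        x1.shape[0],
        x2.shape[0],
    )


def _pooled_sd(sd1, sd2, n1: int, n2: int):
    return np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))


def per_variable_cohens_d(
    dataset: LabeledDataset, on_constant: str = "raise"
) -> np.ndarray:
    """Signed Cohen's d of each variable, (class 1 - class 2) / pooled SD.

    Parameters
    ----------
    dataset : LabeledDataset
        Two-class data; classes ordered by sorted label.
    on_constant : {"raise", "drop"}
        What to do when a variable's pooled SD is zero (a constant
        variable). ``"raise"`` raises :class:`DegenerateVarianceError`;
        ``"drop"`` removes the variable with a warning, so the returned
        vector may be shorter than ``dataset.n_variables``.
    """
    if on_constant not in ("raise", "drop"):
        raise ValueError(f"on_constant must be 'raise' or 'drop', got {on_constant!r}")
    m1, m2, sd1, sd2, n1, n2 = _class_stats(dataset)
    pooled = _pooled_sd(sd1, sd2, n1, n2)
    degenerate = pooled == 0
    if degenerate.any():
        bad = [dataset._names()[j] for j in np.nonzero(degenerate)[0]]
        if on_constant == "raise":
            raise DegenerateVarianceError(
                f"zero pooled SD (constant variables): {bad}"
            )
        warnings.warn(f"dropping constant variables: {bad}", stacklevel=2)
        keep = ~degenerate
        return (m1[keep] - m2[keep]) / pooled[keep]
    return (m1 - m2) / pooled


def average_effect_size(dataset: LabeledDataset, on_constant: str = "raise") -> float:
    """Average effect size d̄: mean over variables of |per-variable d|."""
    d = per_variable_cohens_d(dataset, on_constant=on_constant)
    return float(np.mean(np.abs(d)))


def grand_effect_size(dataset: LabeledDataset) -> float:
    """Grand effect size d_g from grand means and averaged per-variable SDs.

    Per class the grand mean is the mean over variables of the per-variable
    means, and the grand SD is the mean over variables of the per-variable
    sample SDs; d_g is |grand mean difference| over the pooled grand SD.
    """
    m1, m2, sd1, sd2, n1, n2 = _class_stats(dataset)
    mu_g1, mu_g2 = m1.mean(), m2.mean()
    sigma_g1, sigma_g2 = sd1.mean(), sd2.mean()
    pooled_g = _pooled_sd(sigma_g1, sigma_g2, n1, n2)
    if pooled_g == 0:
        raise DegenerateVarianceError("grand pooled SD is zero")
    return float(abs(mu_g1 - mu_g2) / pooled_g)


def classify_effect_size(d: float) -> str:
    """Map a non-negative effect size onto Cohen's ordinal scale.

    ``d <= 0.2`` is ``"trivial"``, ``d >= 0.5`` is ``"significant"`` and
    anything strictly between is ``"intermediate"``. Callers pass
    magnitudes; negative input is rejected.
    """
    if d < 0:
        raise ValueError(f"effect size must be a magnitude >= 0, got {d}")
    if d <= TRIVIAL_BOUND:
        return "trivial"
    if d < SIGNIFICANT_BOUND:
        return "intermediate"
    return "significant"


class EffectSizeEstimator(BaseEstimator):
    """Compute per-variable Cohen's d and the two aggregate effect sizes.

    Follows the scikit-learn estimator contract: construct with
    hyperparameters only, call :meth:`fit` with ``(X, y)``, read fitted
    attributes with trailing underscores.

    Parameters
    ----------
    on_constant : {"raise", "drop"}, default="raise"
        Handling of zero-variance (constant) variables.

    Attributes
    ----------
    per_variable_d_ : ndarray
        Signed Cohen's d per variable, class order = sorted labels.
    d_average_ : float
        Mean magnitude of per-variable d (>= 0).
    d_grand_ : float
        Grand effect size (>= 0).
    classes_ : ndarray
        The two class labels in sorted order.
    summary_ : EffectSizeSummary
        All of the above bundled for serialisation.
    """

    def __init__(self, on_constant: str = "raise"):
        self.on_constant = on_constant

    def fit(self, X, y):
        dataset = X if isinstance(X, LabeledDataset) else LabeledDataset(np.asarray(X), np.asarray(y))
        self.per_variable_d_ = per_variable_cohens_d(dataset, on_constant=self.on_constant)
        self.d_average_ = float(np.mean(np.abs(self.per_variable_d_)))
        self.d_grand_ = grand_effect_size(dataset)
        self.classes_ = dataset.classes
        counts = dataset.class_counts()
        self.n_class1_ = counts[self.classes_[0]]
        self.n_class2_ = counts[self.classes_[1]]
        # under on_constant="drop" the d vector may be shorter than the matrix
        self.n_variables_ = len(self.per_variable_d_)
        names = dataset.variable_names if self.n_variables_ == dataset.n_variables else None
        self.summary_ = EffectSizeSummary(
            per_variable_d=self.per_variable_d_,
            d_average=self.d_average_,
            d_grand=self.d_grand_,
            n_class1=self.n_class1_,
            n_class2=self.n_class2_,
            n_variables=self.n_variables_,
            classes=tuple(str(c) for c in self.classes_),
            variable_names=names,
            dataset_fingerprint=dataset.fingerprint(),
        )
        return self

    def score(self, X=None, y=None) -> float:
        """The larger of the two aggregate effect sizes of the fitted data."""
        check_is_fitted(self, "d_average_")
        return max(self.d_average_, self.d_grand_)


def compute_summary(dataset: LabeledDataset, on_constant: str = "raise") -> EffectSizeSummary:
    """Convenience wrapper: fit an :class:`EffectSizeEstimator` on a dataset."""
    est = EffectSizeEstimator(on_constant=on_constant)
    est.fit(dataset, None)
    return est.summary_
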