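"""Sample-size adequacy criteria and remediation advice.

A decided sample size is judged adequate when it satisfies both rules:

* **Criterion 1** — at least one of the two aggregate effect sizes
  (average d̄ or grand d_g) is >= 0.5 (boundary inclusive, Cohen's scale).
* **Criterion 2** — the machine-learning accuracy at the decided size is
  >= 80%, and, when larger sizes past the accuracy threshold are also
  evaluated, the relative accuracy change to the next such size is
  strictly below 10%.

"The accuracy of a size" is, by default, the best classifier family's
mean cross-validated accuracy at that size; the criteria make a claim
about the data's separability, not about a particular family (`selector`
switches to a named family or the median).

When a size fails, the trends across the schedule point to one of three
remediations: accuracy rising while effect size stays flat calls for more
samples *and* different features; neither rising suggests the features are
uninformative and the design needs revision; a rising effect size that has
not yet crossed the threshold simply needs more samples. "Rising" means a
relative first-to-last increase above a small tolerance (5% by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .effect_size import EffectSizeSummary
from .evaluation import EvaluationCurve
from .errors import SizevalError

__all__ = [
    "CriteriaConfig",
    "CriteriaVerdict",
    "criterion1",
    "criterion2",
    "recommend_remediation",
    "evaluate_sample_size",
    "REMEDIATION_TEXT",
]

REMEDIATION_TEXT = {
    "none": "The decided sample size meets both criteria; additional samples "
            "are unlikely to change the effect sizes or accuracy materially.",
    "more_samples_and_features": "Accuracy improves with more samples but the "
            "effect sizes stay poor: collect more samples and acquire "
            "different, more discriminative features.",
    "revise_design_or_features": "Neither accuracy nor effect size improves "
            "with more samples: the features are not representative; revise "
            "the experimental design and acquire proper features.",
    "more_samples": "The effect size rises with sample size but has not yet "
            "passed the criteria: more samples are required.",
    "insufficient_schedule": "Only one sample size was evaluated; trends "
            "cannot be assessed. Evaluate additional sizes before deciding "
            "on a remediation.",
}


@dataclass
class CriteriaConfig:
    """Thresholds of the two adequacy criteria.

    es_threshold : minimum aggregate effect size (default 0.5, inclusive).
    acc_threshold : minimum accuracy as a proportion (default 0.80, inclusive).
    change_threshold : maximum between-size accuracy change in percent
        (default 10, exclusive — the change must be *smaller than* it).
    trend_tolerance : relative first-to-last increase above which a
        quantity counts as "increasing" (default 0.05).
    selector : "best", "median" or a classifier label — how the accuracy of
        a size is taken across families.
    stability_comparison : "next" compares the decided size with the next
        qualifying larger size; "any" requires stability against every
        qualifying larger size.
    """

    es_threshold: float = 0.5
    acc_threshold: float = 0.80
    change_threshold: float = 10.0
    trend_tolerance: float = 0.05
    selector: str = "best"
    stability_comparison: str = "next"

    def __post_init__(self) -> None:
        if self.es_threshold <= 0 or self.change_threshold <= 0 or self.trend_tolerance <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.acc_threshold < 1:
            raise ValueError(f"acc_threshold must lie in (0, 1), got {self.acc_threshold}")
        if self.stability_comparison not in ("next", "any"):
            raise ValueError("stability_comparison must be 'next' or 'any'")


@dataclass
class CriteriaVerdict:
    """Outcome of applying both criteria at one decided sample size."""

    criterion1_pass: bool
    criterion1_effect_size: float
    criterion1_which: str
    criterion2_pass: bool
    criterion2_detail: str
    criterion2_accuracy: float
    overall: str  # "adequate" | "inadequate"
    remediation: str
    decided_size: int
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        adequate = self.criterion1_pass and self.criterion2_pass
        assert (self.overall == "adequate") == adequate
        assert (self.remediation == "none") == (self.overall == "adequate")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def criterion1(summary: EffectSizeSummary, config: CriteriaConfig | None = None) -> bool:
    """At least one aggregate effect size reaches the threshold (inclusive)."""
    config = config or CriteriaConfig()
    return max(summary.d_average, summary.d_grand) >= config.es_threshold


def _size_accuracy(curve: EvaluationCurve, size: int, config: CriteriaConfig) -> float:
    at = curve.accuracy[curve.accuracy["sample_size"] == size]
    if at.empty:
        raise SizevalError(f"size {size} not present in curve (sizes: {curve.sizes})")
    if config.selector == "best":
        return float(at["mean_accuracy"].max())
    if config.selector == "median":
        return float(at["mean_accuracy"].median())
    sel = at[at["classifier"] == config.selector]
    if sel.empty:
        raise SizevalError(f"classifier {config.selector!r} not present in curve")
    return float(sel["mean_accuracy"].iloc[0])


def criterion2(
    curve: EvaluationCurve, decided_size: int, config: CriteriaConfig | None = None
) -> tuple[bool, str]:
    """Accuracy level and between-size stability at the decided size.

    Condition A: the selected accuracy at ``decided_size`` reaches
    ``acc_threshold`` (inclusive). Condition B applies only when larger
    sizes that themselves reach the threshold exist; the relative accuracy
    change from the decided size to the next such size (or every such size
    with ``stability_comparison="any"``) must be strictly below
    ``change_threshold`` percent.

    Returns (pass, detail) where detail names the failed sub-condition.
    """
    config = config or CriteriaConfig()
    acc = _size_accuracy(curve, decided_size, config)
    if acc < config.acc_threshold:
        return False, (
            f"accuracy level: {acc:.3f} < threshold {config.acc_threshold:.2f}"
        )
    larger = [
        s for s in curve.sizes
        if s > decided_size and _size_accuracy(curve, s, config) >= config.acc_threshold
    ]
    if not larger:
        return True, "accuracy level met; stability clause vacuous (no larger qualifying size)"
    compare = larger[:1] if config.stability_comparison == "next" else larger
    for s in compare:
        change = 100.0 * abs(_size_accuracy(curve, s, config) - acc) / acc
        if not change < config.change_threshold:
            return False, (
                f"stability: change {change:.2f}% from size {decided_size} to {s} "
                f"is not smaller than {config.change_threshold:.0f}%"
            )
    return True, "accuracy level and stability met"


def _relative_rise(first: float, last: float) -> float:
    if first == 0:
        return np.inf if last > 0 else 0.0
    return (last - first) / first


def recommend_remediation(
    curve: EvaluationCurve,
    es_trend=None,
    config: CriteriaConfig | None = None,
) -> str:
    """Map the accuracy and effect-size trends onto a remediation code.

    ``es_trend`` is the per-size aggregate effect size, defaulting to
    ``max(d̄, d_g)`` means from the curve. With a single evaluated size the
    outcome is ``"insufficient_schedule"`` — no trend, no guess.
    """
    config = config or CriteriaConfig()
    sizes = curve.sizes
    if len(sizes) < 2:
        return "insufficient_schedule"
    if es_trend is None:
        es = curve.effect_sizes.sort_values("sample_size")
        es_trend = np.maximum(
            es["d_average_mean"].to_numpy(), es["d_grand_mean"].to_numpy()
        )
    es_trend = np.asarray(es_trend, dtype=float)
    acc_up = (
        _relative_rise(
            _size_accuracy(curve, sizes[0], config), _size_accuracy(curve, sizes[-1], config)
        )
        > config.trend_tolerance
    )
    es_up = _relative_rise(float(es_trend[0]), float(es_trend[-1])) > config.trend_tolerance
    if es_up:
        # a rising effect size (even with rising accuracy) that still fails
        # the criteria is cured by sample size alone
        return "more_samples"
    if acc_up:
        return "more_samples_and_features"
    return "revise_design_or_features"


def evaluate_sample_size(
    summary: EffectSizeSummary,
    curve: EvaluationCurve,
    decided_size: int,
    config: CriteriaConfig | None = None,
) -> CriteriaVerdict:
    """Apply both criteria at the decided size and attach remediation advice.

    The effect-size summary and the curve are expected to come from the
    same dataset; a mismatch of recorded fingerprints is reported as a
    warning (the decision may mix studies).
    """
    config = config or CriteriaConfig()
    fp_s, fp_c = summary.dataset_fingerprint, curve.dataset_fingerprint
    if fp_s and fp_c and fp_s != fp_c:
        warnings.warn(
            f"effect-size summary (fingerprint {fp_s}) and evaluation curve "
            f"({fp_c}) come from different datasets",
            stacklevel=2,
        )
    c1 = criterion1(summary, config)
    which = "d_average" if summary.d_average >= summary.d_grand else "d_grand"
    c2, detail = criterion2(curve, decided_size, config)
    adequate = c1 and c2
    remediation = "none" if adequate else recommend_remediation(curve, config=config)
    return CriteriaVerdict(
        criterion1_pass=c1,
        criterion1_effect_size=float(max(summary.d_average, summary.d_grand)),
        criterion1_which=which,
        criterion2_pass=c2,
        criterion2_detail=detail,
        criterion2_accuracy=_size_accuracy(curve, decided_size, config),
        overall="adequate" if adequate else "inadequate",
        remediation=remediation,
        decided_size=decided_size,
        config=asdict(config),
    )
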