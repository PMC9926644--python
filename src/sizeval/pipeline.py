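"""End-to-end pipeline: simulate/load -> effect sizes -> evaluation -> verdict.

A :class:`RunConfig` fully determines a run: re-running the config written
into an output bundle reproduces every numeric artifact exactly. Each
bundle contains

* ``records.csv`` — one row per (size, repetition, classifier),
* ``curve.json`` — the aggregated learning curve,
* ``effect_size.json`` — effect sizes of the full input data,
* ``verdict.json`` — the criteria decision at the decided size,
* ``config.json`` — the config, tool version, config hash and master seed,
* ``run.log`` — per-stage structured log.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .criteria import REMEDIATION_TEXT, CriteriaConfig, CriteriaVerdict, evaluate_sample_size
from .datasets import LabeledDataset, load_csv
from .effect_size import EffectSizeEstimator, EffectSizeSummary
from .errors import MissingArtifactError
from .evaluation import (
    DEFAULT_FOLDS,
    DEFAULT_REPETITIONS,
    DEFAULT_START_SIZE,
    EvaluationCurve,
    SampleSizeEvaluator,
)
from .simulate import SimulationConfig, apply_quality_substitution, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "render_report"]

logger = logging.getLogger("sizeval")

ARTIFACTS = ("records.csv", "curve.json", "effect_size.json", "verdict.json", "config.json")


@dataclass
class RunConfig:
    """One self-contained, re-runnable pipeline configuration.

    Exactly one of ``input_csv`` and ``simulation`` must be set.
    ``decided_size`` defaults to the largest schedule size.
    """

    input_csv: str | None = None
    label_column: str = "label"
    simulation: dict | None = None
    sizes: list[int] | None = None
    start: int = DEFAULT_START_SIZE
    repetitions: int = DEFAULT_REPETITIONS
    families: list[str] | None = None
    k: int = DEFAULT_FOLDS
    metrics: bool = False
    es_threshold: float = 0.5
    acc_threshold: float = 0.80
    change_threshold: float = 10.0
    trend_tolerance: float = 0.05
    selector: str = "best"
    stability_comparison: str = "next"
    decided_size: int | None = None
    seed: int | None = None
    output_dir: str = "sizeval_out"
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if (self.input_csv is None) == (self.simulation is None):
            raise ValueError("exactly one of input_csv and simulation must be given")

    def criteria_config(self) -> CriteriaConfig:
        return CriteriaConfig(
            es_threshold=self.es_threshold,
            acc_threshold=self.acc_threshold,
            change_threshold=self.change_threshold,
            trend_tolerance=self.trend_tolerance,
            selector=self.selector,
            stability_comparison=self.stability_comparison,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Content hash of the numerically relevant config fields.

        Execution details that cannot change the numbers (output location,
        parallelism) are excluded, so the same analysis written to two
        places carries the same hash.
        """
        d = self.to_dict()
        d.pop("output_dir", None)
        d.pop("n_jobs", None)
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        d.pop("version", None)
        d.pop("config_hash", None)
        return cls.from_dict(d)


def _load_input(config: RunConfig) -> LabeledDataset:
    if config.input_csv is not None:
        logger.info("loading CSV %s (label column %r)", config.input_csv, config.label_column)
        return load_csv(config.input_csv, config.label_column)
    sim_dict = dict(config.simulation)
    if config.seed is not None and sim_dict.get("seed") is None:
        sim_dict["seed"] = config.seed
    sim = SimulationConfig(**sim_dict)
    logger.info("simulating dataset: %s", sim.to_dict())
    if sim.quality_fraction > 0:
        dataset, _, substituted = apply_quality_substitution(sim)
        logger.info("quality substitution replaced %d variables", len(substituted))
    else:
        dataset, _ = generate_dataset(sim)
    return dataset


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full protocol and write the output bundle.

    Returns a bundle dict with the dataset, summary, records, curve,
    verdict and the output directory.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("sizeval %s | config hash %s | master seed %s",
                    __version__, config.hash(), config.seed)
        dataset = _load_input(config)
        logger.info("dataset: %d samples x %d variables, classes %s",
                    dataset.n_samples, dataset.n_variables, dataset.class_counts())

        es = EffectSizeEstimator().fit(dataset, None)
        summary = es.summary_
        logger.info("effect sizes: d_average=%.4f d_grand=%.4f", es.d_average_, es.d_grand_)

        evaluator = SampleSizeEvaluator(
            sizes=config.sizes,
            start=config.start,
            repetitions=config.repetitions,
            families=tuple(config.families) if config.families else None,
            k=config.k,
            metrics=config.metrics,
            random_state=config.seed,
            n_jobs=config.n_jobs,
        )
        evaluator.fit(dataset)
        curve = evaluator.curve_
        logger.info("evaluation: sizes %s x %d repetitions x %d classifiers",
                    evaluator.schedule_.sizes, evaluator.schedule_.repetitions,
                    len(evaluator.specs_))

        decided = config.decided_size or evaluator.schedule_.sizes[-1]
        verdict = evaluate_sample_size(summary, curve, decided, config.criteria_config())
        logger.info("verdict at n=%d: %s (remediation: %s)",
                    decided, verdict.overall, verdict.remediation)

        stamp = {"version": __version__, "config_hash": config.hash(), "seed": config.seed}
        evaluator.records_.to_csv(out / "records.csv", index=False)
        _write_stamped(out / "curve.json", curve.to_dict(), stamp)
        _write_stamped(out / "effect_size.json", summary.to_dict(), stamp)
        _write_stamped(out / "verdict.json", verdict.to_dict(), stamp)
        _write_stamped(out / "config.json", config.to_dict(), stamp)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {
        "dataset": dataset,
        "summary": summary,
        "records": evaluator.records_,
        "curve": curve,
        "verdict": verdict,
        "output_dir": out,
    }


def _write_stamped(path: Path, payload: dict, stamp: dict) -> None:
    doc = dict(payload)
    doc.update(stamp)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)


def load_bundle(output_dir) -> dict:
    """Re-read a written bundle for reporting."""
    out = Path(output_dir)
    missing = [a for a in ARTIFACTS if not (out / a).exists()]
    if missing:
        raise MissingArtifactError(f"bundle {out} is missing artifacts: {missing}")
    with open(out / "verdict.json") as fh:
        verdict = json.load(fh)
    with open(out / "effect_size.json") as fh:
        summary = json.load(fh)
    return {
        "curve": EvaluationCurve.from_json(out / "curve.json"),
        "verdict": verdict,
        "summary": summary,
        "output_dir": out,
    }


def render_report(bundle, plots: bool = False) -> str:
    """Deterministic plain-text report of a bundle (optionally with plots).

    ``bundle`` is the dict returned by :func:`run_pipeline` or an output
    directory path. Plots (accuracy vs size with CI bands, effect sizes vs
    size, change bars) are written next to the bundle artifacts.
    """
    if not isinstance(bundle, dict):
        bundle = load_bundle(bundle)
    curve: EvaluationCurve = bundle["curve"]
    verdict = bundle["verdict"]
    if isinstance(verdict, CriteriaVerdict):
        verdict = verdict.to_dict()
    summary = bundle["summary"]
    if isinstance(summary, EffectSizeSummary):
        summary = summary.to_dict()

    lines = []
    lines.append("sample-size adequacy report")
    lines.append("=" * 27)
    lines.append(f"decided sample size: {verdict['decided_size']}")
    lines.append("")
    lines.append(f"criterion 1 (effect size >= {verdict['config']['es_threshold']}): "
                 f"{'PASS' if verdict['criterion1_pass'] else 'FAIL'} "
                 f"[max(d_average={summary['d_average']:.4f}, "
                 f"d_grand={summary['d_grand']:.4f}) = "
                 f"{verdict['criterion1_effect_size']:.4f}]")
    lines.append(f"criterion 2 (accuracy >= {verdict['config']['acc_threshold']:.0%}, "
                 f"change < {verdict['config']['change_threshold']:.0f}%): "
                 f"{'PASS' if verdict['criterion2_pass'] else 'FAIL'} "
                 f"[accuracy {verdict['criterion2_accuracy']:.4f}; "
                 f"{verdict['criterion2_detail']}]")
    lines.append("")
    lines.append(f"overall: the decided sample size is {verdict['overall'].upper()}")
    if verdict["remediation"] != "none":
        lines.append(f"remediation: {REMEDIATION_TEXT[verdict['remediation']]}")
    else:
        lines.append(REMEDIATION_TEXT["none"])
    lines.append("")
    lines.append("mean accuracy by classifier and size:")
    acc = curve.accuracy.pivot(index="sample_size", columns="classifier",
                               values="mean_accuracy")
    lines.append(acc.round(4).to_string())
    lines.append("")
    lines.append("effect sizes by size (mean +/- SD across subsamples):")
    lines.append(curve.effect_sizes.round(4).to_string(index=False))
    if len(curve.sizes) < 2:
        lines.append("")
        lines.append("note: single evaluated size; the stability clause of "
                     "criterion 2 is vacuous and trends are unavailable.")
    text = "\n".join(lines) + "\n"

    out = bundle.get("output_dir")
    if out is not None:
        with open(Path(out) / "report.txt", "w") as fh:
            fh.write(text)
        if plots:
            _render_plots(curve, Path(out))
    return text


def _render_plots(curve: EvaluationCurve, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for clf, grp in curve.accuracy.groupby("classifier"):
        grp = grp.sort_values("sample_size")
        ax.plot(grp["sample_size"], grp["mean_accuracy"], marker="o", label=clf)
        ax.fill_between(grp["sample_size"], grp["ci_low"], grp["ci_high"], alpha=0.2)
    ax.set_xscale("log", base=2)
    ax.set_xlabel("total sample size")
    ax.set_ylabel("mean CV accuracy (95% CI)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "accuracy_vs_size.png", dpi=120)
    plt.close(fig)

    es = curve.effect_sizes.sort_values("sample_size")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for col, lab in (("d_average", "average effect size"), ("d_grand", "grand effect size")):
        ax.errorbar(es["sample_size"], es[f"{col}_mean"], yerr=es[f"{col}_sd"],
                    marker="o", capsize=3, label=lab)
    ax.set_xscale("log", base=2)
    ax.set_xlabel("total sample size")
    ax.set_ylabel("effect size (a.u.)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "effect_size_vs_size.png", dpi=120)
    plt.close(fig)

    if not curve.changes.empty:
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for clf, grp in curve.changes.groupby("classifier"):
            ax.plot(grp["to_size"], grp["change_pct"], marker="s", label=clf)
        ax.set_xscale("log", base=2)
        ax.set_xlabel("total sample size (upper of the pair)")
        ax.set_ylabel("relative accuracy change (%)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "accuracy_change.png", dpi=120)
        plt.close(fig)
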