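"""Two-class Gaussian simulator with controlled per-variable effect sizes.

Each variable j is drawn independently: class 1 values follow
``Normal(0, noise_sd^2)`` and class 2 values follow
``Normal(d_j * noise_sd, noise_sd^2)``, so the *population* Cohen's d of
variable j equals the target ``d_j``. Targets are drawn uniformly from a
regime-specific range:

* ``good``  — d ~ U(0.5, 1.4), a clearly separable dataset;
* ``poor``  — d ~ U(0.01, 0.2), trivial separation on Cohen's scale;
* ``custom`` — caller-supplied ``d_range``.

The *quality substitution* manipulation starts from a poor dataset and
regenerates the class-2 values of a chosen fraction of variables with
good-regime mean shifts, emulating a study in which only part of the
feature panel is informative. The fraction counts variables, not samples,
and the substituted subsets are nested across fractions under a fixed seed
(fraction 0 leaves the poor dataset untouched; fraction 1 yields a fully
good dataset).

Randomness flows from one master seed through named, deterministically
spawned child streams (targets, class values, substitution), so a
configuration reproduces bit-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .datasets import LabeledDataset
from .errors import InvalidRangeError

__all__ = [
    "SimulationConfig",
    "REGIME_RANGES",
    "draw_effect_targets",
    "generate_dataset",
    "apply_quality_substitution",
]

#: Default target-d ranges per regime (dimensionless, Cohen's d scale).
REGIME_RANGES = {"good": (0.5, 1.4), "poor": (0.01, 0.2)}

#: Minimum samples per class: half the protocol's smallest total of 16.
MIN_PER_CLASS = 8

# named offsets into the master SeedSequence spawn, so adding a stage never
# silently reshuffles another stage's stream
_STREAMS = {"targets": 0, "values": 1, "subst_select": 2, "subst_values": 3}


@dataclass
class SimulationConfig:
    """Configuration of one simulated two-class dataset.

    Parameters
    ----------
    n_per_class : int
        Samples per class (>= 8, i.e. half the smallest evaluated total).
    n_variables : int, default=100
        Number of feature columns.
    regime : {"good", "poor", "custom"}
        Chooses the default ``d_range``; ``custom`` requires an explicit one.
    d_range : (float, float), optional
        Bounds of the uniform per-variable target-d distribution.
    quality_fraction : float in [0, 1], default=0.0
        Fraction of variables substituted with good-regime variables by
        :func:`apply_quality_substitution`.
    noise_sd : float, default=1.0
        Within-class standard deviation sigma (arbitrary units).
    seed : int, optional
        Master seed; all child streams derive from it.
    """

    n_per_class: int
    n_variables: int = 100
    regime: str = "custom"
    d_range: tuple[float, float] | None = None
    quality_fraction: float = 0.0
    noise_sd: float = 1.0
    seed: int | None = None
    labels: tuple = field(default=("class1", "class2"))
    #: optional variable-variable correlation matrix; identity (independent
    #: variables) when None. Targets then control the *marginal* d.
    correlation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.regime not in ("good", "poor", "custom"):
            raise InvalidRangeError(f"unknown regime {self.regime!r}")
        if self.d_range is None:
            if self.regime == "custom":
                raise InvalidRangeError("regime 'custom' requires an explicit d_range")
            self.d_range = REGIME_RANGES[self.regime]
        low, high = self.d_range
        if not (0 <= low <= high):
            raise InvalidRangeError(f"d_range must satisfy 0 <= low <= high, got {self.d_range}")
        if not 0 <= self.quality_fraction <= 1:
            raise InvalidRangeError(
                f"quality_fraction must lie in [0, 1], got {self.quality_fraction}"
            )
        if self.n_per_class < MIN_PER_CLASS:
            raise InvalidRangeError(
                f"n_per_class must be >= {MIN_PER_CLASS}, got {self.n_per_class}"
            )
        if self.noise_sd <= 0:
            raise InvalidRangeError(f"noise_sd must be positive, got {self.noise_sd}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["d_range"] = list(self.d_range)
        d["labels"] = list(self.labels)
        if self.correlation is not None:
            d["correlation"] = np.asarray(self.correlation).tolist()
        return d

    def child_rngs(self) -> dict[str, np.random.Generator]:
        """Named per-stage generators spawned deterministically from the seed."""
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(children[i]) for name, i in _STREAMS.items()}


def draw_effect_targets(config: SimulationConfig, rng: np.random.Generator | None = None) -> np.ndarray:
    """Draw the per-variable target Cohen's d, uniform over ``config.d_range``."""
    if rng is None:
        rng = config.child_rngs()["targets"]
    low, high = config.d_range
    return rng.uniform(low, high, size=config.n_variables)


def _sample_classes(
    targets: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n, v, sd = config.n_per_class, config.n_variables, config.noise_sd
    if config.correlation is None:
        x1 = rng.normal(0.0, sd, size=(n, v))
        x2 = rng.normal(targets * sd, sd, size=(n, v))
    else:
        corr = np.asarray(config.correlation, dtype=float)
        if corr.shape != (v, v):
            raise InvalidRangeError(f"correlation must be {v}x{v}, got {corr.shape}")
        chol = np.linalg.cholesky(corr)
        x1 = rng.standard_normal((n, v)) @ chol.T * sd
        x2 = rng.standard_normal((n, v)) @ chol.T * sd + targets * sd
    return x1, x2


def _assemble(x1: np.ndarray, x2: np.ndarray, config: SimulationConfig) -> LabeledDataset:
    values = np.vstack([x1, x2])
    labels = np.array(
        [config.labels[0]] * x1.shape[0] + [config.labels[1]] * x2.shape[0]
    )
    return LabeledDataset(values, labels)


def generate_dataset(config: SimulationConfig) -> tuple[LabeledDataset, np.ndarray]:
    """Simulate a balanced two-class dataset; returns (dataset, target d vector).

    Class 1 is centred at zero and class 2 is shifted by ``d_j * noise_sd``
    on variable j, so each variable's population Cohen's d equals its
    target. Fully reproducible under ``config.seed``.
    """
    rngs = config.child_rngs()
    targets = draw_effect_targets(config, rngs["targets"])
    x1, x2 = _sample_classes(targets, config, rngs["values"])
    return _assemble(x1, x2, config), targets


def apply_quality_substitution(
    config: SimulationConfig,
) -> tuple[LabeledDataset, np.ndarray, np.ndarray]:
    """Poor dataset with a fraction of variables replaced by good ones.

    Generates the base dataset from the poor regime under ``config.seed``,
    then regenerates the class-2 values of ``round(quality_fraction * vs)``
    randomly chosen variables with good-regime mean shifts (the class-1
    values stay untouched, so the manipulation perturbs one group only).

    Returns
    -------
    dataset : LabeledDataset
    targets : ndarray
        Per-variable population d after substitution.
    substituted : ndarray of int
        Indices of the substituted variables (nested across fractions for
        a fixed seed: a larger fraction substitutes a superset).
    """
    if config.regime != "poor":
        raise InvalidRangeError(
            f"quality substitution starts from the poor regime, got {config.regime!r}"
        )
    rngs = config.child_rngs()
    targets = draw_effect_targets(config, rngs["targets"])
    x1, x2 = _sample_classes(targets, config, rngs["values"])

    n_sub = round(config.quality_fraction * config.n_variables)
    # one permutation and one full good draw per seed: subsets are nested in
    # the fraction and each variable keeps its good target across fractions
    order = rngs["subst_select"].permutation(config.n_variables)
    substituted = np.sort(order[:n_sub])
    good_low, good_high = REGIME_RANGES["good"]
    good_targets = rngs["subst_values"].uniform(good_low, good_high, config.n_variables)
    good_x2 = rngs["subst_values"].normal(
        good_targets * config.noise_sd, config.noise_sd,
        size=(config.n_per_class, config.n_variables),
    )

    targets = targets.copy()
    targets[substituted] = good_targets[substituted]
    x2 = x2.copy()
    x2[:, substituted] = good_x2[:, substituted]
    return _assemble(x1, x2, config), targets, substituted
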