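"""Synthetic wide classification tables with a known informative core.

The generator emulates the shape of high-dimensional biomedical tables
(features ≫ informative features): a small set of informative columns
draws from class-dependent Gaussians whose means are evenly spaced
across a total range of ``effect_size`` noise standard deviations (for
two classes, exactly ``effect_size·noise_sd`` apart), and the remaining
columns are label-independent Gaussian noise. Informative columns are scattered
at random positions (not a prefix), so index/name mix-ups surface in
tests. A Student-t noise option stress-tests importance ranking under
heavy tails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import FeatureTable
from .errors import ConfigurationError

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "recovery_score"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic table.

    ``effect_size`` is the total spread of the class means in units of
    ``noise_sd`` (equal to the adjacent-class spacing for two classes);
    0 makes informative columns indistinguishable from noise. ``class_proportions`` defaults to balanced classes; counts
    follow largest-remainder rounding. ``noise_df`` switches noise to a
    Student-t with that many degrees of freedom (None = Gaussian).
    """

    n_samples: int = 400
    n_features: int = 210
    n_informative: int = 10
    n_classes: int = 3
    effect_size: float = 2.0
    noise_sd: float = 1.0
    class_proportions: tuple[float, ...] | None = None
    noise_df: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ConfigurationError("n_informative cannot exceed n_features")
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if self.class_proportions is not None:
            props = tuple(float(p) for p in self.class_proportions)
            if len(props) != self.n_classes:
                raise ConfigurationError("one proportion per class required")
            if any(p <= 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
                raise ConfigurationError("proportions must be positive and sum to 1")
            object.__setattr__(self, "class_proportions", props)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: which features carry signal, and where."""

    informative_feature_names: frozenset[str]
    class_means: dict[str, dict[str, float]] = field(default_factory=dict)
    # class_means[feature][class] = mean of that feature in that class


def _class_counts(spec: SyntheticSpec) -> list[int]:
    props = spec.class_proportions or tuple(
        1.0 / spec.n_classes for _ in range(spec.n_classes)
    )
    exact = [p * spec.n_samples for p in props]
    counts = [int(np.floor(e)) for e in exact]
    remainders = [e - c for e, c in zip(exact, counts)]
    for i in sorted(range(spec.n_classes), key=lambda i: -remainders[i])[
        : spec.n_samples - sum(counts)
    ]:
        counts[i] += 1
    if any(c < 1 for c in counts):
        raise ConfigurationError(
            f"class counts {counts} leave an empty class; increase n_samples"
        )
    return counts


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw one table and its ground truth, deterministically from the seed."""
    rng = np.random.default_rng(spec.seed)
    counts = _class_counts(spec)
    labels = np.repeat([f"c{i}" for i in range(spec.n_classes)], counts)

    width = len(str(spec.n_features))
    names = [f"f{i + 1:0{width}d}" for i in range(spec.n_features)]
    informative_idx = rng.choice(spec.n_features, size=spec.n_informative,
                                 replace=False)

    if spec.noise_df is None:
        values = rng.normal(0.0, spec.noise_sd,
                            size=(spec.n_samples, spec.n_features))
    else:
        values = rng.standard_t(spec.noise_df,
                                size=(spec.n_samples, spec.n_features)) * spec.noise_sd

    class_means: dict[str, dict[str, float]] = {}
    row_class = np.repeat(np.arange(spec.n_classes), counts)
    spacing = spec.effect_size * spec.noise_sd / (spec.n_classes - 1)
    for j in informative_idx:
        # each informative feature orders the classes its own way
        offsets = rng.permutation(spec.n_classes) * spacing
        values[:, j] += offsets[row_class]
        class_means[names[j]] = {
            f"c{c}": float(offsets[c]) for c in range(spec.n_classes)
        }

    table = FeatureTable(
        values=values,
        feature_names=tuple(names),
        labels=tuple(labels),
        sample_ids=tuple(f"s{i:04d}" for i in range(spec.n_samples)),
    )
    truth = GroundTruth(
        informative_feature_names=frozenset(names[j] for j in informative_idx),
        class_means=class_means,
    )
    return table, truth


def recovery_score(selected, truth: GroundTruth,
                   n_features: int | None = None) -> tuple[float, float]:
    """(sensitivity, false-positive fraction) of a selected feature set.

    Sensitivity is the recovered fraction of the planted informative
    features; the false-positive fraction is the share of
    non-informative features that leaked into the selection (0 when the
    non-informative pool size is unknown and nothing noisy was picked).
    """
    selected = set(selected)
    informative = truth.informative_feature_names
    sensitivity = (
        len(selected & informative) / len(informative) if informative else 0.0
    )
    false_picks = selected - informative
    if n_features is None:
        n_features = len(informative) + len(false_picks)
    n_noise = n_features - len(informative)
    fpr = len(false_picks) / n_noise if n_noise else 0.0
    return sensitivity, fpr
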