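"""Empirical-distribution-function bootstrap resampling.

The bootstrap sample X* = X*_1..X*_O is drawn uniformly with replacement
from the original O observations — i.e. by sampling the empirical
distribution function F̂_O(t) = (1/O) Σ I(X_i ≤ t). The draw is
unstratified; a redraw guard keeps every class present so downstream
stratified cross-validation stays well defined.

The pipeline applies this draw at up to three positions:

* ``outer`` — once per run, before any selection (OFBS); the forest then
  sees the whole (resampled) table per tree.
* ``inner`` — no outer draw; each tree of the forest resamples (IFBS).
* ``outer_inner`` — both (O/IFBS).
* ``none`` — ablation baseline: plain RFS-RFE on the original table.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .data_model import FeatureTable
from .errors import DataError, ResamplingError

__all__ = ["BootstrapPosition", "BootstrapSpec", "empirical_cdf", "draw_bootstrap"]

#: redraws allowed before giving up on class coverage
_COVERAGE_RETRIES = 100


class BootstrapPosition(str, Enum):
    """Where in the pipeline the with-replacement draw is applied."""

    OUTER = "outer"
    INNER = "inner"
    OUTER_INNER = "outer_inner"
    NONE = "none"

    @classmethod
    def parse(cls, text: str) -> "BootstrapPosition":
        aliases = {"both": cls.OUTER_INNER, "o/i": cls.OUTER_INNER}
        text = text.strip().lower()
        if text in aliases:
            return aliases[text]
        try:
            return cls(text)
        except ValueError:
            raise ValueError(
                f"unknown bootstrap position {text!r}; "
                f"expected one of outer, inner, outer_inner/both, none"
            ) from None

    @property
    def outer_draw(self) -> bool:
        return self in (BootstrapPosition.OUTER, BootstrapPosition.OUTER_INNER)

    @property
    def per_tree_bootstrap(self) -> bool:
        return self in (BootstrapPosition.INNER, BootstrapPosition.OUTER_INNER)


@dataclass(frozen=True)
class BootstrapSpec:
    position: BootstrapPosition = BootstrapPosition.OUTER
    seed: int = 0


def empirical_cdf(values, t: float) -> float:
    """Evaluate the EDF F̂_O(t) = (1/O) Σ I(X_i ≤ t).

    Right-continuous and monotone non-decreasing in ``t``; 0 below the
    sample minimum and 1 at or above the maximum.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise DataError("empirical_cdf requires at least one observation")
    return float(np.count_nonzero(values <= t)) / values.size


def draw_bootstrap(table: FeatureTable, seed: int) -> FeatureTable:
    """Draw a with-replacement sample of the table's own size.

    Every output row is an exact copy of some input row. Duplicated
    sample ids get a ``#k`` suffix so ids stay unique. If a class is
    missing from the draw (possible for rare classes in small tables),
    the draw is repeated with an incremented seed up to 100 times.
    """
    if table.n_samples < 1:
        raise DataError("cannot bootstrap an empty table")
    wanted = set(table.classes)
    for attempt in range(_COVERAGE_RETRIES):
        rng = np.random.default_rng(seed + attempt)
        idx = rng.integers(0, table.n_samples, size=table.n_samples)
        drawn = {table.labels[i] for i in idx}
        if drawn == wanted:
            return table.take_rows(idx, sample_ids=_dedupe_ids(table, idx))
    missing = sorted(wanted - drawn)
    raise ResamplingError(
        f"bootstrap failed to cover class(es) {missing} in {_COVERAGE_RETRIES} attempts"
    )


def _dedupe_ids(table: FeatureTable, idx: np.ndarray) -> list[str]:
    counts: dict[str, int] = {}
    out = []
    for i in idx:
        base = table.sample_ids[i]
        k = counts.get(base, 0)
        counts[base] = k + 1
        out.append(base if k == 0 else f"{base}#{k}")
    return out
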