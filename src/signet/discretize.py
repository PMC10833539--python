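"""Discretization of per-sample activity measurements into level patterns.

Every entity (gene, TF-coding gene or regulatory region) is reduced to a
fixed-length *pattern*: one discrete level per cell population.  Variable
entities are min-max binned into four levels (1 = population minimum,
4 = maximum), silent entities get an all-``0`` pattern and entities with
constant activity an all-``5`` pattern.  The binning is performed per
entity, so patterns capture relative dynamics, not absolute magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SILENT = "silent"
CONSTANT = "constant"
VARIABLE = "variable"

ENTITY_CLASSES = (SILENT, CONSTANT, VARIABLE)

#: patterns are single-digit strings, one digit per population
MAX_POPULATIONS = 9


class DegenerateRangeError(ValueError):
    """Raised when a variable entity has zero activity range.

    Such an entity must be classified ``constant`` instead of being
    discretized.
    """


@dataclass(frozen=True)
class ActivityMatrix:
    """Per-population log10 mean activities for a set of entities.

    Attributes
    ----------
    populations:
        Ordered population labels (length ``n``).
    values:
        DataFrame indexed by entity id with one column per population,
        holding log10 of the per-population mean activity.
    raw_means:
        Same shape as ``values`` but before the pseudocount/log transform;
        used for silent-entity detection.
    """

    populations: tuple[str, ...]
    values: pd.DataFrame
    raw_means: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.populations):
            raise ValueError("value columns must match the declared population order")

    def row(self, entity_id: str) -> np.ndarray:
        return self.values.loc[entity_id].to_numpy(dtype=float)


def population_log_means(
    sample_table: pd.DataFrame,
    sample_map: Mapping[str, str],
    populations: Sequence[str] | None = None,
    pseudocount: float = 1.0,
) -> ActivityMatrix:
    """Average samples per population and log10-transform.

    Parameters
    ----------
    sample_table:
        Entities x samples table of normalized counts/densities.
    sample_map:
        Sample name -> population label.  Every column of ``sample_table``
        must be mapped.
    populations:
        Output population order; defaults to first-appearance order of the
        mapped populations.
    pseudocount:
        Added to each per-population mean before the log so that zero
        activities stay finite.  Silent-entity detection happens upstream
        on the raw means, so the pseudocount never masks silence.
    """
    unmapped = [s for s in sample_table.columns if s not in sample_map]
    if unmapped:
        raise ValueError(f"samples without a population mapping: {unmapped}")
    if populations is None:
        seen: dict[str, None] = {}
        for s in sample_table.columns:
            seen.setdefault(sample_map[s], None)
        populations = list(seen)
    by_pop: dict[str, list[str]] = {p: [] for p in populations}
    for s in sample_table.columns:
        p = sample_map[s]
        if p in by_pop:
            by_pop[p].append(s)
    empty = [p for p, cols in by_pop.items() if not cols]
    if empty:
        raise ValueError(f"populations with no samples: {empty}")

    raw = pd.DataFrame(
        {p: sample_table[cols].mean(axis=1) for p, cols in by_pop.items()},
        index=sample_table.index,
    )
    with np.errstate(divide="ignore"):
        values = np.log10(raw + pseudocount)
    return ActivityMatrix(tuple(populations), values, raw_means=raw)


def level_of(value: float, vmin: float, vmax: float, n_bins: int = 4) -> int:
    """Min-max bin one log-mean value onto the 1..n_bins scale.

    The range [vmin, vmax] is split into ``n_bins`` equal intervals; the
    minimum maps to 1 and the maximum to ``n_bins``:
    ``max(1, ceil(n_bins * (value - vmin) / (vmax - vmin)))``.
    A value exactly on an interior boundary k/n_bins of the range gets
    level k (ceil of an integer).
    """
    if vmax <= vmin:
        raise DegenerateRangeError(
            f"degenerate range [{vmin}, {vmax}]: classify the entity constant"
        )
    if not (vmin <= value <= vmax):
        raise ValueError(f"value {value} outside [{vmin}, {vmax}]")
    lev = max(1, math.ceil(n_bins * (value - vmin) / (vmax - vmin)))
    return min(lev, n_bins)  # guards float noise at value == vmax


def pattern_of(log_means: Sequence[float] | np.ndarray, cls: str, n_bins: int = 4) -> str:
    """Build the pattern string for one entity given its class.

    silent -> all-0, constant -> all-5, variable -> elementwise
    :func:`level_of` against the row min/max.
    """
    vals = np.asarray(log_means, dtype=float)
    n = vals.size
    if n > MAX_POPULATIONS:
        raise ValueError(
            f"{n} populations exceed the {MAX_POPULATIONS}-digit pattern encoding"
        )
    if cls == SILENT:
        return "0" * n
    if cls == CONSTANT:
        return "5" * n
    if cls != VARIABLE:
        raise ValueError(f"unknown entity class {cls!r}")
    vmin, vmax = float(vals.min()), float(vals.max())
    return "".join(str(level_of(v, vmin, vmax, n_bins=n_bins)) for v in vals)


def classify_entity(
    raw_means: Sequence[float] | np.ndarray,
    log_means: Sequence[float] | np.ndarray,
    de_label: str | None = None,
    activity_floor: float = 1.0,
    constancy_epsilon: float = 1e-9,
) -> str:
    """Classify an entity as silent / constant / variable.

    An external label (e.g. from a differential-expression analysis) always
    wins.  Otherwise: silent when every per-population raw mean is below
    ``activity_floor``; constant when the log-mean range is below
    ``constancy_epsilon``; variable otherwise.
    """
    if de_label is not None:
        if de_label not in ENTITY_CLASSES:
            raise ValueError(f"invalid external class {de_label!r}")
        return de_label
    raw = np.asarray(raw_means, dtype=float)
    if (raw < activity_floor).all():
        return SILENT
    logm = np.asarray(log_means, dtype=float)
    if logm.max() - logm.min() < constancy_epsilon:
        return CONSTANT
    return VARIABLE


def discretize_table(
    sample_table: pd.DataFrame,
    sample_map: Mapping[str, str],
    populations: Sequence[str] | None = None,
    de_info: Mapping[str, str] | None = None,
    pseudocount: float = 1.0,
    activity_floor: float = 1.0,
    constancy_epsilon: float = 1e-9,
    n_bins: int = 4,
) -> pd.DataFrame:
    """Run the full discretization on a samples table.

    Returns a DataFrame with columns ``entity_id``, ``class``, ``pattern``,
    in the input row order.
    """
    mat = population_log_means(
        sample_table, sample_map, populations=populations, pseudocount=pseudocount
    )
    de_info = de_info or {}
    records = []
    for entity in mat.values.index:
        raw = mat.raw_means.loc[entity].to_numpy(dtype=float)
        logm = mat.values.loc[entity].to_numpy(dtype=float)
        cls = classify_entity(
            raw,
            logm,
            de_label=de_info.get(entity),
            activity_floor=activity_floor,
            constancy_epsilon=constancy_epsilon,
        )
        if cls != SILENT and not np.isfinite(logm).all():
            raise ValueError(
                f"non-finite log activity for {entity!r}; raise the pseudocount"
            )
        if cls == VARIABLE and logm.max() - logm.min() <= 0:
            # externally forced variable but flat: refuse silently degrading
            raise DegenerateRangeError(
                f"entity {entity!r} labeled variable but has zero log-range"
            )
        records.append((entity, cls, pattern_of(logm, cls, n_bins=n_bins)))
    return pd.DataFrame(records, columns=["entity_id", "class", "pattern"])


# ---------------------------------------------------------------------------
# pattern helpers shared by downstream modules


def pattern_levels(pattern: str) -> tuple[int, ...]:
    return tuple(int(c) for c in pattern)


def is_silent(pattern: str) -> bool:
    return len(pattern) > 0 and set(pattern) == {"0"}


def is_constant(pattern: str) -> bool:
    return len(pattern) > 0 and set(pattern) == {"5"}


def is_variable(pattern: str) -> bool:
    levels = set(pattern)
    return (
        len(pattern) > 0
        and levels <= {"1", "2", "3", "4"}
        and "1" in levels
        and "4" in levels
    )


def validate_pattern(pattern: str) -> None:
    """Check the structural pattern invariant (all-0, all-5, or 1..4 with
    both extremes present)."""
    if not (is_silent(pattern) or is_constant(pattern) or is_variable(pattern)):
        raise ValueError(f"invalid pattern {pattern!r}")
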