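"""Construct multiple views from one feature table by presence filtering.

OTU tables produced by different preprocessing pipelines can be turned into
a grid of views by filtering features on how many individuals carry them:

* ``frequency`` — keep a feature if it is present (count > 0) in at least a
  given *number* of individuals;
* ``prevalence`` — keep a feature if it is present in at least a given
  *fraction* of individuals;
* ``none`` — keep everything (the unfiltered view).

With the default thresholds (frequency {2, 5, 10, 50}, prevalence
{2%, 5%, 10%, 20%, 50%}, plus the unfiltered table) each input table yields
exactly 10 views; four input tables (e.g. one per OTU clustering threshold)
yield 40.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import IntegrityError, ParameterError, ViewTable

__all__ = [
    "FilterSpec",
    "filter_features",
    "build_view_grid",
    "DEFAULT_FREQ_THRESHOLDS",
    "DEFAULT_PREV_THRESHOLDS",
]

logger = logging.getLogger(__name__)

DEFAULT_FREQ_THRESHOLDS: tuple[int, ...] = (2, 5, 10, 50)
DEFAULT_PREV_THRESHOLDS: tuple[float, ...] = (0.02, 0.05, 0.10, 0.20, 0.50)


@dataclass(frozen=True)
class FilterSpec:
    """One filtering configuration.

    mode="frequency": ``threshold`` is the minimum number of individuals in
    which a feature must be present.  mode="prevalence": ``threshold`` is the
    minimum fraction (in (0, 1]) of individuals.  mode="none": identity.
    """

    mode: str
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("frequency", "prevalence", "none"):
            raise ParameterError(f"unknown filter mode {self.mode!r}")
        if self.mode == "none":
            if self.threshold is not None:
                raise ParameterError("mode='none' carries no threshold")
            return
        if self.threshold is None or self.threshold <= 0:
            raise ParameterError("threshold must be positive")
        if self.mode == "frequency" and int(self.threshold) != self.threshold:
            raise ParameterError("frequency threshold must be an integer")
        if self.mode == "prevalence" and not 0 < self.threshold <= 1:
            raise ParameterError("prevalence threshold must be in (0, 1]")

    def tag(self) -> str:
        if self.mode == "none":
            return "raw"
        if self.mode == "frequency":
            return f"freq{int(self.threshold)}"
        return f"prev{self.threshold * 100:g}pct"


def filter_features(table: ViewTable, spec: FilterSpec) -> ViewTable:
    """Keep the features whose presence count meets ``spec``.

    Presence means a strictly positive value.  The sample set and the
    relative feature order are unchanged.  Comparison is inclusive
    (count >= threshold).
    """
    if table.is_empty:
        raise IntegrityError("cannot filter an empty table")
    if spec.mode == "none":
        return ViewTable(f"{table.view_id}__raw", table.data.copy())
    presence = (table.values > 0).sum(axis=0)
    if spec.mode == "frequency":
        min_count = float(int(spec.threshold))
    else:
        # fraction of individuals; tiny slack guards against float artifacts
        # such as 0.1 * 30 = 3.0000000000000004 dropping presence == 3
        min_count = spec.threshold * table.n_samples - 1e-9
    keep = np.flatnonzero(presence >= min_count)
    if keep.size == 0:
        raise IntegrityError(
            f"filter {spec.tag()} removes every feature of "
            f"{table.view_id!r}; use a weaker threshold"
        )
    cols = [table.feature_ids[i] for i in keep]
    return ViewTable(f"{table.view_id}__{spec.tag()}", table.data[cols].copy())


def build_view_grid(
    table: ViewTable,
    freq_thresholds: Sequence[int] = DEFAULT_FREQ_THRESHOLDS,
    prev_thresholds: Sequence[float] = DEFAULT_PREV_THRESHOLDS,
    include_unfiltered: bool = True,
) -> list[ViewTable]:
    """One view per filter configuration, skipping (with a log line) any
    configuration that would empty the table so large grids always complete.
    """
    freq_thresholds = list(freq_thresholds or [])
    prev_thresholds = list(prev_thresholds or [])
    if not freq_thresholds and not prev_thresholds and not include_unfiltered:
        raise ParameterError("no filter configuration requested")
    specs = [FilterSpec("frequency", t) for t in freq_thresholds]
    specs += [FilterSpec("prevalence", t) for t in prev_thresholds]
    if include_unfiltered:
        specs.append(FilterSpec("none"))
    out: list[ViewTable] = []
    for spec in specs:
        try:
            out.append(filter_features(table, spec))
        except IntegrityError as exc:
            logger.warning("skipping configuration %s: %s", spec.tag(), exc)
    return out


def equivalent_frequency(prev_threshold: float, n_samples: int) -> int:
    """Frequency threshold selecting the same features as a prevalence one."""
    return max(1, math.ceil(prev_threshold * n_samples - 1e-9))
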