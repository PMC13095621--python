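"""Rule-based four-type endplate shape classification.

An endplate profile is one of four morphological types:

* ``flat`` — concavity depth < 1 mm;
* ``flat_bottom`` — depth >= 1 mm with a plateau-like depression floor
  ("flat-bottomed concave");
* ``asymmetric_concave`` — depth >= 1 mm and margin-to-apex length ratio
  >= 1.3;
* ``uniform_concave`` — depth >= 1 mm, ratio between 1 and 1.3.

The depth and ratio cut-offs are the study conventions for lumbar
endplates; the plateau criterion (floor span >= 30% of the chord)
operationalizes "flat surface on both sides of the depression", which has
no published numeric threshold.  The flat-bottom rule is applied before
the ratio rule because a plateau floor can carry any asymmetry ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import math

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .morphometry import ProfileMetrics

SEGMENTS = ("L4_sup", "L4_inf", "L5_sup", "L5_inf", "S1_sup")


class ShapeClass(str, Enum):
    UNIFORM_CONCAVE = "uniform_concave"
    ASYMMETRIC_CONCAVE = "asymmetric_concave"
    FLAT_BOTTOM = "flat_bottom"
    FLAT = "flat"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CLASS_ORDER = (ShapeClass.UNIFORM_CONCAVE, ShapeClass.ASYMMETRIC_CONCAVE,
               ShapeClass.FLAT_BOTTOM, ShapeClass.FLAT)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the four-type rules (all exposed, defaults are the
    study conventions)."""

    depth_threshold: float = 1.0      # mm; depth below this is flat
    ratio_threshold: float = 1.3      # length ratio at/above this is asymmetric
    plateau_threshold: float = 0.30   # floor span fraction at/above this is flat-bottom

    def __post_init__(self):
        if self.depth_threshold <= 0 or self.plateau_threshold <= 0:
            raise ParameterError("thresholds must be positive")
        if self.ratio_threshold <= 1:
            raise ParameterError("ratio_threshold must exceed 1")


def classify(metrics: ProfileMetrics,
             config: ClassifierConfig | None = None) -> ShapeClass:
    """Assign one of the four shape classes to a measured profile.

    Boundary behaviour: depth exactly at the threshold is concave
    (">= 1 mm"), ratio exactly at the threshold is asymmetric (">= 1.3").
    """
    config = config or ClassifierConfig()
    vals = (metrics.concavity_depth, metrics.ratio, metrics.plateau_fraction)
    if not all(math.isfinite(v) for v in vals):
        raise InputError(f"non-finite metrics: depth/ratio/plateau = {vals}")
    if metrics.concavity_depth < config.depth_threshold:
        return ShapeClass.FLAT
    if metrics.plateau_fraction >= config.plateau_threshold:
        return ShapeClass.FLAT_BOTTOM
    if metrics.ratio >= config.ratio_threshold:
        return ShapeClass.ASYMMETRIC_CONCAVE
    return ShapeClass.UNIFORM_CONCAVE


def classify_cohort(records) -> pd.DataFrame:
    """Per-segment shape distribution table.

    ``records`` is an iterable of mappings (or a DataFrame) with at least
    ``segment`` and ``shape_class`` keys.  Returns a table indexed by
    segment (plus a ``total`` row) with one count column and one
    percentage column per class; percentages are per segment.
    """
    df = pd.DataFrame(records)
    if "segment" not in df or "shape_class" not in df:
        raise InputError("records need 'segment' and 'shape_class' fields")
    unknown = set(df["segment"]) - set(SEGMENTS)
    if unknown:
        raise InputError(f"unknown segment labels: {sorted(unknown)}")
    classes = [c.value for c in CLASS_ORDER]
    bad = set(df["shape_class"].astype(str)) - set(classes)
    if bad:
        raise InputError(f"unknown shape classes: {sorted(bad)}")

    counts = (df.assign(shape_class=df["shape_class"].astype(str))
                .groupby(["segment", "shape_class"]).size()
                .unstack(fill_value=0)
                .reindex(index=[s for s in SEGMENTS
                                if s in set(df["segment"])],
                         columns=classes, fill_value=0))
    counts.loc["total"] = counts.sum(axis=0)
    out = counts.copy()
    totals = counts.sum(axis=1)
    for c in classes:
        out[f"{c}_pct"] = np.where(totals > 0,
                                   100.0 * counts[c] / totals, 0.0)
    out.index.name = "segment"
    return out


def distribution_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Same layout as :func:`classify_cohort` but starting from a
    segment x class count table (e.g. a published form-distribution
    table)."""
    classes = [c.value for c in CLASS_ORDER]
    missing = [c for c in classes if c not in counts.columns]
    if missing:
        raise InputError(f"count table lacks class columns: {missing}")
    tab = counts[classes].copy()
    tab.loc["total"] = tab.sum(axis=0)
    totals = tab.sum(axis=1)
    for c in classes:
        tab[f"{c}_pct"] = 100.0 * tab[c] / totals
    tab.index.name = "segment"
    return tab
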