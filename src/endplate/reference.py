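"""Bundled summary tables from the reference cohort.

The package ships the published summary tables of a 33-patient
(19 male, 14 female) young-adult lumbar cohort — 165 endplates across
L4 sup/inf, L5 sup/inf and S1 sup — as plain CSV files:

* ``form_distribution_<plane>.csv`` — per-segment counts of the four
  shape classes (whole cohort);
* ``morphology_by_sex_<plane>.csv`` — the same counts split by sex
  (2 x 4 contingency tables per segment);
* ``depth_by_sex_<plane>.csv`` — concavity-depth summaries
  (n, mean, SD in mm) per segment and sex.

These tables drive the synthetic generator's default class mixes and
serve as fixed inputs for the statistics layer; they are aggregate
numbers only, no patient-level data.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import InputError

_PLANES = ("sagittal", "coronal")
SEX_LEVELS = ("male", "female")
CLASS_COLUMNS = ("uniform_concave", "asymmetric_concave", "flat_bottom", "flat")


def _read(name: str) -> pd.DataFrame:
    with resources.files("endplate.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def _check_plane(plane: str):
    if plane not in _PLANES:
        raise InputError(f"plane must be one of {_PLANES}, got {plane!r}")


def load_form_distribution(plane: str) -> pd.DataFrame:
    """Segment x class count table for the whole reference cohort."""
    _check_plane(plane)
    return _read(f"form_distribution_{plane}.csv").set_index("segment")


def load_morphology_by_sex(plane: str) -> pd.DataFrame:
    """Per-segment, per-sex shape-class counts (long format)."""
    _check_plane(plane)
    return _read(f"morphology_by_sex_{plane}.csv")


def load_depth_by_sex(plane: str) -> pd.DataFrame:
    """Per-segment, per-sex concavity-depth summaries (n, mean, sd)."""
    _check_plane(plane)
    return _read(f"depth_by_sex_{plane}.csv")


def contingency_for_segment(plane: str, segment: str) -> np.ndarray:
    """2 x 4 (sex x class) count table for one segment."""
    df = load_morphology_by_sex(plane)
    sub = df[df["segment"] == segment]
    if len(sub) != 2:
        raise InputError(f"no 2-sex table for segment {segment!r}")
    sub = sub.set_index("sex").loc[list(SEX_LEVELS), list(CLASS_COLUMNS)]
    return sub.to_numpy(dtype=np.int64)


def depth_summaries_for_segment(plane: str, segment: str):
    """(male, female) GroupSummary pair for one segment's depth."""
    from .stats import GroupSummary

    df = load_depth_by_sex(plane)
    sub = df[df["segment"] == segment].set_index("sex")
    if set(SEX_LEVELS) - set(sub.index):
        raise InputError(f"no depth summaries for segment {segment!r}")
    out = []
    for sex in SEX_LEVELS:
        row = sub.loc[sex]
        out.append(GroupSummary(int(row["n"]), float(row["mean"]),
                                float(row["sd"])))
    return tuple(out)
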