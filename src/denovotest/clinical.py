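"""Clinical feature summaries and behavioral metrics.

Covers three small, exactly-specified computations:

* frequencies of categorical clinical features and means of developmental
  milestones over a matrix of individuals (cells may be present/absent/missing,
  a number of months, or an interval like ``24-30``);
* preference indices for social recognition and three-chamber sociability
  assays, PI = (t1 - t2) / (t1 + t2) in [-1, 1];
* hysteresis segmentation of open-field velocity traces into movement bouts
  (a bout starts at two consecutive frames at or above 2 cm/s and stops at two
  consecutive frames below 1.75 cm/s).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

PRESENT_MARKERS = {"+"}
ABSENT_MARKERS = {"-", "−"}  # ASCII hyphen and Unicode minus
MISSING_MARKERS = {"", "na", "nan", "none", "?"}

_INTERVAL_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*[-–]\s*(\d+(?:\.\d+)?)\s*$")


class ClinicalMatrix:
    """Individuals x features matrix with categorical and numeric rows.

    Stored as a DataFrame with features as rows and individuals as columns
    (cells are raw strings).  Categorical cells are ``+`` (present), ``-``
    (absent) or missing; any other non-missing token — a qualifier such as
    ``retro`` or ``broad based`` — counts as present for its binary feature.
    Numeric milestone cells are months, an interval ``lo-hi`` (contributing
    its midpoint), or missing.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.index.has_duplicates:
            raise ValueError("duplicate feature names")
        if frame.columns.has_duplicates:
            raise ValueError("duplicate individual ids")
        self.frame = frame.astype("string")

    @classmethod
    def from_tsv(cls, path) -> "ClinicalMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype="string",
                         keep_default_na=False, comment="#")
        return cls(df)

    @property
    def individuals(self) -> tuple:
        return tuple(self.frame.columns)

    @property
    def features(self) -> tuple:
        return tuple(self.frame.index)

    def _row(self, feature: str) -> pd.Series:
        if feature not in self.frame.index:
            raise KeyError(f"feature {feature!r} not in matrix")
        return self.frame.loc[feature]

    @staticmethod
    def _is_missing(cell) -> bool:
        if cell is None or (isinstance(cell, float) and math.isnan(cell)):
            return True
        return str(cell).strip().lower() in MISSING_MARKERS


def feature_frequency(matrix: ClinicalMatrix, feature: str) -> tuple:
    """(present, informative, truncated percent) for a categorical feature.

    The percentage denominator is the number of individuals with information
    available for the feature; the percentage is truncated toward zero.
    """
    row = matrix._row(feature)
    present = informative = 0
    for cell in row:
        if ClinicalMatrix._is_missing(cell):
            continue
        informative += 1
        token = str(cell).strip()
        if token in ABSENT_MARKERS:
            continue
        present += 1  # '+' or a qualified entry both count as present
    if informative == 0:
        raise ValueError(f"no informative individuals for feature {feature!r}")
    return present, informative, (100 * present) // informative


def milestone_mean(matrix: ClinicalMatrix, milestone: str) -> float:
    """Arithmetic mean age (months); intervals contribute their midpoint."""
    row = matrix._row(milestone)
    values = []
    for cell in row:
        if ClinicalMatrix._is_missing(cell):
            continue
        token = str(cell).strip()
        m = _INTERVAL_RE.match(token)
        if m:
            values.append((float(m.group(1)) + float(m.group(2))) / 2.0)
            continue
        try:
            values.append(float(token))
        except ValueError:
            continue  # annotated non-numeric cell, e.g. "NA (few words ...)"
    if not values:
        raise ValueError(f"no informative values for milestone {milestone!r}")
    return math.fsum(values) / len(values)


def load_table1() -> ClinicalMatrix:
    """The packaged 11-individual clinical matrix fixture."""
    ref = resources.files("denovotest.data").joinpath("table1_clinical.tsv")
    with resources.as_file(ref) as path:
        return ClinicalMatrix.from_tsv(path)


# -- preference indices --------------------------------------------------------


def discrimination_pi(t_novel: float, t_familiar: float) -> float:
    """Social recognition preference index: (novel - familiar)/(novel + familiar)."""
    if t_novel < 0 or t_familiar < 0:
        raise ValueError("investigation times must be >= 0")
    total = t_novel + t_familiar
    if total <= 0:
        raise ValueError("at least one investigation time must be > 0")
    return (t_novel - t_familiar) / total


def chamber_pi(t_social: float, t_object: float, innate_pi: float = 0.0) -> float:
    """Three-chamber sociability PI, normalised by subtracting the innate
    (habituation-phase) chamber preference."""
    if t_social < 0 or t_object < 0:
        raise ValueError("chamber times must be >= 0")
    total = t_social + t_object
    if total <= 0:
        raise ValueError("at least one chamber time must be > 0")
    return (t_social - t_object) / total - innate_pi


# -- movement bout segmentation -------------------------------------------------


@dataclass(frozen=True)
class VelocityTrace:
    """Per-frame speed samples (cm/s) at a fixed frame rate."""

    velocities: np.ndarray
    frame_rate: float = 25.0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        v = np.asarray(self.velocities, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("trace must be a 1-D array of at least 2 frames")
        if np.any(v < 0):
            raise ValueError("speeds must be >= 0")
        object.__setattr__(self, "velocities", v)

    @property
    def n_frames(self) -> int:
        return int(self.velocities.size)

    @classmethod
    def from_csv(cls, path, frame_rate: float = 25.0) -> "VelocityTrace":
        df = pd.read_csv(path)
        if "velocity" not in df.columns:
            raise ValueError("trace CSV requires a 'velocity' column")
        return cls(df["velocity"].to_numpy(dtype=float), frame_rate=frame_rate)


def movement_bouts(trace: VelocityTrace, start_threshold: float = 2.0,
                   stop_threshold: float = 1.75) -> list:
    """Hysteresis segmentation of a velocity trace into movement bouts.

    A bout opens at the first of two consecutive frames with v >= the start
    threshold, and closes at the first frame below the stop threshold whose
    successor is also below it (or which is the final frame).  Bouts are
    returned as disjoint, ordered, half-open ``(start_frame, end_frame)``
    intervals in frames.  Persistence windows are two frames, as defined for
    the open-field assay; both thresholds are configurable.
    """
    if stop_threshold > start_threshold:
        raise ValueError("stop threshold must not exceed start threshold")
    v = trace.velocities
    n = v.size
    bouts = []
    i = 0
    moving = False
    start = None
    while i < n:
        if not moving:
            if i + 1 < n and v[i] >= start_threshold and v[i + 1] >= start_threshold:
                moving, start = True, i
            i += 1
        else:
            if v[i] < stop_threshold and (i + 1 >= n or v[i + 1] < stop_threshold):
                bouts.append((start, i))
                moving = False
            i += 1
    if moving:
        bouts.append((start, n))
    return bouts


def total_bout_duration(bouts) -> int:
    return sum(e - s for s, e in bouts)
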