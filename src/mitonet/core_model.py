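"""Abundance-ratio data model and three-way regulation classification.

Quantitative proteomics compares protein abundance between mtDNA-depleted
(rho0) and parental (rho+) mitochondria as a linear-scale ratio rho0/rho+.
Each quantified protein is classified as *up*-regulated (ratio >= 1.5),
*down*-regulated (ratio <= 0.67, i.e. a 1.5-fold decrease) or *unchanged*
(strictly in between).  Both cut-offs are inclusive and configurable.

Ratios are consumed on the linear scale throughout; log transforms happen
only in the concordance analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"
REGULATION_CLASSES = (UP, DOWN, UNCHANGED)


@dataclass(frozen=True)
class ClassificationThresholds:
    """Fold-change cut-offs for the three-way regulation call.

    Parameters
    ----------
    up_min : float
        Minimum linear ratio for an up call (inclusive).  Default 1.5.
    down_max : float
        Maximum linear ratio for a down call (inclusive).  Default 0.67,
        the conventional printed value for a 1.5-fold decrease (not the
        exact fraction 2/3).
    """

    up_min: float = 1.5
    down_max: float = 0.67

    def __post_init__(self) -> None:
        if not (0.0 < self.down_max < self.up_min):
            raise ValueError(
                f"thresholds must satisfy 0 < down_max < up_min, "
                f"got down_max={self.down_max}, up_min={self.up_min}"
            )


DEFAULT_THRESHOLDS = ClassificationThresholds()


@dataclass
class AbundanceRecord:
    """One quantified protein with its rho0/rho+ abundance ratio."""

    protein_id: str
    protein_ratio: float
    regulation: Optional[str] = None


def classify_abundance(
    ratio: float,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
    protein_id: Optional[str] = None,
) -> str:
    """Classify a single linear abundance ratio.

    Returns ``"up"`` iff ``ratio >= thresholds.up_min``, ``"down"`` iff
    ``ratio <= thresholds.down_max`` and ``"unchanged"`` otherwise; both
    boundaries are inclusive.

    Raises
    ------
    ValueError
        If the ratio is non-positive or non-finite.  The message names the
        offending protein when ``protein_id`` is given.
    """
    try:
        value = float(ratio)
    except (TypeError, ValueError):
        value = math.nan
    if not math.isfinite(value) or value <= 0.0:
        who = f" for protein {protein_id!r}" if protein_id is not None else ""
        raise ValueError(
            f"abundance ratio must be a positive finite number, got {ratio!r}{who}"
        )
    if value >= thresholds.up_min:
        return UP
    if value <= thresholds.down_max:
        return DOWN
    return UNCHANGED


def classify_table(
    table: pd.DataFrame,
    thresholds: ClassificationThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Classify every row of an abundance table.

    ``table`` needs columns ``protein_id`` and ``protein_ratio``.  Rows with
    a missing ratio are dropped (the count is logged); non-positive or
    non-finite ratios are rejected with the protein named.  Returns a copy
    with a ``regulation`` column appended.
    """
    required = {"protein_id", "protein_ratio"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"abundance table lacks columns: {sorted(missing)}")
    out = table.copy()
    n_missing = int(out["protein_ratio"].isna().sum())
    if n_missing:
        logger.info("dropping %d rows with missing abundance ratio", n_missing)
        out = out[out["protein_ratio"].notna()]
    out = out.reset_index(drop=True)
    out["regulation"] = [
        classify_abundance(r, thresholds, protein_id=p)
        for p, r in zip(out["protein_id"], out["protein_ratio"])
    ]
    return out


@dataclass(frozen=True)
class ClassSummary:
    """Counts of the three regulation classes over one dataset."""

    n_up: int
    n_down: int
    n_unchanged: int
    n_total: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.n_total < 0:
            object.__setattr__(
                self, "n_total", self.n_up + self.n_down + self.n_unchanged
            )
        if self.n_up + self.n_down + self.n_unchanged != self.n_total:
            raise ValueError("class counts do not sum to n_total")

    def percentages(self) -> dict:
        """Per-class percentage of n_total, rounded to two decimals."""
        if self.n_total == 0:
            return {UP: 0.0, DOWN: 0.0, UNCHANGED: 0.0}
        return {
            UP: round(100.0 * self.n_up / self.n_total, 2),
            DOWN: round(100.0 * self.n_down / self.n_total, 2),
            UNCHANGED: round(100.0 * self.n_unchanged / self.n_total, 2),
        }


def summarize_classes(records) -> ClassSummary:
    """Summarize regulation classes of classified records.

    Accepts a classified DataFrame (``protein_id``/``regulation`` columns)
    or an iterable of :class:`AbundanceRecord` with ``regulation`` set.
    Duplicate protein ids are rejected.
    """
    if isinstance(records, pd.DataFrame):
        ids = list(records["protein_id"])
        classes = list(records["regulation"])
    else:
        records = list(records)
        ids = [r.protein_id for r in records]
        classes = [r.regulation for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate protein ids: {dup[:5]}")
    bad = [c for c in classes if c not in REGULATION_CLASSES]
    if bad:
        raise ValueError(f"unclassified or invalid regulation values: {bad[:5]}")
    return ClassSummary(
        n_up=classes.count(UP),
        n_down=classes.count(DOWN),
        n_unchanged=classes.count(UNCHANGED),
    )
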