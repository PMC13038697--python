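"""Four-value repeatability analysis of lung tissue volume.

For one subject scanned on two different days, inspiratory and expiratory
tissue volumes give four values.  "Variation" between any two of them is
defined as their absolute difference expressed as a percentage of the
largest of the four values (the largest is "set to 100%").  Reported are all
six pairwise variations, their min and max, the min/max over the four
cross-day pairs only, and the designated same-phase between-day variations
(expiration vs expiration, inspiration vs inspiration).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FourValueSet", "VariationReport", "variation_metrics", "cohort_repeatability"]

_LABELS = ("exp_day1", "ins_day1", "exp_day2", "ins_day2")


@dataclass(frozen=True)
class FourValueSet:
    """Tissue volumes (ml) from two phases on each of two days."""

    exp_day1: float
    ins_day1: float
    exp_day2: float
    ins_day2: float
    subject_id: str = ""

    def values(self) -> tuple[float, float, float, float]:
        return (self.exp_day1, self.ins_day1, self.exp_day2, self.ins_day2)

    def __post_init__(self) -> None:
        if any(v <= 0 or not np.isfinite(v) for v in self.values()):
            raise ValueError(f"all four tissue volumes must be positive: {self.values()}")


@dataclass(frozen=True)
class VariationReport:
    """Pairwise percent variations for one subject (percent of the largest value)."""

    pairwise_pct: dict[tuple[str, str], float]
    max_pct: float
    min_pct: float
    cross_day_max_pct: float
    cross_day_min_pct: float
    exp_between_days_pct: float
    ins_between_days_pct: float
    subject_id: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "max_pct": self.max_pct,
            "min_pct": self.min_pct,
            "cross_day_max_pct": self.cross_day_max_pct,
            "cross_day_min_pct": self.cross_day_min_pct,
            "exp_between_days_pct": self.exp_between_days_pct,
            "ins_between_days_pct": self.ins_between_days_pct,
        }


def variation_metrics(s: FourValueSet) -> VariationReport:
    """All pairwise |difference| / max-of-four x 100 metrics for one subject."""
    vals = dict(zip(_LABELS, s.values()))
    largest = max(vals.values())
    pairwise = {
        (a, b): 100.0 * abs(vals[a] - vals[b]) / largest
        for a, b in combinations(_LABELS, 2)
    }
    cross_day = {
        k: v for k, v in pairwise.items() if k[0].endswith("day1") and k[1].endswith("day2")
    }
    return VariationReport(
        pairwise_pct=pairwise,
        max_pct=max(pairwise.values()),
        min_pct=min(pairwise.values()),
        cross_day_max_pct=max(cross_day.values()),
        cross_day_min_pct=min(cross_day.values()),
        exp_between_days_pct=pairwise[("exp_day1", "exp_day2")],
        ins_between_days_pct=pairwise[("ins_day1", "ins_day2")],
        subject_id=s.subject_id,
    )


def cohort_repeatability(cohort: Sequence[FourValueSet]) -> pd.DataFrame:
    """Mean +- SD of each variation metric across subjects.

    Returns a DataFrame indexed by metric with columns ``mean_pct``,
    ``sd_pct``, ``n`` and ``sd_defined``.  With a single subject the SD is
    reported as 0 and flagged undefined.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    rows = [variation_metrics(s).as_dict() for s in cohort]
    df = pd.DataFrame(rows)
    n = len(rows)
    out = pd.DataFrame(
        {
            "mean_pct": df.mean(),
            "sd_pct": df.std(ddof=1) if n > 1 else pd.Series(0.0, index=df.columns),
            "n": n,
            "sd_defined": n > 1,
        }
    )
    out.index.name = "metric"
    return out
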