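"""Choosing the working air CT number via the inspiration dilution model.

Inspiration adds a volume of pure air to the expiratory lung.  Treating CT
numbers like solute concentrations, the inspiratory mean CT number is the
expiratory "mean x volume" total plus the inspired air's contribution,
divided by the inspiratory volume:

    n_theory = (n_exp * V_exp + n_air * (V_ins - V_exp)) / V_ins

Comparing n_theory against the actually measured inspiratory mean, for
candidate air CT numbers (-1000 HU nominal, or the trachea air actually
measured on either phase), scores how realistic each candidate is: the
smaller the error, the better the candidate describes air as imaged.
Because of the scatter effect, measured trachea air (about -980 HU)
systematically beats the nominal -1000 HU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .volume_model import LungMeasurement

__all__ = [
    "PairedScan",
    "AirDefinition",
    "AirComparisonResult",
    "theoretical_inspiratory_mean",
    "dilution_error",
    "default_air_definitions",
    "compare_air_definitions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedScan:
    """One subject's paired expiratory/inspiratory lung measurement.

    ``exp_air_hu`` / ``ins_air_hu`` are the trachea ROI air CT numbers on
    each phase.  Inspiratory volume is expected to exceed expiratory volume;
    a violation is flagged (QC), not fatal.
    """

    exp: LungMeasurement
    ins: LungMeasurement
    exp_air_hu: float
    ins_air_hu: float
    subject_id: str = ""
    scan_date: str = ""

    @property
    def volume_ordering_ok(self) -> bool:
        return self.ins.volume_ml >= self.exp.volume_ml

    def __post_init__(self) -> None:
        if not self.volume_ordering_ok:
            logger.warning(
                "PairedScan %s %s: inspiratory volume %.1f ml below expiratory %.1f ml",
                self.subject_id, self.scan_date, self.ins.volume_ml, self.exp.volume_ml,
            )


def theoretical_inspiratory_mean(p: PairedScan, air_hu: float) -> float:
    """Dilution-model prediction of the inspiratory mean CT number.

    (n_exp * V_exp + air_hu * (V_ins - V_exp)) / V_ins — linear in
    ``air_hu`` with slope (V_ins - V_exp) / V_ins.
    """
    if p.ins.volume_ml <= 0:
        raise ValueError("inspiratory total volume must be positive")
    return (
        p.exp.mean_hu * p.exp.volume_ml + air_hu * (p.ins.volume_ml - p.exp.volume_ml)
    ) / p.ins.volume_ml


def dilution_error(p: PairedScan, air_hu: float) -> float:
    """|theoretical - actually measured| inspiratory mean CT number, HU."""
    return abs(theoretical_inspiratory_mean(p, air_hu) - p.ins.mean_hu)


@dataclass(frozen=True)
class AirDefinition:
    """A candidate definition of the air CT number, constant or per-scan."""

    name: str
    value: Callable[[PairedScan], float]

    @classmethod
    def constant(cls, name: str, hu: float) -> "AirDefinition":
        return cls(name=name, value=lambda p: hu)


def default_air_definitions() -> list[AirDefinition]:
    """Nominal -1000 HU plus the two measured-trachea candidates."""
    return [
        AirDefinition.constant("minus_1000", -1000.0),
        AirDefinition("measured_expiratory", lambda p: p.exp_air_hu),
        AirDefinition("measured_inspiratory", lambda p: p.ins_air_hu),
    ]


@dataclass(frozen=True)
class AirComparisonResult:
    """Per-candidate dilution errors, their summary, and pairwise tests."""

    errors: dict[str, np.ndarray]
    summary: pd.DataFrame  # index: candidate; columns: mean_hu, sd_hu, n
    p_values: dict[tuple[str, str], float] = field(default_factory=dict)
    winner: str = ""


def compare_air_definitions(
    cohort: Sequence[PairedScan],
    definitions: Sequence[AirDefinition] | None = None,
) -> AirComparisonResult:
    """Score candidate air CT numbers on a paired-scan cohort.

    For each candidate the per-case dilution error vector and its mean +- SD
    are computed; candidates are compared pairwise with the two-sided
    Wilcoxon signed-rank test (exact for n <= 25 without zero differences,
    normal approximation otherwise).  The winner is the candidate with the
    smallest mean error.  With fewer than two scans only descriptive output
    is produced.
    """
    if definitions is None:
        definitions = default_air_definitions()
    if not cohort:
        raise ValueError("cohort is empty")
    errors = {
        d.name: np.array([dilution_error(p, d.value(p)) for p in cohort])
        for d in definitions
    }
    n = len(cohort)
    summary = pd.DataFrame(
        {
            "mean_hu": {k: v.mean() for k, v in errors.items()},
            "sd_hu": {k: v.std(ddof=1) if n > 1 else 0.0 for k, v in errors.items()},
            "n": {k: n for k in errors},
        }
    )
    p_values: dict[tuple[str, str], float] = {}
    if n >= 2:
        names = list(errors)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                diff = errors[a] - errors[b]
                if np.all(diff == 0):
                    p_values[(a, b)] = 1.0
                    continue
                method = "exact" if n <= 25 and not np.any(diff == 0) else "approx"
                res = stats.wilcoxon(errors[a], errors[b], alternative="two-sided",
                                     method=method)
                p_values[(a, b)] = float(res.pvalue)
    else:
        logger.info("cohort of size 1: skipping paired rank tests")
    winner = summary["mean_hu"].idxmin()
    return AirComparisonResult(errors=errors, summary=summary, p_values=p_values,
                               winner=str(winner))
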