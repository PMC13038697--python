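"""Published normative linear models for lung tissue volume, and cohort
correlation utilities.

The shipped models predict lung tissue volume (ml, measured-air convention)
from either subject height (m) or total lung volume (ml), fitted on 100
normal never-smokers (50 male, 50 female).  They are frozen constants — the
published normative surface — and are never refitted; :func:`fit_linear` is
available for synthetic cohorts but returns a new model object.

Correlation strength follows the conventional bands: |r| > 0.7 strong,
0.4 < |r| <= 0.7 moderate, 0.2 < |r| <= 0.4 weak, |r| <= 0.2 absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LinearModel",
    "SubjectRecord",
    "SHIPPED_MODELS",
    "get_model",
    "predict",
    "invert",
    "fit_linear",
    "strength_label",
    "cohort_correlations",
    "constants_manifest",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinearModel:
    """A y = slope * x + intercept model with its reported correlation."""

    slope: float
    intercept: float
    predictor_name: str  # "height_m" | "total_volume_ml"
    population: str  # "pooled" | "male" | "female"
    r: float


#: Published regression coefficients, keyed by (predictor, population).
SHIPPED_MODELS: dict[tuple[str, str], LinearModel] = {
    ("height_m", "pooled"): LinearModel(584.71, -464.19, "height_m", "pooled", 0.65),
    ("height_m", "male"): LinearModel(362.11, -76.003, "height_m", "male", 0.36),
    ("height_m", "female"): LinearModel(401.49, -192.33, "height_m", "female", 0.39),
    ("total_volume_ml", "pooled"): LinearModel(0.0689, 215.33, "total_volume_ml", "pooled", 0.75),
    ("total_volume_ml", "male"): LinearModel(0.0493, 314.82, "total_volume_ml", "male", 0.63),
    ("total_volume_ml", "female"): LinearModel(0.0666, 210.78, "total_volume_ml", "female", 0.54),
}


def get_model(predictor: str = "height_m", population: str = "pooled") -> LinearModel:
    try:
        return SHIPPED_MODELS[(predictor, population)]
    except KeyError:
        raise KeyError(
            f"no shipped model for predictor={predictor!r}, population={population!r}; "
            f"available: {sorted(SHIPPED_MODELS)}"
        ) from None


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's covariates and measured volumes (missing values None)."""

    id: str
    sex: str  # "male" | "female"
    age: float | None = None
    height_m: float | None = None
    weight_kg: float | None = None
    bsa_m2: float | None = None
    tissue_volume_ml: float | None = None
    total_volume_ml: float | None = None

    def __post_init__(self) -> None:
        for name in ("height_m", "weight_kg", "bsa_m2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when present, got {v}")


def predict(model: LinearModel, x: float) -> float:
    """Predicted tissue volume (ml) at predictor value ``x``."""
    if x <= 0:
        raise ValueError(f"predictor value must be positive, got {x}")
    return model.slope * x + model.intercept


def invert(model: LinearModel, y: float) -> float:
    """Predictor value at which the model predicts ``y`` ml."""
    if model.slope == 0:
        raise ZeroDivisionError("cannot invert a zero-slope model")
    return (y - model.intercept) / model.slope


def fit_linear(
    x: Sequence[float], y: Sequence[float], predictor_name: str, population: str = "custom"
) -> LinearModel:
    """Ordinary least squares fit for synthetic cohorts (never overwrites
    the shipped constants)."""
    res = stats.linregress(np.asarray(x, float), np.asarray(y, float))
    return LinearModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        predictor_name=predictor_name,
        population=population,
        r=float(res.rvalue),
    )


def strength_label(r: float) -> str:
    a = abs(r)
    if a > 0.7:
        return "strong"
    if a > 0.4:
        return "moderate"
    if a > 0.2:
        return "weak"
    return "absent"


_COVARIATES = ("height_m", "weight_kg", "bsa_m2", "age", "total_volume_ml")


def cohort_correlations(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Spearman rank correlation of tissue volume against each covariate.

    Pairs with fewer than 3 complete records are skipped (logged).  Returns
    a DataFrame indexed by covariate with columns r, p, n, label.
    """
    rows = {}
    for cov in _COVARIATES:
        pairs = [
            (getattr(s, cov), s.tissue_volume_ml)
            for s in cohort
            if getattr(s, cov) is not None and s.tissue_volume_ml is not None
        ]
        if len(pairs) < 3:
            logger.info("covariate %s skipped: only %d complete records", cov, len(pairs))
            continue
        x, y = zip(*pairs)
        r, p = stats.spearmanr(x, y)
        rows[cov] = {"r": float(r), "p": float(p), "n": len(pairs), "label": strength_label(r)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "covariate"
    return df


def constants_manifest() -> dict[str, dict[str, float | str]]:
    """All shipped models as a plain JSON-serialisable mapping."""
    return {
        f"{m.predictor_name}:{m.population}": {
            "slope": m.slope,
            "intercept": m.intercept,
            "predictor": m.predictor_name,
            "population": m.population,
            "r": m.r,
        }
        for m in SHIPPED_MODELS.values()
    }
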