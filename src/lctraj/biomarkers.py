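"""Deterministic clinical index calculators.

HOMA insulin indices, insulin unit conversion, Friedewald LDL cholesterol,
and a pluggable external risk-score interface.  All calculators are pure
functions: scalars in, scalars out (NaN encodes "undefined"), no hidden
state.  Vectorised use goes through :func:`numpy.vectorize`-free broadcasting
where noted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

#: pmol/l per µU/ml for human insulin (WHO standard conversion).
INSULIN_PMOL_PER_UU = 6.945

#: Friedewald validity bound for triglycerides, mmol/l (≈400 mg/dl).
FRIEDEWALD_TG_MAX = 4.52


def convert_insulin(value: float) -> float:
    """Convert insulin concentration from pmol/l to µU/ml.

    Parameters
    ----------
    value : float
        Insulin concentration in pmol/l.  Must be non-negative.

    Returns
    -------
    float
        Concentration in µU/ml (``value / 6.945``).
    """
    arr = np.asarray(value, dtype=float)
    if np.any(arr < 0):
        raise ValueError("insulin concentration must be non-negative")
    out = arr / INSULIN_PMOL_PER_UU
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def homa_indices(fpg: float, fasting_insulin: float) -> tuple[float, float]:
    """Homeostasis-model indices of insulin resistance and beta-cell function.

    Parameters
    ----------
    fpg : float
        Fasting plasma glucose, mmol/l; must be > 0.
    fasting_insulin : float
        Fasting insulin, µU/ml; must be >= 0.

    Returns
    -------
    (homa_ir, homa_b) : tuple of float
        ``homa_ir = I * G / 22.5`` (unitless) and
        ``homa_b = 20 * I / (G - 3.5)`` (percent).  ``homa_b`` is NaN for
        glucose at or below 3.5 mmol/l, where the index is undefined.
    """
    if fpg <= 0:
        raise ValueError("fasting plasma glucose must be positive")
    if fasting_insulin < 0:
        raise ValueError("fasting insulin must be non-negative")
    homa_ir = fasting_insulin * fpg / 22.5
    homa_b = 20.0 * fasting_insulin / (fpg - 3.5) if fpg > 3.5 else math.nan
    return homa_ir, homa_b


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """Friedewald estimate of LDL cholesterol, mmol/l dialect.

    ``ldl = tc - hdl - tg / 2.2``; NaN when triglycerides exceed the
    4.52 mmol/l validity bound.  A negative result (total cholesterol below
    HDL) signals inconsistent inputs and is returned as-is.
    """
    if tc < 0 or hdl < 0 or tg < 0:
        raise ValueError("lipid concentrations must be non-negative")
    if tg > FRIEDEWALD_TG_MAX:
        return math.nan
    return tc - hdl - tg / 2.2


@dataclass
class LinearScorer:
    """Pluggable external risk scorer: linear predictor + link.

    The coefficient tables of published risk scores (e.g. the Framingham
    diabetes and CVD scores) live in their source papers; this class applies
    any such table supplied by the user as ``{field: coefficient}`` with an
    intercept and a link function, returning a probability in [0, 1].
    """

    coefficients: Mapping[str, float]
    intercept: float = 0.0
    link: str = "logit"  # "logit" or "identity"
    required_fields: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.link not in ("logit", "identity"):
            raise ValueError(f"unknown link: {self.link!r}")
        if not self.required_fields:
            self.required_fields = tuple(self.coefficients)

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearScorer":
        spec = json.loads(Path(path).read_text())
        return cls(
            coefficients=spec["coefficients"],
            intercept=spec.get("intercept", 0.0),
            link=spec.get("link", "logit"),
            required_fields=tuple(spec.get("required_fields", ())),
        )

    def __call__(self, panel: Mapping[str, float]) -> float:
        for name in self.required_fields:
            v = panel.get(name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return math.nan
        eta = self.intercept + sum(
            c * float(panel[name]) for name, c in self.coefficients.items()
        )
        if self.link == "identity":
            return min(1.0, max(0.0, eta))
        return 1.0 / (1.0 + math.exp(-eta))


def external_risk_score(panel: Mapping[str, float], scorer) -> float:
    """Apply a pluggable risk scorer to a biomarker panel.

    ``scorer`` is any callable mapping a panel to a probability; missing
    required fields yield NaN, never a silent imputation.
    """
    return scorer(panel)
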