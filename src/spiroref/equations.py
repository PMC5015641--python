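"""Reference-value models for spirometry indices.

Two model families are supported:

* **LMS models** (GLI-style): at each (sex, age, height) the reference
  distribution of an index is summarised by a skewness power ``L``, a
  predicted median ``M`` and a coefficient of variation ``S``.  The median
  follows ``M = exp(m0 + m1*ln(height) + m2*ln(age) + Mspline(age))`` and
  ``S = exp(s0 + s1*ln(age) + Sspline(age))``; ``L``, ``Mspline`` and
  ``Sspline`` come from an age lookup table interpolated linearly in age.
* **Linear models with a constant residual SD** (classical regression
  equations): the predicted value is a polynomial in height and age
  (optionally on the log scale) and the spread is a single residual SD in
  outcome units.  These sets may additionally carry fixed
  percent-of-predicted cutoffs that operationally define their 2.5th
  percentile (e.g. FVC < 80 % predicted).

All indices use litres for volumes; the FEV1/FVC ratio is stored as a
fraction in (0, 1] and only rendered as a percentage in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Union

import numpy as np
from scipy.stats import norm

__all__ = [
    "INDICES",
    "SEXES",
    "Subject",
    "SpirometryMeasurement",
    "LMSPoint",
    "LinearPoint",
    "LMSCoefficients",
    "LinearCoefficients",
    "LMSEquationSet",
    "LinearEquationSet",
    "EquationSet",
    "PredictionResult",
    "z_score",
    "inverse_z",
    "lln",
    "z_from_percentile",
    "percentile_from_z",
    "is_extrapolated",
    "zscore_difference",
    "ZSCORE_DIFFERENCE_THRESHOLD",
]

INDICES = ("fev1", "fvc", "ratio")
SEXES = ("male", "female")

#: significant between-model z-score difference, in SD units
ZSCORE_DIFFERENCE_THRESHOLD = 0.3

ArrayLike = Union[float, np.ndarray]


class EquationSetError(ValueError):
    """Invalid equation-set definition or evaluation request."""


# ---------------------------------------------------------------------------
# subject-level records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Subject:
    """Demographics of one study participant."""

    id: str
    sex: str
    age: float
    height: float  # cm
    centre: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.age > 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if not self.height > 0:
            raise ValueError(f"height must be > 0, got {self.height}")


@dataclass(frozen=True)
class SpirometryMeasurement:
    """Measured FEV1 and FVC in litres; the ratio is derived.

    ``valid`` is False when FEV1 exceeds FVC — a physically impossible
    record that is flagged rather than silently accepted.
    """

    fev1: float
    fvc: float

    def __post_init__(self) -> None:
        if not self.fev1 > 0:
            raise ValueError(f"fev1 must be > 0, got {self.fev1}")
        if not self.fvc > 0:
            raise ValueError(f"fvc must be > 0, got {self.fvc}")

    @property
    def ratio(self) -> float:
        return self.fev1 / self.fvc

    @property
    def valid(self) -> bool:
        return self.fev1 <= self.fvc

    def value(self, index: str) -> float:
        if index == "fev1":
            return self.fev1
        if index == "fvc":
            return self.fvc
        if index == "ratio":
            return self.ratio
        raise KeyError(index)


# ---------------------------------------------------------------------------
# distribution points
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LMSPoint:
    """L, M, S of the reference distribution at one (sex, age, height)."""

    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if not self.M > 0:
            raise ValueError(f"M must be > 0, got {self.M}")
        if not self.S > 0:
            raise ValueError(f"S must be > 0, got {self.S}")


@dataclass(frozen=True)
class LinearPoint:
    """Predicted value and constant residual SD of a linear-SD model."""

    predicted: float
    residual_sd: float

    def __post_init__(self) -> None:
        if not self.predicted > 0:
            raise ValueError(f"predicted must be > 0, got {self.predicted}")
        if not self.residual_sd > 0:
            raise ValueError(f"residual_sd must be > 0, got {self.residual_sd}")


# ---------------------------------------------------------------------------
# scalar transforms
# ---------------------------------------------------------------------------


def z_from_percentile(p: ArrayLike) -> ArrayLike:
    """Standard-normal quantile of percentile ``p`` (0 < p < 100)."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 100):
        raise ValueError("percentile must lie strictly between 0 and 100")
    out = norm.ppf(p / 100.0)
    return float(out) if out.ndim == 0 else out


def percentile_from_z(z: ArrayLike) -> ArrayLike:
    """Standard-normal CDF of ``z``, expressed as a percentile in (0, 100)."""
    out = 100.0 * norm.cdf(np.asarray(z, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def z_score(y: ArrayLike, point: LMSPoint | LinearPoint) -> ArrayLike:
    """z-score of a measured value under an LMS or linear-SD point.

    LMS transform: ``z = ((y/M)**L - 1) / (L*S)`` for ``L != 0`` and
    ``z = ln(y/M) / S`` for ``L == 0``; linear: ``z = (y - predicted)/SD``.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(point, LinearPoint):
        out = (y - point.predicted) / point.residual_sd
    else:
        if np.any(y <= 0):
            raise ValueError("measured value must be > 0 under an LMS model")
        if point.L == 0.0:
            out = np.log(y / point.M) / point.S
        else:
            # expm1 form of ((y/M)**L - 1)/(L*S), stable for small |L|
            out = np.expm1(point.L * np.log(y / point.M)) / (point.L * point.S)
    return float(out) if np.ndim(out) == 0 else out


def inverse_z(z: ArrayLike, point: LMSPoint | LinearPoint) -> ArrayLike:
    """Measured value whose z-score equals ``z`` (inverse of :func:`z_score`)."""
    z = np.asarray(z, dtype=float)
    if isinstance(point, LinearPoint):
        out = point.predicted + z * point.residual_sd
    elif point.L == 0.0:
        out = point.M * np.exp(point.S * z)
    else:
        base = 1.0 + point.L * point.S * z
        if np.any(base <= 0):
            raise ValueError("z too extreme for the LMS parameters (non-positive base)")
        # log1p form of M * base**(1/L), stable for small |L|
        out = point.M * np.exp(np.log1p(point.L * point.S * z) / point.L)
    return float(out) if np.ndim(out) == 0 else out


def lln(point: LMSPoint | LinearPoint, percentile: float) -> float:
    """Lower limit of normal: the value at the requested centile of the point."""
    z = z_from_percentile(percentile)
    return inverse_z(z, point)


# ---------------------------------------------------------------------------
# equation sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LMSCoefficients:
    """Fixed coefficients and spline table for one (sex, index)."""

    m_intercept: float
    m_lnheight: float
    m_lnage: float
    s_intercept: float
    s_lnage: float
    spline_age: np.ndarray
    spline_l: np.ndarray
    spline_m: np.ndarray
    spline_s: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.spline_age, dtype=float)
        if ages.size < 2:
            raise EquationSetError("spline table needs at least two rows")
        if not np.all(np.diff(ages) > 0):
            raise EquationSetError("spline ages must be strictly increasing")
        for name in ("spline_l", "spline_m", "spline_s"):
            if np.asarray(getattr(self, name)).shape != ages.shape:
                raise EquationSetError(f"{name} length differs from spline_age")


@dataclass(frozen=True)
class LinearCoefficients:
    """Named polynomial terms and residual SD for one (sex, index).

    Supported term names: intercept, height, age, height2, age2,
    height_age, lnheight, lnage.  With ``log_outcome`` the polynomial
    predicts ``ln(y)`` and the prediction is exponentiated.
    """

    terms: Mapping[str, float]
    residual_sd: float
    log_outcome: bool = False

    _TERMS = ("intercept", "height", "age", "height2", "age2", "height_age",
              "lnheight", "lnage")

    def __post_init__(self) -> None:
        if not self.residual_sd > 0:
            raise EquationSetError(f"residual_sd must be > 0, got {self.residual_sd}")
        for name in self.terms:
            if name not in self._TERMS:
                raise EquationSetError(f"unknown linear term {name!r}")

    def predict(self, age: ArrayLike, height: ArrayLike) -> ArrayLike:
        age = np.asarray(age, dtype=float)
        height = np.asarray(height, dtype=float)
        t = self.terms
        out = (t.get("intercept", 0.0)
               + t.get("height", 0.0) * height
               + t.get("age", 0.0) * age
               + t.get("height2", 0.0) * height ** 2
               + t.get("age2", 0.0) * age ** 2
               + t.get("height_age", 0.0) * height * age)
        if "lnheight" in t:
            out = out + t["lnheight"] * np.log(height)
        if "lnage" in t:
            out = out + t["lnage"] * np.log(age)
        if self.log_outcome:
            out = np.exp(out)
        return float(out) if np.ndim(out) == 0 else out


def _check_key(sex: str, index: str) -> None:
    if sex not in SEXES:
        raise EquationSetError(f"sex must be one of {SEXES}, got {sex!r}")
    if index not in INDICES:
        raise EquationSetError(f"index must be one of {INDICES}, got {index!r}")


@dataclass(frozen=True)
class LMSEquationSet:
    """A named LMS reference model with per-(sex, index) coefficient blocks."""

    name: str
    coefficients: Mapping[tuple[str, str], LMSCoefficients]
    valid_age_range: tuple[float, float]

    model_type = "lms"

    def __post_init__(self) -> None:
        lo, hi = self.valid_age_range
        if not lo < hi:
            raise EquationSetError(f"invalid valid_age_range {self.valid_age_range}")

    @property
    def indices(self) -> tuple[str, ...]:
        return tuple(sorted({idx for (_, idx) in self.coefficients}))

    def _coef(self, sex: str, index: str) -> LMSCoefficients:
        _check_key(sex, index)
        try:
            return self.coefficients[(sex, index)]
        except KeyError:
            raise EquationSetError(
                f"equation set {self.name!r} has no block for ({sex}, {index})"
            ) from None

    def lms_arrays(self, sex: str, age: ArrayLike, height: ArrayLike,
                   index: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised (L, M, S) at the given ages/heights.

        Ages outside the spline span use the nearest tabulated row
        (constant extrapolation); callers flag such evaluations via
        :func:`is_extrapolated` rather than refusing them.
        """
        c = self._coef(sex, index)
        age = np.asarray(age, dtype=float)
        height = np.asarray(height, dtype=float)
        msp = np.interp(age, c.spline_age, c.spline_m)
        ssp = np.interp(age, c.spline_age, c.spline_s)
        L = np.interp(age, c.spline_age, c.spline_l)
        M = np.exp(c.m_intercept + c.m_lnheight * np.log(height)
                   + c.m_lnage * np.log(age) + msp)
        S = np.exp(c.s_intercept + c.s_lnage * np.log(age) + ssp)
        return L, M, S

    def lms_at(self, sex: str, age: float, height: float, index: str,
               strict: bool = False) -> LMSPoint:
        if strict and is_extrapolated(self, age):
            lo, hi = self.valid_age_range
            raise EquationSetError(
                f"age {age} outside valid range [{lo}, {hi}] in strict mode")
        L, M, S = self.lms_arrays(sex, age, height, index)
        return LMSPoint(float(L), float(M), float(S))

    point_at = lms_at

    def predicted(self, sex: str, age: ArrayLike, height: ArrayLike,
                  index: str) -> ArrayLike:
        _, M, _ = self.lms_arrays(sex, age, height, index)
        return float(M) if np.ndim(M) == 0 else M

    def z(self, sex: str, age: ArrayLike, height: ArrayLike, index: str,
          y: ArrayLike) -> ArrayLike:
        L, M, S = self.lms_arrays(sex, age, height, index)
        y = np.asarray(y, dtype=float)
        if np.any(y <= 0):
            raise ValueError("measured value must be > 0 under an LMS model")
        with np.errstate(divide="ignore", invalid="ignore"):
            z_general = np.expm1(L * np.log(y / M)) / (L * S)
            z_log = np.log(y / M) / S
        out = np.where(L == 0.0, z_log, z_general)
        return float(out) if np.ndim(out) == 0 else out

    def value_at_z(self, sex: str, age: ArrayLike, height: ArrayLike,
                   index: str, z: ArrayLike) -> ArrayLike:
        """Inverse of :meth:`z` — the measured value at a given z-score."""
        L, M, S = self.lms_arrays(sex, age, height, index)
        z = np.asarray(z, dtype=float)
        base = 1.0 + L * S * z
        if np.any(base <= 0):
            raise ValueError("z too extreme for the LMS parameters")
        with np.errstate(divide="ignore"):
            y_general = M * np.exp(np.log1p(L * S * z)
                                   / np.where(L == 0.0, 1.0, L))
            y_log = M * np.exp(S * z)
        out = np.where(L == 0.0, y_log, y_general)
        return float(out) if np.ndim(out) == 0 else out

    def lln_values(self, sex: str, age: ArrayLike, height: ArrayLike,
                   index: str, percentile: float,
                   z_limit: float | None = None) -> ArrayLike:
        """LLN in index units.  ``z_limit`` overrides the exact quantile
        (used for the rounded-convention policies)."""
        z = z_from_percentile(percentile) if z_limit is None else z_limit
        return self.value_at_z(sex, age, height, index, z)


@dataclass(frozen=True)
class LinearEquationSet:
    """A named linear-prediction model with a constant residual SD.

    ``pct_pred_lln_cutoffs`` — when present — are fixed percent-of-predicted
    limits that stand in for the model's 2.5th percentile (the operational
    definition used with classical Finnish equations: FEV1/FVC < 88 %,
    FVC < 80 %, FEV1 < 80 % predicted).
    """

    name: str
    coefficients: Mapping[tuple[str, str], LinearCoefficients]
    valid_age_range: tuple[float, float]
    pct_pred_lln_cutoffs: Mapping[str, float] | None = None

    model_type = "linear_sd"

    def __post_init__(self) -> None:
        lo, hi = self.valid_age_range
        if not lo < hi:
            raise EquationSetError(f"invalid valid_age_range {self.valid_age_range}")
        if self.pct_pred_lln_cutoffs is not None:
            for idx, cut in self.pct_pred_lln_cutoffs.items():
                if idx not in INDICES:
                    raise EquationSetError(f"cutoff for unknown index {idx!r}")
                if not 0 < cut < 150:
                    raise EquationSetError(
                        f"pct_pred cutoff for {idx} must be in (0, 150), got {cut}")

    @property
    def indices(self) -> tuple[str, ...]:
        return tuple(sorted({idx for (_, idx) in self.coefficients}))

    def _coef(self, sex: str, index: str) -> LinearCoefficients:
        _check_key(sex, index)
        try:
            return self.coefficients[(sex, index)]
        except KeyError:
            raise EquationSetError(
                f"equation set {self.name!r} has no block for ({sex}, {index})"
            ) from None

    def point_at(self, sex: str, age: float, height: float, index: str,
                 strict: bool = False) -> LinearPoint:
        if strict and is_extrapolated(self, age):
            lo, hi = self.valid_age_range
            raise EquationSetError(
                f"age {age} outside valid range [{lo}, {hi}] in strict mode")
        c = self._coef(sex, index)
        return LinearPoint(float(c.predict(age, height)), c.residual_sd)

    def predicted(self, sex: str, age: ArrayLike, height: ArrayLike,
                  index: str) -> ArrayLike:
        out = self._coef(sex, index).predict(age, height)
        return float(out) if np.ndim(out) == 0 else out

    def z(self, sex: str, age: ArrayLike, height: ArrayLike, index: str,
          y: ArrayLike) -> ArrayLike:
        c = self._coef(sex, index)
        out = (np.asarray(y, dtype=float) - c.predict(age, height)) / c.residual_sd
        return float(out) if np.ndim(out) == 0 else out

    def value_at_z(self, sex: str, age: ArrayLike, height: ArrayLike,
                   index: str, z: ArrayLike) -> ArrayLike:
        c = self._coef(sex, index)
        out = c.predict(age, height) + np.asarray(z, dtype=float) * c.residual_sd
        return float(out) if np.ndim(out) == 0 else out

    def lln_values(self, sex: str, age: ArrayLike, height: ArrayLike,
                   index: str, percentile: float,
                   z_limit: float | None = None) -> ArrayLike:
        """LLN in index units.

        When the set declares percent-of-predicted cutoffs and the 2.5th
        percentile is requested, the LLN is ``cutoff/100 × predicted`` —
        the operational definition those models are used with.  Otherwise
        it falls back to ``predicted + z·SD``.
        """
        if (self.pct_pred_lln_cutoffs is not None
                and index in self.pct_pred_lln_cutoffs
                and percentile == 2.5):
            pred = self.predicted(sex, age, height, index)
            out = self.pct_pred_lln_cutoffs[index] / 100.0 * np.asarray(pred)
            return float(out) if np.ndim(out) == 0 else out
        z = z_from_percentile(percentile) if z_limit is None else z_limit
        return self.value_at_z(sex, age, height, index, z)


EquationSet = Union[LMSEquationSet, LinearEquationSet]


# ---------------------------------------------------------------------------
# per-index prediction and model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PredictionResult:
    """Everything one equation set says about one measured index value."""

    index: str
    predicted: float
    z: float
    percent_predicted: float
    percentile: float
    lln: float
    extrapolated: bool


def is_extrapolated(eqset: EquationSet, age: ArrayLike) -> ArrayLike:
    """True iff ``age`` falls outside the set's valid age range (bounds
    inclusive: an evaluation exactly at a bound is not extrapolated)."""
    lo, hi = eqset.valid_age_range
    age = np.asarray(age, dtype=float)
    out = (age < lo) | (age > hi)
    return bool(out) if out.ndim == 0 else out


def predict_index(eqset: EquationSet, subject: Subject,
                  measurement: SpirometryMeasurement, index: str,
                  lln_percentile: float = 2.5,
                  z_limit: float | None = None) -> PredictionResult:
    """Full per-index evaluation of one subject under one equation set."""
    y = measurement.value(index)
    pred = eqset.predicted(subject.sex, subject.age, subject.height, index)
    z = eqset.z(subject.sex, subject.age, subject.height, index, y)
    limit = eqset.lln_values(subject.sex, subject.age, subject.height, index,
                             lln_percentile, z_limit)
    return PredictionResult(
        index=index,
        predicted=float(pred),
        z=float(z),
        percent_predicted=100.0 * y / float(pred),
        percentile=float(percentile_from_z(z)),
        lln=float(limit),
        extrapolated=bool(is_extrapolated(eqset, subject.age)),
    )


def zscore_difference(subject: Subject, measurement: SpirometryMeasurement,
                      eqset_a: EquationSet, eqset_b: EquationSet, index: str,
                      threshold: float = ZSCORE_DIFFERENCE_THRESHOLD
                      ) -> tuple[float, bool]:
    """z under set A minus z under set B, flagged when |Δz| > threshold.

    The default threshold of ±0.3 SD is the conventional limit for a
    clinically significant between-model difference.
    """
    for eqset in (eqset_a, eqset_b):
        if (subject.sex, index) not in eqset.coefficients:
            raise EquationSetError(
                f"index {index!r} not covered by equation set {eqset.name!r}")
    y = measurement.value(index)
    za = eqset_a.z(subject.sex, subject.age, subject.height, index, y)
    zb = eqset_b.z(subject.sex, subject.age, subject.height, index, y)
    delta = float(za) - float(zb)
    return delta, abs(delta) > threshold
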