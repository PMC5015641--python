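"""Pattern classification and severity grading at a configurable LLN.

Spirometric patterns (each a separate binary flag against the lower
limit of normal of its index):

* **airway obstruction** — FEV1/FVC below its LLN;
* **possible restrictive pattern** — FVC below its LLN;
* **decreased ventilatory capacity** — FEV1 below its LLN;
* **isolated reduced FEV1** — FEV1 reduced while ratio and FVC are not.

Two LLN percentiles are in common use: the 2.5th (screening and case
finding in random populations) and the 5th (clinical evaluation of
symptomatic individuals).  In ``convention`` mode the corresponding
z-limits are the rounded values −2 and −1.645; ``exact`` mode uses the
full-precision normal quantiles.

Severity of reduced FEV1 is graded on two scales: a z-score scheme used
with LMS-family reference sets, and a percent-of-predicted scheme used
with the classical Finnish linear equations (published variant: ≥ 80 %
is *normal*; harmonised variant relabels that band *mild* so the scale
aligns category-for-category with the z-score scheme).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from .equations import PredictionResult, z_from_percentile

__all__ = [
    "LLNPolicy",
    "PatternCall",
    "SeverityGrade",
    "SEVERITY_ORDER",
    "classify_pattern",
    "grade_severity_z",
    "grade_severity_viljanen",
]

#: rounded z-limits by percentile, as conventionally used in reporting
_CONVENTION_Z = {2.5: -2.0, 5.0: -1.645}


@dataclass(frozen=True)
class LLNPolicy:
    """Lower-limit-of-normal policy: which percentile, and whether the
    z-limit is the exact normal quantile or the rounded convention."""

    percentile: float = 2.5
    z_limit_mode: str = "convention"

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError(f"percentile must be in (0, 100), got {self.percentile}")
        if self.z_limit_mode not in ("exact", "convention"):
            raise ValueError(f"z_limit_mode must be 'exact' or 'convention', "
                             f"got {self.z_limit_mode!r}")

    @property
    def standard(self) -> bool:
        """True for the two percentiles in standard use (2.5 and 5)."""
        return float(self.percentile) in (2.5, 5.0)

    @property
    def z_limit(self) -> float:
        """Effective z-limit: −2 / −1.645 under the convention, else exact."""
        if self.z_limit_mode == "convention":
            try:
                return _CONVENTION_Z[float(self.percentile)]
            except KeyError:
                warnings.warn(
                    f"no rounded convention for the {self.percentile}th "
                    f"percentile; using the exact quantile", stacklevel=2)
        return float(z_from_percentile(self.percentile))


class SeverityGrade(str, enum.Enum):
    NORMAL = "normal"
    MILD = "mild"
    MODERATE = "moderate"
    MODERATELY_SEVERE = "moderately_severe"
    SEVERE = "severe"
    VERY_SEVERE = "very_severe"

    def __str__(self) -> str:  # plain value in tables and CSVs
        return self.value


SEVERITY_ORDER = tuple(SeverityGrade)


@dataclass(frozen=True)
class PatternCall:
    """Binary pattern flags for one subject under one equation set."""

    obstruction: bool
    possible_restriction: bool
    decreased_vc: bool

    @property
    def isolated_reduced_fev1(self) -> bool:
        return (self.decreased_vc and not self.obstruction
                and not self.possible_restriction)


def classify_pattern(fev1: PredictionResult, fvc: PredictionResult,
                     ratio: PredictionResult,
                     policy: LLNPolicy | None = None) -> PatternCall:
    """Pattern flags from the per-index evaluations of one subject.

    Abnormality is strict: a value exactly at its LLN is normal.  The
    three results must come from the same equation set evaluated under
    ``policy`` (the LLNs embedded in them already reflect it).
    """
    if (fev1.index, fvc.index, ratio.index) != ("fev1", "fvc", "ratio"):
        raise ValueError("expected PredictionResults for (fev1, fvc, ratio), got "
                         f"({fev1.index}, {fvc.index}, {ratio.index})")
    measured = {r.index: r.predicted * r.percent_predicted / 100.0
                for r in (fev1, fvc, ratio)}
    return PatternCall(
        obstruction=measured["ratio"] < ratio.lln,
        possible_restriction=measured["fvc"] < fvc.lln,
        decreased_vc=measured["fev1"] < fev1.lln,
    )


def grade_severity_z(z_fev1: float, policy: LLNPolicy) -> SeverityGrade:
    """Severity of reduced FEV1 on the z-score scale.

    Normal means z at or above the policy's LLN z-limit.  Below it, the
    bands are mild down to −2, moderate to −2.5, moderately severe to
    −3, severe to −4 and very severe beyond; each boundary belongs to
    the more severe band (z = −2.5 grades moderately severe).  With the
    2.5th-percentile convention limit of −2 the mild band is empty.
    """
    z = float(z_fev1)
    if z >= policy.z_limit:
        return SeverityGrade.NORMAL
    if z > -2.0:
        return SeverityGrade.MILD
    if z > -2.5:
        return SeverityGrade.MODERATE
    if z > -3.0:
        return SeverityGrade.MODERATELY_SEVERE
    if z > -4.0:
        return SeverityGrade.SEVERE
    return SeverityGrade.VERY_SEVERE


def grade_severity_viljanen(percent_predicted_fev1: float,
                            variant: str = "published") -> SeverityGrade:
    """Severity of reduced FEV1 on the percent-of-predicted scale.

    Bands: ≥ 80 normal (``published``) or mild (``harmonized``);
    [65, 80) moderate; [45, 65) moderately severe; [25, 45) severe;
    below 25 very severe.
    """
    if variant not in ("published", "harmonized"):
        raise ValueError(f"variant must be 'published' or 'harmonized', "
                         f"got {variant!r}")
    p = float(percent_predicted_fev1)
    if not p > 0:
        raise ValueError(f"percent predicted must be > 0, got {p}")
    if p >= 80.0:
        return (SeverityGrade.NORMAL if variant == "published"
                else SeverityGrade.MILD)
    if p >= 65.0:
        return SeverityGrade.MODERATE
    if p >= 45.0:
        return SeverityGrade.MODERATELY_SEVERE
    if p >= 25.0:
        return SeverityGrade.SEVERE
    return SeverityGrade.VERY_SEVERE
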