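"""Cohort-level statistics: stratified prevalence, percent-predicted
summaries, severity distributions and between-model agreement.

These operate on interpretation frames produced by
:func:`spiroref.interpret.interpret_cohort`.  Percentages in rendered
tables are reported to one decimal place; the returned frames keep full
precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classification import SeverityGrade
from .equations import INDICES, ZSCORE_DIFFERENCE_THRESHOLD

__all__ = [
    "StratumSpec",
    "AgreementResult",
    "DegenerateAgreementError",
    "PATTERNS",
    "prevalence",
    "cohen_kappa",
    "chi_square",
    "paired_t",
    "summarize_percent_predicted",
    "severity_distribution",
    "crosstab_grades",
    "crosstab_flags",
    "zscore_difference_summary",
]

PATTERNS = ("obstruction", "possible_restriction", "decreased_vc",
            "isolated_reduced_fev1")

#: default age bins for prevalence-by-age reports
DEFAULT_AGE_BINS = ((21, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 74))


@dataclass(frozen=True)
class StratumSpec:
    """Sex filter plus ordered, non-overlapping age bins (inclusive bounds).

    ``include_all`` adds an unstratified "all ages" row; the special
    21–65-year stratum used alongside classical reference sets is just
    the bin (21, 65).
    """

    sex: str = "all"
    age_bins: Sequence[tuple[float, float]] = ()
    include_all: bool = True

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "all"):
            raise ValueError(f"sex filter must be male/female/all, got {self.sex!r}")
        prev_hi = -np.inf
        for lo, hi in self.age_bins:
            if lo > hi:
                raise ValueError(f"age bin [{lo}, {hi}] has low > high")
            if lo <= prev_hi:
                raise ValueError("age bins must be non-overlapping and increasing")
            prev_hi = hi

    def rows(self) -> list[tuple[str, float, float]]:
        out = []
        if self.include_all:
            out.append(("all", -np.inf, np.inf))
        for lo, hi in self.age_bins:
            out.append((f"{lo:g}-{hi:g}", float(lo), float(hi)))
        return out


class DegenerateAgreementError(ValueError):
    """Kappa undefined: both raters constant and identical (p_e = 1)."""


@dataclass(frozen=True)
class AgreementResult:
    """Cohen's kappa with its observed and chance agreement."""

    kappa: float
    p_o: float
    p_e: float
    n: int


# ---------------------------------------------------------------------------
# prevalence
# ---------------------------------------------------------------------------


def prevalence(interp: pd.DataFrame, pattern: str,
               strata: StratumSpec | None = None) -> pd.DataFrame:
    """Stratified prevalence of one pattern flag.

    Returns one row per (sex stratum, age stratum) with columns
    ``count``, ``n``, ``prevalence`` (percent, NaN when n = 0) and
    ``n_extrapolated`` (subjects counted while outside the equation
    set's valid age range).  Subjects are counted in every stratum they
    fall into; an empty stratum yields n = 0 with prevalence marked NaN
    rather than 0.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}, got {pattern!r}")
    if strata is None:
        strata = StratumSpec(age_bins=((21, 65),))
    sexes = (["male", "female", "all"] if strata.sex == "all" else [strata.sex])
    rows = []
    for sex in sexes:
        sub = interp if sex == "all" else interp[interp["sex"] == sex]
        for label, lo, hi in strata.rows():
            cell = sub[(sub["age"] >= lo) & (sub["age"] <= hi)]
            n = len(cell)
            count = int(cell[pattern].sum())
            rows.append({
                "pattern": pattern,
                "sex": sex,
                "age_stratum": label,
                "count": count,
                "n": n,
                "prevalence": (100.0 * count / n) if n else np.nan,
                "n_extrapolated": int(cell["extrapolated"].sum()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# agreement and comparison statistics
# ---------------------------------------------------------------------------


def cohen_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    """Unweighted Cohen's kappa between two aligned categorical vectors.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement
    ``p_o = trace/n`` and chance agreement ``p_e = Σ row_i·col_i / n²``
    from the cross-tabulation.  Raises
    :class:`DegenerateAgreementError` when p_e = 1 (both raters constant
    and identical), where kappa is undefined.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("labels must be two aligned non-empty 1-d vectors")
    table = pd.crosstab(pd.Series(a), pd.Series(b), dropna=False)
    # square the table over the union of labels
    labels = sorted(set(table.index) | set(table.columns), key=str)
    table = table.reindex(index=labels, columns=labels, fill_value=0)
    mat = table.to_numpy(dtype=float)
    n = mat.sum()
    p_o = np.trace(mat) / n
    p_e = float(mat.sum(axis=1) @ mat.sum(axis=0)) / n ** 2
    if p_e >= 1.0 - 1e-15:
        raise DegenerateAgreementError(
            "kappa undefined: both classifications are the same constant")
    return AgreementResult(kappa=(p_o - p_e) / (1.0 - p_e),
                           p_o=float(p_o), p_e=float(p_e), n=int(n))


def chi_square(table) -> tuple[float, float, int]:
    """Pearson chi-square test of independence on a contingency table.

    Returns (statistic, p-value, degrees of freedom).  Requires every
    expected count to be positive; otherwise an error suggests merging
    categories.  No continuity correction is applied.
    """
    mat = np.asarray(table, dtype=float)
    if mat.ndim != 2 or min(mat.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    expected = stats.contingency.expected_freq(mat)
    if np.any(expected <= 0):
        raise ValueError("zero expected count in contingency table; "
                         "merge sparse categories before testing")
    res = stats.chi2_contingency(mat, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def paired_t(values_a: Sequence[float],
             values_b: Sequence[float]) -> tuple[float, float, int]:
    """Two-sided paired-samples t-test; returns (t, p, df).

    ``t = mean(d) / (sd(d)/sqrt(n))`` on the differences d = a − b with
    df = n − 1.  Raises on zero-variance differences, where the
    statistic is undefined.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two aligned vectors of length >= 2")
    d = a - b
    if np.ptp(d) == 0:
        raise ValueError("paired differences have zero variance; "
                         "t statistic undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), int(a.size - 1)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_percent_predicted(interps: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Measured, predicted and percent-predicted summaries per
    sex × index × equation set (the layout of a measured-vs-predicted
    summary table).

    ``interps`` maps an equation-set label to its interpretation frame.
    With a single subject the SD is undefined and reported NaN.  The
    ratio rows are rendered in percent.
    """
    rows = []
    for label, interp in interps.items():
        for sex in ("male", "female"):
            sub = interp[interp["sex"] == sex]
            for index in INDICES:
                scale = 100.0 if index == "ratio" else 1.0
                meas = sub[f"measured_{index}"] * scale
                pred = sub[f"pred_{index}"] * scale
                pct = sub[f"pctpred_{index}"]
                rows.append({
                    "eqset": label, "sex": sex, "index": index, "n": len(sub),
                    "measured_mean": meas.mean(),
                    "measured_sd": meas.std(ddof=1) if len(sub) > 1 else np.nan,
                    "measured_min": meas.min(),
                    "measured_max": meas.max(),
                    "predicted_mean": pred.mean(),
                    "pctpred_mean": pct.mean(),
                    "pctpred_sd": pct.std(ddof=1) if len(sub) > 1 else np.nan,
                })
    return pd.DataFrame(rows)


def severity_distribution(interp: pd.DataFrame,
                          by_sex: bool = True) -> pd.DataFrame:
    """Proportion of subjects in each severity grade (per sex).

    Proportions over the six grades sum to 1 within each group.
    """
    grades = [g.value for g in SeverityGrade]
    groups = (["male", "female"] if by_sex else ["all"])
    rows = []
    for sex in groups:
        sub = interp if sex == "all" else interp[interp["sex"] == sex]
        counts = sub["severity"].value_counts()
        n = len(sub)
        for g in grades:
            c = int(counts.get(g, 0))
            rows.append({"sex": sex, "grade": g, "count": c, "n": n,
                         "proportion": c / n if n else np.nan})
    return pd.DataFrame(rows)


def _aligned(interp_a: pd.DataFrame, interp_b: pd.DataFrame) -> None:
    if len(interp_a) != len(interp_b) or \
            not (interp_a["id"].to_numpy() == interp_b["id"].to_numpy()).all():
        raise ValueError("interpretation frames are not aligned on the same "
                         "cohort (ids differ); interpret the same subjects "
                         "in the same order under both sets")


def crosstab_grades(interp_a: pd.DataFrame,
                    interp_b: pd.DataFrame) -> pd.DataFrame:
    """Square severity-grade confusion matrix (rows = set A, cols = B)."""
    _aligned(interp_a, interp_b)
    grades = [g.value for g in SeverityGrade]
    table = pd.crosstab(interp_a["severity"], interp_b["severity"], dropna=False)
    return table.reindex(index=grades, columns=grades, fill_value=0)


def crosstab_flags(interp_a: pd.DataFrame, interp_b: pd.DataFrame,
                   pattern: str) -> pd.DataFrame:
    """2×2 confusion matrix for one binary pattern flag."""
    _aligned(interp_a, interp_b)
    labels = [False, True]
    table = pd.crosstab(interp_a[pattern], interp_b[pattern], dropna=False)
    return table.reindex(index=labels, columns=labels, fill_value=0)


def zscore_difference_summary(interp_a: pd.DataFrame, interp_b: pd.DataFrame,
                              threshold: float = ZSCORE_DIFFERENCE_THRESHOLD
                              ) -> pd.DataFrame:
    """Per-index summary of between-model z-score differences.

    Reports mean and SD of Δz = z_A − z_B and the fraction of subjects
    beyond the ±``threshold`` band (default ±0.3 SD, the conventional
    limit for a clinically significant difference).
    """
    _aligned(interp_a, interp_b)
    rows = []
    for index in INDICES:
        d = interp_a[f"z_{index}"].to_numpy() - interp_b[f"z_{index}"].to_numpy()
        rows.append({
            "index": index,
            "mean_delta_z": float(np.mean(d)),
            "sd_delta_z": float(np.std(d, ddof=1)) if d.size > 1 else np.nan,
            "threshold": threshold,
            "frac_flagged": float(np.mean(np.abs(d) > threshold)),
        })
    return pd.DataFrame(rows)
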