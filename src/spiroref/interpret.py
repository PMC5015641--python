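"""Cohort-level interpretation: evaluate every subject under an equation set.

The central product is a wide per-subject DataFrame ("interpretation
frame") with, for each index ``i`` in (fev1, fvc, ratio): ``pred_i``,
``z_i``, ``pctpred_i``, ``lln_i``; plus the pattern flags, the severity
grade, and an ``extrapolated`` flag.  All downstream cohort statistics
(prevalence tables, agreement, severity distributions) consume this
frame.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classification import (
    LLNPolicy,
    SeverityGrade,
    grade_severity_viljanen,
    grade_severity_z,
)
from .equations import INDICES, EquationSet, is_extrapolated

__all__ = ["interpret_cohort", "grading_scheme_for"]

log = logging.getLogger(__name__)


def grading_scheme_for(eqset: EquationSet) -> str:
    """Default severity scheme for a model family: z-scores for LMS sets,
    percent predicted for linear-SD (classical) sets."""
    return "zscore" if eqset.model_type == "lms" else "viljanen"


def interpret_cohort(cohort: pd.DataFrame, eqset: EquationSet,
                     policy: LLNPolicy | None = None,
                     scheme: str | None = None,
                     viljanen_variant: str = "published",
                     drop_invalid: bool = True) -> pd.DataFrame:
    """Interpret every subject of a cohort under one equation set.

    Parameters
    ----------
    cohort
        Frame with columns id, sex, age, height, fev1, fvc (as produced
        by :func:`spiroref.fileio.read_subjects_csv` or the synthetic
        generator).  An explicit ``ratio`` column overrides fev1/fvc.
    eqset
        The reference model to evaluate.
    policy
        LLN policy; defaults to the 2.5th percentile with the rounded
        z-limit convention.
    scheme
        Severity scheme: ``"zscore"`` or ``"viljanen"``; defaults to the
        family pairing from :func:`grading_scheme_for`.  A cross-pairing
        is allowed but logged as a warning.
    drop_invalid
        Exclude records with FEV1 > FVC (logged with a count); when
        False they are kept and marked ``valid = False``.
    """
    if policy is None:
        policy = LLNPolicy()
    if scheme is None:
        scheme = grading_scheme_for(eqset)
    elif scheme != grading_scheme_for(eqset):
        log.warning("severity scheme %r cross-paired with a %s equation set",
                    scheme, eqset.model_type)
    if scheme not in ("zscore", "viljanen"):
        raise ValueError(f"unknown severity scheme {scheme!r}")

    df = cohort.copy()
    valid = df["fev1"].to_numpy() <= df["fvc"].to_numpy() + 1e-12
    if drop_invalid and not valid.all():
        n_bad = int((~valid).sum())
        log.warning("excluding %d record(s) with FEV1 > FVC", n_bad)
        df = df.loc[valid].reset_index(drop=True)
        valid = np.ones(len(df), dtype=bool)

    sexes = df["sex"].to_numpy()
    age = df["age"].to_numpy(dtype=float)
    height = df["height"].to_numpy(dtype=float)
    measured = {
        "fev1": df["fev1"].to_numpy(dtype=float),
        "fvc": df["fvc"].to_numpy(dtype=float),
        "ratio": (df["ratio"].to_numpy(dtype=float) if "ratio" in df.columns
                  else df["fev1"].to_numpy(dtype=float)
                  / df["fvc"].to_numpy(dtype=float)),
    }

    out = pd.DataFrame({"id": df["id"].to_numpy(), "sex": sexes,
                        "age": age, "height": height})
    if "centre" in df.columns:
        out["centre"] = df["centre"].to_numpy()
    out["eqset"] = eqset.name

    # rounded-convention z-limit only applies at the policy's own percentile
    z_limit = policy.z_limit if policy.z_limit_mode == "convention" else None
    for index in INDICES:
        pred = np.empty(len(df))
        z = np.empty(len(df))
        limit = np.empty(len(df))
        for sex in ("male", "female"):
            m = sexes == sex
            if not m.any():
                continue
            pred[m] = eqset.predicted(sex, age[m], height[m], index)
            z[m] = eqset.z(sex, age[m], height[m], index, measured[index][m])
            limit[m] = eqset.lln_values(sex, age[m], height[m], index,
                                        policy.percentile, z_limit)
        out[f"measured_{index}"] = measured[index]
        out[f"pred_{index}"] = pred
        out[f"z_{index}"] = z
        out[f"pctpred_{index}"] = 100.0 * measured[index] / pred
        out[f"lln_{index}"] = limit

    out["obstruction"] = out["measured_ratio"] < out["lln_ratio"]
    out["possible_restriction"] = out["measured_fvc"] < out["lln_fvc"]
    out["decreased_vc"] = out["measured_fev1"] < out["lln_fev1"]
    out["isolated_reduced_fev1"] = (out["decreased_vc"]
                                    & ~out["obstruction"]
                                    & ~out["possible_restriction"])

    if scheme == "zscore":
        grades = [grade_severity_z(zv, policy) for zv in out["z_fev1"]]
    else:
        grades = [grade_severity_viljanen(p, viljanen_variant)
                  for p in out["pctpred_fev1"]]
    out["severity"] = pd.Categorical([g.value for g in grades],
                                     categories=[g.value for g in SeverityGrade])
    out["severity_scheme"] = scheme
    out["extrapolated"] = is_extrapolated(eqset, age)
    out["valid"] = valid
    n_ex = int(out["extrapolated"].sum())
    if n_ex:
        log.info("%d evaluation(s) outside the valid age range of %s "
                 "(computed and flagged)", n_ex, eqset.name)
    return out
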