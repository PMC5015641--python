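"""Synthetic cohorts and fixture reference models.

The generator emulates a two-centre Finnish general-population sample:
633 subjects in an urban stratum and 695 in a rural one (1,328 in all,
45.0 % male), ages drawn per sex from truncated normals on 21–74 years
(means 48.8/48.2, SDs 13.2/12.9 for males/females) and heights from
normals (176.5 ± 6.6 cm male, 163.0 ± 6.1 cm female).  Healthy lung
indices are drawn so their z-scores under a designated *truth* equation
set are standard normal; obstructive or restrictive subpopulations are
injected as z-shifts with retained truth labels.

Two generation modes exist because the three indices cannot all be
exactly standard normal at once when the ratio is derived from the
volumes:

* ``index_consistent`` — draw z(FVC) and z(ratio), derive
  FEV1 = ratio × FVC.  Physically consistent (FEV1 ≤ FVC always); the
  FEV1 z-distribution is then only approximately standard normal.
* ``marginal`` — draw each index independently from its own truth
  distribution.  Used for per-index calibration; the stored ``ratio``
  column then intentionally differs from fev1/fvc.

Fixture equation sets (both families) are physiologically plausible,
deterministic in the seed, and serialise byte-identically.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import truncnorm

from .equations import (
    INDICES,
    EquationSet,
    LinearCoefficients,
    LinearEquationSet,
    LMSCoefficients,
    LMSEquationSet,
)
from .fileio import write_equation_set

__all__ = [
    "DiseaseComponent",
    "Stratum",
    "CohortConfig",
    "generate_cohort",
    "inject_disease",
    "generate_fixture_equation_set",
    "scale_median",
]

log = logging.getLogger(__name__)

RATIO_BOUNDS = (0.3, 1.0)   # healthy-draw truncation for the ratio index
RATIO_FLOOR = 0.2           # hard physical floor after disease injection


class Stratum(BaseModel):
    centre: str
    n: int = Field(ge=0)


class DiseaseComponent(BaseModel):
    """A diseased subpopulation expressed as z-shifts under the truth set.

    ``obstructive`` shifts z(ratio); ``restrictive`` shifts z(FVC) (and
    z(FEV1) in marginal mode, where FEV1 is drawn independently).  The
    shift for each affected subject is drawn from
    N(z_shift_mean, z_shift_sd²), so a zero SD is a pure location shift
    and a positive SD additionally inflates the spread.
    """

    type: Literal["obstructive", "restrictive"]
    prevalence: float = Field(ge=0.0, le=1.0)
    z_shift_mean: float = -3.0
    z_shift_sd: float = Field(default=0.0, ge=0.0)


class CohortConfig(BaseModel):
    """Full parameterisation of the synthetic cohort generator.

    Defaults reproduce the two-centre study sample the package is
    calibrated to; all distributions are per sex.
    """

    strata: list[Stratum] = Field(
        default_factory=lambda: [Stratum(centre="Helsinki", n=633),
                                 Stratum(centre="Kemi", n=695)])
    male_fraction: float = Field(default=597 / 1328, ge=0.0, le=1.0)
    age_mean: dict[str, float] = Field(
        default_factory=lambda: {"male": 48.8, "female": 48.2})
    age_sd: dict[str, float] = Field(
        default_factory=lambda: {"male": 13.2, "female": 12.9})
    age_range: tuple[float, float] = (21.0, 74.0)
    height_mean: dict[str, float] = Field(
        default_factory=lambda: {"male": 176.5, "female": 163.0})
    height_sd: dict[str, float] = Field(
        default_factory=lambda: {"male": 6.6, "female": 6.1})
    mode: Literal["index_consistent", "marginal"] = "index_consistent"
    z_correlation: float = Field(default=0.0, ge=-1.0, le=1.0)
    disease_components: list[DiseaseComponent] = Field(default_factory=list)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        total = sum(c.prevalence for c in self.disease_components)
        if total > 1.0:
            raise ValueError(f"disease prevalences sum to {total} > 1")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError(f"invalid age_range {self.age_range}")
        return self

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.strata)


def _truncnorm_draw(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _values_at_z(truth: EquationSet, sexes: np.ndarray, age: np.ndarray,
                 height: np.ndarray, index: str, z: np.ndarray) -> np.ndarray:
    out = np.empty(len(age))
    for sex in ("male", "female"):
        m = sexes == sex
        if m.any():
            out[m] = truth.value_at_z(sex, age[m], height[m], index, z[m])
    return out


def _z_at_values(truth: EquationSet, sexes: np.ndarray, age: np.ndarray,
                 height: np.ndarray, index: str, y: np.ndarray) -> np.ndarray:
    out = np.empty(len(age))
    for sex in ("male", "female"):
        m = sexes == sex
        if m.any():
            out[m] = truth.z(sex, age[m], height[m], index, y[m])
    return out


def _recompute_values(cohort: pd.DataFrame, truth: EquationSet,
                      mode: str) -> None:
    """Refresh measured columns from the latent z columns, in place."""
    sexes = cohort["sex"].to_numpy()
    age = cohort["age"].to_numpy(dtype=float)
    height = cohort["height"].to_numpy(dtype=float)
    fvc = _values_at_z(truth, sexes, age, height, "fvc",
                       cohort["z_true_fvc"].to_numpy(dtype=float))
    ratio = _values_at_z(truth, sexes, age, height, "ratio",
                         cohort["z_true_ratio"].to_numpy(dtype=float))
    cohort["fvc"] = fvc
    cohort["ratio"] = ratio
    if mode == "index_consistent":
        cohort["fev1"] = ratio * fvc
        cohort["z_true_fev1"] = _z_at_values(truth, sexes, age, height,
                                             "fev1", cohort["fev1"].to_numpy())
    else:
        cohort["fev1"] = _values_at_z(truth, sexes, age, height, "fev1",
                                      cohort["z_true_fev1"].to_numpy(dtype=float))


def generate_cohort(config: CohortConfig, truth: EquationSet
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a cohort under ``config`` with lung indices calibrated to
    ``truth``.

    Returns ``(cohort, labels)``: the cohort frame (id, centre, sex,
    age, height, fev1, fvc, ratio, plus the latent ``z_true_*`` columns
    and a ``component`` column) and the truth-label sidecar for injected
    disease.  Reproducible bit-for-bit given (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    parts = []
    counter = 0
    for stratum in config.strata:
        n = stratum.n
        n_male = int(round(config.male_fraction * n))
        sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
        age = np.empty(n)
        height = np.empty(n)
        for sex in ("male", "female"):
            m = sexes == sex
            if not m.any():
                continue
            age[m] = _truncnorm_draw(rng, config.age_mean[sex],
                                     config.age_sd[sex], *config.age_range,
                                     size=int(m.sum()))
            height[m] = rng.normal(config.height_mean[sex],
                                   config.height_sd[sex], size=int(m.sum()))
        ids = [f"S{counter + i:06d}" for i in range(n)]
        counter += n
        parts.append(pd.DataFrame({
            "id": ids, "centre": stratum.centre, "sex": sexes,
            "age": age, "height": height,
        }))
    cohort = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["id", "centre", "sex", "age", "height"])

    n = len(cohort)
    if config.mode == "marginal":
        for index in INDICES:
            cohort[f"z_true_{index}"] = rng.standard_normal(n)
    else:
        rho = config.z_correlation
        z = rng.multivariate_normal([0.0, 0.0],
                                    [[1.0, rho], [rho, 1.0]], size=n) \
            if n else np.empty((0, 2))
        cohort["z_true_fvc"] = z[:, 0] if n else []
        cohort["z_true_ratio"] = z[:, 1] if n else []
        cohort["z_true_fev1"] = 0.0  # filled by _recompute_values

    if n:
        # truncate ratio draws into the physiological band by resampling z
        sexes = cohort["sex"].to_numpy()
        age = cohort["age"].to_numpy(dtype=float)
        height = cohort["height"].to_numpy(dtype=float)
        n_trunc = 0
        for _ in range(100):
            ratio = _values_at_z(truth, sexes, age, height, "ratio",
                                 cohort["z_true_ratio"].to_numpy())
            bad = (ratio <= RATIO_BOUNDS[0]) | (ratio > RATIO_BOUNDS[1])
            if not bad.any():
                break
            n_trunc += int(bad.sum())
            col = cohort.columns.get_loc("z_true_ratio")
            cohort.iloc[np.flatnonzero(bad), col] = \
                rng.standard_normal(int(bad.sum()))
        if n_trunc:
            log.info("resampled %d ratio draw(s) outside %s", n_trunc,
                     RATIO_BOUNDS)
        _recompute_values(cohort, truth, config.mode)
    else:
        for col in ("fev1", "fvc", "ratio", "z_true_fev1", "z_true_fvc",
                    "z_true_ratio"):
            cohort[col] = pd.Series(dtype=float)

    cohort["component"] = ""
    cohort.attrs["mode"] = config.mode
    label_parts = []
    for component in config.disease_components:
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        cohort, lab = inject_disease(cohort, component, truth, seed=sub_seed)
        if len(lab):
            label_parts.append(lab)
    labels = (pd.concat(label_parts, ignore_index=True) if label_parts
              else pd.DataFrame(columns=["id", "component", "z_shift"]))
    return cohort, labels


def inject_disease(cohort: pd.DataFrame, component: DiseaseComponent,
                   truth: EquationSet, seed: int
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shift a random healthy subset's z-scores to create a diseased
    subpopulation; returns the modified cohort and its truth labels.

    The subset has size ``round(prevalence × n)`` drawn from the not yet
    affected subjects.  Shifts that would push a subject outside
    physical validity (ratio outside (0.2, 1], non-positive volumes) are
    resampled, with a logged count.
    """
    mode = cohort.attrs.get("mode", "index_consistent")
    rng = np.random.default_rng(seed)
    cohort = cohort.copy()
    cohort.attrs["mode"] = mode
    n = len(cohort)
    k = int(round(component.prevalence * n))
    if k == 0:
        return cohort, pd.DataFrame(columns=["id", "component", "z_shift"])
    eligible = np.flatnonzero(cohort["component"].to_numpy() == "")
    if k > eligible.size:
        raise ValueError(f"cannot place {k} diseased subjects: only "
                         f"{eligible.size} healthy remain")
    chosen = rng.choice(eligible, size=k, replace=False)
    chosen.sort()

    targets = (["z_true_ratio"] if component.type == "obstructive"
               else (["z_true_fvc", "z_true_fev1"] if mode == "marginal"
                     else ["z_true_fvc"]))
    shift = rng.normal(component.z_shift_mean, component.z_shift_sd, size=k)

    sexes = cohort["sex"].to_numpy()[chosen]
    age = cohort["age"].to_numpy(dtype=float)[chosen]
    height = cohort["height"].to_numpy(dtype=float)[chosen]
    base = {t: cohort[t].to_numpy(dtype=float)[chosen] for t in targets}

    n_resampled = 0
    for _ in range(100):
        bad = np.zeros(k, dtype=bool)
        for t in targets:
            index = t.removeprefix("z_true_")
            z_new = base[t] + shift
            # the LMS inverse needs 1 + L*S*z > 0; treat violations as invalid
            try:
                y = _values_at_z(truth, sexes, age, height, index, z_new)
            except ValueError:
                y = np.full(k, np.nan)
                for j in range(k):
                    try:
                        y[j] = _values_at_z(truth, sexes[j:j + 1],
                                            age[j:j + 1], height[j:j + 1],
                                            index, z_new[j:j + 1])[0]
                    except ValueError:
                        pass
            if index == "ratio":
                bad |= ~np.isfinite(y) | (y <= RATIO_FLOOR) | (y > 1.0)
            else:
                bad |= ~np.isfinite(y) | (y <= 0)
        if not bad.any():
            break
        n_resampled += int(bad.sum())
        shift[bad] = rng.normal(component.z_shift_mean,
                                component.z_shift_sd, size=int(bad.sum()))
    if n_resampled:
        log.info("resampled %d disease shift(s) violating physical validity",
                 n_resampled)

    for t in targets:
        col = cohort.columns.get_loc(t)
        cohort.iloc[chosen, col] = base[t] + shift
    comp_col = cohort.columns.get_loc("component")
    cohort.iloc[chosen, comp_col] = component.type
    _recompute_values(cohort, truth, mode)
    labels = pd.DataFrame({
        "id": cohort["id"].to_numpy()[chosen],
        "component": component.type,
        "z_shift": shift,
    })
    return cohort, labels


# ---------------------------------------------------------------------------
# fixture equation sets
# ---------------------------------------------------------------------------

# target medians at (mean height, age 48) per (sex, index)
_MEDIAN_TARGETS = {
    ("male", "fvc"): 5.2, ("male", "fev1"): 4.05, ("male", "ratio"): 0.78,
    ("female", "fvc"): 3.65, ("female", "fev1"): 2.91, ("female", "ratio"): 0.80,
}
_REF_HEIGHT = {"male": 176.5, "female": 163.0}
_REF_AGE = 48.0

_LINEAR_TERMS = {
    ("male", "fev1"): {"height": 0.046, "age": -0.028},
    ("male", "fvc"): {"height": 0.058, "age": -0.025},
    ("male", "ratio"): {"height": -0.0002, "age": -0.0019},
    ("female", "fev1"): {"height": 0.040, "age": -0.023},
    ("female", "fvc"): {"height": 0.049, "age": -0.021},
    ("female", "ratio"): {"height": -0.0002, "age": -0.0017},
}
_LINEAR_SD = {
    ("male", "fev1"): 0.50, ("male", "fvc"): 0.60, ("male", "ratio"): 0.070,
    ("female", "fev1"): 0.40, ("female", "fvc"): 0.45, ("female", "ratio"): 0.060,
}


def _round6(x):
    return np.round(np.asarray(x, dtype=float), 6)


def generate_fixture_equation_set(seed: int = 0,
                                  family: Literal["lms", "linear_sd"] = "lms",
                                  name: str | None = None,
                                  path=None) -> EquationSet:
    """A physiologically plausible fixture reference model.

    LMS family: M increases with height (positive ln-height power) and
    declines smoothly beyond young adulthood; S stays in roughly
    0.10–0.15 and L in 0.7–1.3; the age spline spans 18–95 years on a
    one-year grid.  Linear family: per-sex linear predictions in height
    and age with a constant residual SD, valid 18–65 years, carrying the
    classical percent-of-predicted LLN cutoffs (ratio 88, volumes 80).

    All coefficients are rounded to six decimals so that writing the set
    with :func:`spiroref.fileio.write_equation_set` and loading it back
    reproduces the in-memory model exactly; the same seed always yields
    a byte-identical file.  ``path``, when given, writes the file.
    """
    rng = np.random.default_rng(seed)
    if name is None:
        name = f"fixture-{family}-{seed}"

    if family == "lms":
        ages = np.arange(18.0, 95.0 + 1e-9, 1.0)
        coefficients = {}
        for sex in ("male", "female"):
            for index in INDICES:
                target = _MEDIAN_TARGETS[(sex, index)] * rng.uniform(0.98, 1.02)
                m_lnheight = (rng.uniform(1.9, 2.3) if index != "ratio"
                              else rng.uniform(-0.15, -0.05))
                m_lnage = rng.uniform(-0.08, -0.03)
                # smooth decline beyond age 25, plus a gentle seeded wave
                k = (1.2e-4 if index != "ratio" else 4e-5) * rng.uniform(0.8, 1.2)
                phase = rng.uniform(0, 2 * np.pi)
                msp = (-k * np.clip(ages - 25.0, 0.0, None) ** 2
                       + 0.002 * np.sin(2 * np.pi * (ages - 18) / 60 + phase))
                msp_ref = float(np.interp(_REF_AGE, ages, msp))
                m_intercept = (np.log(target)
                               - m_lnheight * np.log(_REF_HEIGHT[sex])
                               - m_lnage * np.log(_REF_AGE) - msp_ref)
                s_target = rng.uniform(0.11, 0.14) if index != "ratio" \
                    else rng.uniform(0.10, 0.12)
                s_lnage = rng.uniform(0.02, 0.08)
                ssp = 0.002 * np.sin(2 * np.pi * (ages - 18) / 45
                                     + rng.uniform(0, 2 * np.pi))
                ssp_ref = float(np.interp(_REF_AGE, ages, ssp))
                s_intercept = (np.log(s_target) - s_lnage * np.log(_REF_AGE)
                               - ssp_ref)
                L = (1.0 + rng.uniform(-0.2, 0.2)
                     + 0.1 * np.sin(2 * np.pi * (ages - 18) / 77
                                    + rng.uniform(0, 2 * np.pi)))
                coefficients[(sex, index)] = LMSCoefficients(
                    m_intercept=float(_round6(m_intercept)),
                    m_lnheight=float(_round6(m_lnheight)),
                    m_lnage=float(_round6(m_lnage)),
                    s_intercept=float(_round6(s_intercept)),
                    s_lnage=float(_round6(s_lnage)),
                    spline_age=_round6(ages),
                    spline_l=_round6(L),
                    spline_m=_round6(msp),
                    spline_s=_round6(ssp),
                )
        eqset: EquationSet = LMSEquationSet(
            name=name, coefficients=coefficients, valid_age_range=(18.0, 95.0))
    elif family == "linear_sd":
        coefficients = {}
        for (sex, index), slopes in _LINEAR_TERMS.items():
            jitter = rng.uniform(0.97, 1.03)
            h = slopes["height"] * jitter
            a = slopes["age"] * rng.uniform(0.97, 1.03)
            target = _MEDIAN_TARGETS[(sex, index)]
            intercept = target - h * _REF_HEIGHT[sex] - a * _REF_AGE
            coefficients[(sex, index)] = LinearCoefficients(
                terms={"intercept": float(_round6(intercept)),
                       "height": float(_round6(h)),
                       "age": float(_round6(a))},
                residual_sd=float(_round6(_LINEAR_SD[(sex, index)]
                                          * rng.uniform(0.95, 1.05))),
            )
        eqset = LinearEquationSet(
            name=name, coefficients=coefficients, valid_age_range=(18.0, 65.0),
            pct_pred_lln_cutoffs={"ratio": 88.0, "fvc": 80.0, "fev1": 80.0})
    else:
        raise ValueError(f"family must be 'lms' or 'linear_sd', got {family!r}")

    if path is not None:
        write_equation_set(eqset, path)
    return eqset


def scale_median(eqset: LMSEquationSet, factor: float,
                 name: str | None = None) -> LMSEquationSet:
    """A copy of an LMS set with every predicted median multiplied by
    ``factor`` (L and S unchanged) — the 'offset pair' device for
    between-model z-difference studies."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    coefficients = {
        key: LMSCoefficients(
            m_intercept=c.m_intercept + float(np.log(factor)),
            m_lnheight=c.m_lnheight, m_lnage=c.m_lnage,
            s_intercept=c.s_intercept, s_lnage=c.s_lnage,
            spline_age=c.spline_age, spline_l=c.spline_l,
            spline_m=c.spline_m, spline_s=c.spline_s)
        for key, c in eqset.coefficients.items()
    }
    return LMSEquationSet(name=name or f"{eqset.name}-x{factor:g}",
                          coefficients=coefficients,
                          valid_age_range=eqset.valid_age_range)
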