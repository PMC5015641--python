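"""Reading and writing coefficient files and subject-level CSV data.

Coefficient-file dialect (plain text, UTF-8, ``#`` comments)::

    name: Demo LMS
    model_type: lms
    valid_age_range: 18 95

    [male fev1]
    m_intercept: -10.34
    m_lnheight: 2.18
    m_lnage: 0.02
    s_intercept: -2.10
    s_lnage: 0.05
    spline:
    age, L, Mspline, Sspline
    18.00, 1.00, 0.0100, -0.0050
    ...

Linear-SD files replace the per-section body with named polynomial terms::

    name: Demo linear
    model_type: linear_sd
    valid_age_range: 18 65
    pct_pred_lln_cutoffs: ratio=88 fvc=80 fev1=80

    [male fev1]
    intercept: -3.1
    height: 0.046
    age: -0.028
    residual_sd: 0.50

Spline rows may be comma- or tab-separated.  One file holds one equation
set; a full set carries a section per (sex, index) pair.

Subject CSV interchange: columns ``id, sex, age, height_cm, fev1_l,
fvc_l`` (header required, UTF-8); optional ``centre`` and ``ratio``
columns are preserved when present.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .equations import (
    INDICES,
    SEXES,
    EquationSet,
    EquationSetError,
    LinearCoefficients,
    LinearEquationSet,
    LMSCoefficients,
    LMSEquationSet,
)

__all__ = [
    "SchemaError",
    "load_equation_set",
    "write_equation_set",
    "read_subjects_csv",
    "write_subjects_csv",
    "SUBJECT_COLUMNS",
]

SUBJECT_COLUMNS = ("id", "sex", "age", "height_cm", "fev1_l", "fvc_l")

_LMS_FIELDS = ("m_intercept", "m_lnheight", "m_lnage", "s_intercept", "s_lnage")


class SchemaError(EquationSetError):
    """A coefficient file violates the documented schema."""


def _fail(path, lineno: int | None, msg: str) -> None:
    where = f"{path}:{lineno}" if lineno else str(path)
    raise SchemaError(f"{where}: {msg}")


def _split_sections(lines: list[str], path) -> tuple[dict, list]:
    """Header key/values + list of (section key, lineno, body lines)."""
    header: dict[str, str] = {}
    sections: list[tuple[str, int, list[tuple[int, str]]]] = []
    current: list[tuple[int, str]] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.lstrip().startswith("["):
            key = line.strip()
            if not key.endswith("]"):
                _fail(path, lineno, f"unterminated section header {key!r}")
            current = []
            sections.append((key[1:-1].strip(), lineno, current))
        elif current is None:
            if ":" not in line:
                _fail(path, lineno, f"expected 'key: value' in header, got {line!r}")
            k, v = line.split(":", 1)
            header[k.strip()] = v.strip()
        else:
            current.append((lineno, line))
    return header, sections


def _parse_float(path, lineno, key, value) -> float:
    try:
        return float(value)
    except ValueError:
        _fail(path, lineno, f"field {key!r}: not a number: {value!r}")


def _parse_spline(path, body: list[tuple[int, str]], start: int):
    rows = []
    header_seen = False
    for lineno, line in body[start:]:
        parts = [p for p in line.replace(",", " ").replace("\t", " ").split() if p]
        if not header_seen:
            if [p.lower() for p in parts] != ["age", "l", "mspline", "sspline"]:
                _fail(path, lineno,
                      "spline header must be 'age, L, Mspline, Sspline'")
            header_seen = True
            continue
        if len(parts) != 4:
            _fail(path, lineno, f"spline row needs 4 values, got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            _fail(path, lineno, f"non-numeric spline row: {line!r}")
    if len(rows) < 2:
        _fail(path, body[start][0] if body[start:] else None,
              "spline table needs at least two data rows")
    arr = np.asarray(rows, dtype=float)
    if not np.all(np.diff(arr[:, 0]) > 0):
        _fail(path, None, "spline ages must be strictly increasing")
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


def _section_key(path, lineno, key: str) -> tuple[str, str]:
    parts = key.split()
    if len(parts) != 2:
        _fail(path, lineno, f"section header must be '[sex index]', got [{key}]")
    sex, index = parts
    if sex not in SEXES:
        _fail(path, lineno, f"unknown sex {sex!r} (expected one of {SEXES})")
    if index not in INDICES:
        _fail(path, lineno, f"unknown index {index!r} (expected one of {INDICES})")
    return sex, index


def load_equation_set(path: str | Path) -> EquationSet:
    """Load and validate an equation set from a coefficient file.

    Raises :class:`SchemaError` naming the offending field and line for
    any violation of the documented dialect.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    header, sections = _split_sections(lines, path)

    for required in ("name", "model_type", "valid_age_range"):
        if required not in header:
            _fail(path, None, f"missing header field {required!r}")
    name = header["name"]
    model_type = header["model_type"]
    if model_type not in ("lms", "linear_sd"):
        _fail(path, None, f"field 'model_type': must be 'lms' or 'linear_sd', "
                          f"got {model_type!r}")
    range_parts = header["valid_age_range"].replace(",", " ").split()
    if len(range_parts) != 2:
        _fail(path, None, "field 'valid_age_range': expected two numbers")
    lo = _parse_float(path, None, "valid_age_range", range_parts[0])
    hi = _parse_float(path, None, "valid_age_range", range_parts[1])
    if not lo < hi:
        _fail(path, None, f"field 'valid_age_range': min must be < max, "
                          f"got [{lo}, {hi}]")
    if not sections:
        _fail(path, None, "no [sex index] sections found")

    cutoffs = None
    if "pct_pred_lln_cutoffs" in header:
        cutoffs = {}
        for item in header["pct_pred_lln_cutoffs"].replace(",", " ").split():
            if "=" not in item:
                _fail(path, None, "field 'pct_pred_lln_cutoffs': expected "
                                  f"'index=value' items, got {item!r}")
            idx, val = item.split("=", 1)
            if idx not in INDICES:
                _fail(path, None, f"field 'pct_pred_lln_cutoffs': unknown "
                                  f"index {idx!r}")
            cutoffs[idx] = _parse_float(path, None, "pct_pred_lln_cutoffs", val)

    coefficients: dict[tuple[str, str], object] = {}
    for key, lineno, body in sections:
        sexidx = _section_key(path, lineno, key)
        if sexidx in coefficients:
            _fail(path, lineno, f"duplicate section [{key}]")
        fields: dict[str, float] = {}
        flags: dict[str, bool] = {}
        spline = None
        for i, (ln, line) in enumerate(body):
            if ":" not in line:
                _fail(path, ln, f"expected 'key: value', got {line!r}")
            k, v = (s.strip() for s in line.split(":", 1))
            if k == "spline":
                spline = _parse_spline(path, body, i + 1)
                break
            if k == "log_outcome":
                flags[k] = v.lower() in ("true", "1", "yes")
            else:
                fields[k] = _parse_float(path, ln, k, v)

        if model_type == "lms":
            missing = [f for f in _LMS_FIELDS if f not in fields]
            if missing:
                _fail(path, lineno, f"section [{key}]: missing field(s) {missing}")
            if spline is None:
                _fail(path, lineno, f"section [{key}]: missing spline table")
            age, L, msp, ssp = spline
            try:
                coefficients[sexidx] = LMSCoefficients(
                    *(fields[f] for f in _LMS_FIELDS),
                    spline_age=age, spline_l=L, spline_m=msp, spline_s=ssp)
            except EquationSetError as exc:
                _fail(path, lineno, f"section [{key}]: {exc}")
        else:
            if "residual_sd" not in fields:
                _fail(path, lineno, f"section [{key}]: missing field 'residual_sd'")
            sd = fields.pop("residual_sd")
            try:
                coefficients[sexidx] = LinearCoefficients(
                    terms=fields, residual_sd=sd,
                    log_outcome=flags.get("log_outcome", False))
            except EquationSetError as exc:
                _fail(path, lineno, f"section [{key}]: {exc}")

    try:
        if model_type == "lms":
            return LMSEquationSet(name=name, coefficients=coefficients,
                                  valid_age_range=(lo, hi))
        return LinearEquationSet(name=name, coefficients=coefficients,
                                 valid_age_range=(lo, hi),
                                 pct_pred_lln_cutoffs=cutoffs)
    except EquationSetError as exc:
        _fail(path, None, str(exc))


def write_equation_set(eqset: EquationSet, path: str | Path) -> Path:
    """Serialise an equation set to the coefficient-file dialect.

    Output is byte-deterministic: fixed field order and a fixed ``%.6f``
    float format, so identical models produce identical files.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write(f"name: {eqset.name}\n")
    buf.write(f"model_type: {eqset.model_type}\n")
    lo, hi = eqset.valid_age_range
    buf.write(f"valid_age_range: {lo:g} {hi:g}\n")
    if eqset.model_type == "linear_sd" and eqset.pct_pred_lln_cutoffs:
        items = " ".join(f"{k}={v:g}"
                         for k, v in sorted(eqset.pct_pred_lln_cutoffs.items()))
        buf.write(f"pct_pred_lln_cutoffs: {items}\n")
    for (sex, index) in sorted(eqset.coefficients):
        c = eqset.coefficients[(sex, index)]
        buf.write(f"\n[{sex} {index}]\n")
        if eqset.model_type == "lms":
            for f in _LMS_FIELDS:
                buf.write(f"{f}: {getattr(c, f):.6f}\n")
            buf.write("spline:\n")
            buf.write("age, L, Mspline, Sspline\n")
            for a, L, m, s in zip(c.spline_age, c.spline_l, c.spline_m, c.spline_s):
                buf.write(f"{a:.2f}, {L:.6f}, {m:.6f}, {s:.6f}\n")
        else:
            for k in sorted(c.terms):
                buf.write(f"{k}: {c.terms[k]:.6f}\n")
            if c.log_outcome:
                buf.write("log_outcome: true\n")
            buf.write(f"residual_sd: {c.residual_sd:.6f}\n")
    path.write_text(buf.getvalue(), encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# subject CSV
# ---------------------------------------------------------------------------


def read_subjects_csv(path: str | Path) -> pd.DataFrame:
    """Read the subject interchange CSV, validating schema and invariants.

    Returns a DataFrame with columns id, sex, age, height, fev1, fvc
    (plus centre/ratio when present) and a boolean ``valid`` column that
    is False where FEV1 > FVC.  Structural problems (missing columns,
    unknown sex codes, non-positive numbers) raise ``ValueError`` with
    the offending rows listed by line number.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str})
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    errors: list[str] = []
    sex = df["sex"].astype(str).str.strip().str.lower()
    bad_sex = ~sex.isin(SEXES)
    for i in df.index[bad_sex]:
        errors.append(f"line {i + 2}: unknown sex {df.at[i, 'sex']!r}")
    numeric = {}
    for col in ("age", "height_cm", "fev1_l", "fvc_l"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals <= 0)
        for i in df.index[bad]:
            errors.append(f"line {i + 2}: column {col!r}: "
                          f"invalid value {df.at[i, col]!r}")
        numeric[col] = vals
    if errors:
        raise ValueError(f"{path}: {len(errors)} bad record(s):\n"
                         + "\n".join(errors[:20]))

    out = pd.DataFrame({
        "id": df["id"],
        "sex": sex,
        "age": numeric["age"],
        "height": numeric["height_cm"],
        "fev1": numeric["fev1_l"],
        "fvc": numeric["fvc_l"],
    })
    if "centre" in df.columns:
        out["centre"] = df["centre"]
    if "ratio" in df.columns:
        out["ratio"] = pd.to_numeric(df["ratio"], errors="coerce")
    out["valid"] = out["fev1"] <= out["fvc"]
    return out


def write_subjects_csv(cohort: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort frame to the subject interchange CSV."""
    path = Path(path)
    out = pd.DataFrame({
        "id": cohort["id"],
        "sex": cohort["sex"],
        "age": cohort["age"],
        "height_cm": cohort["height"],
        "fev1_l": cohort["fev1"],
        "fvc_l": cohort["fvc"],
    })
    for extra in ("centre", "ratio"):
        if extra in cohort.columns:
            out[extra] = cohort[extra]
    out.to_csv(path, index=False, float_format="%.6f")
    return path
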