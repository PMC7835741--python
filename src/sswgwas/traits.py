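"""Adjustment of pig growth measurements to the 100 kg reference weight.

Off-test measurements are taken at whatever weight the animal happened to
reach, so national evaluation systems standardize them to a common 100 kg
endpoint with sex-specific correction factors (the CCSI convention; "sire"
factors apply to males, "dam" factors to females):

* AGE100 = age - (weight - 100) / CF1, CF1 = (weight/age) * 1.826 (male)
  or * 1.715 (female);
* ADG100 = 100 kg / AGE100, reported in g/day;
* BF100  = BF  * A / (A + B (weight - 100)), A,B = 13.47, 0.1115 (male)
  or 15.65, 0.1566 (female);
* LMD100 = LMD * a / (a + b (weight - 100)), a,b = 50.52, 0.228 (male)
  or 52.01, 0.228 (female);
* LMP100 = 61.21920 - 0.77665 * BF100 + 0.15239 * LMD100.

The lean-percentage equation is applied to the already-adjusted BF and LMD.
Animals measured outside 100 +/- 5 kg are flagged, not dropped.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AGE_FACTOR = {"male": 1.826, "female": 1.715}
BF_COEF = {"male": (13.47, 0.1115), "female": (15.65, 0.1566)}
LMD_COEF = {"male": (50.52, 0.228), "female": (52.01, 0.228)}
LMP_INTERCEPT = 61.21920
LMP_BF_COEF = -0.77665
LMP_LMD_COEF = 0.15239

_MALE_TOKENS = {"male", "m", "1", "sire", "boar"}
_FEMALE_TOKENS = {"female", "f", "2", "dam", "gilt", "sow"}


def normalize_sex(sex) -> np.ndarray:
    """Map assorted sex codings to 'male'/'female' (vectorized, 1-d output)."""
    arr = np.atleast_1d(np.asarray(sex, dtype=object)).ravel()
    out = np.empty(arr.shape, dtype=object)
    for i, v in enumerate(arr):
        token = str(v).strip().lower()
        if token in _MALE_TOKENS:
            out[i] = "male"
        elif token in _FEMALE_TOKENS:
            out[i] = "female"
        else:
            raise ValueError(f"unrecognized sex code {v!r}")
    return out


def _lookup(sex, table: dict) -> np.ndarray:
    """Per-element coefficient lookup; returns array of scalars or pairs."""
    return np.asarray([table[s] for s in normalize_sex(sex)], dtype=float)


def _maybe_scalar(out: np.ndarray, *inputs):
    scalar = all(np.ndim(x) == 0 for x in inputs)
    return float(out[0]) if scalar else out


def adjust_age(age, weight, sex):
    """Days to 100 kg from measured age (days) and weight (kg)."""
    age = np.atleast_1d(np.asarray(age, dtype=float))
    w = np.atleast_1d(np.asarray(weight, dtype=float))
    if np.any(age <= 0) or np.any(w <= 0):
        raise ValueError("measured age and weight must be strictly positive")
    cf1 = w / age * _lookup(sex, AGE_FACTOR)
    out = age - (w - 100.0) / cf1
    return _maybe_scalar(out, np.asarray(weight))


def adjust_adg(age100):
    """Average daily gain to 100 kg, in g/day, from adjusted age in days."""
    a = np.atleast_1d(np.asarray(age100, dtype=float))
    if np.any(a <= 0):
        raise ValueError("adjusted age must be strictly positive")
    return _maybe_scalar(100_000.0 / a, np.asarray(age100))


def _ratio_adjust(value, weight, sex, table, what):
    v = np.atleast_1d(np.asarray(value, dtype=float))
    w = np.atleast_1d(np.asarray(weight, dtype=float))
    if np.any(v < 0):
        raise ValueError(f"{what} must be non-negative")
    coefs = _lookup(sex, table)
    a, b = coefs[:, 0], coefs[:, 1]
    denom = a + b * (w - 100.0)
    if np.any(denom <= 0):
        raise ValueError("adjustment denominator non-positive (weight too far below 100 kg)")
    return _maybe_scalar(v * a / denom, np.asarray(value))


def adjust_bf(bf, weight, sex):
    """Backfat thickness (mm) adjusted to 100 kg."""
    return _ratio_adjust(bf, weight, sex, BF_COEF, "backfat")


def adjust_lmd(lmd, weight, sex):
    """Loin muscle depth (mm) adjusted to 100 kg."""
    return _ratio_adjust(lmd, weight, sex, LMD_COEF, "loin muscle depth")


def compute_lmp(bf100, lmd100):
    """Predicted lean meat percentage from 100 kg-adjusted BF and LMD."""
    bf = np.atleast_1d(np.asarray(bf100, dtype=float))
    lmd = np.atleast_1d(np.asarray(lmd100, dtype=float))
    if not (np.all(np.isfinite(bf)) and np.all(np.isfinite(lmd))):
        raise ValueError("non-finite input to lean meat percentage")
    out = LMP_INTERCEPT + LMP_BF_COEF * bf + LMP_LMD_COEF * lmd
    return _maybe_scalar(out, np.asarray(bf100))


def adjust_table(
    frame: pd.DataFrame,
    sex_col: str = "sex",
    age_col: str = "age",
    weight_col: str = "weight",
    bf_col: str = "bf",
    lmd_col: str = "lmd",
    id_col: str = "id",
) -> pd.DataFrame:
    """Adjust a raw-measurement table; one output row per animal.

    Emits age100, adg100, bf100, lmd100, lmp100 plus an ``off_target_weight``
    flag for animals measured outside 100 +/- 5 kg (flagged, not dropped).
    """
    sex = normalize_sex(frame[sex_col])
    weight = np.asarray(frame[weight_col], dtype=float)
    out = pd.DataFrame({id_col: frame[id_col].values, sex_col: sex})
    out["age100"] = adjust_age(frame[age_col].values, weight, sex)
    out["adg100"] = adjust_adg(out["age100"].values)
    if bf_col in frame and lmd_col in frame:
        out["bf100"] = adjust_bf(frame[bf_col].values, weight, sex)
        out["lmd100"] = adjust_lmd(frame[lmd_col].values, weight, sex)
        out["lmp100"] = compute_lmp(out["bf100"].values, out["lmd100"].values)
    out["off_target_weight"] = np.abs(weight - 100.0) > 5.0
    return out
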