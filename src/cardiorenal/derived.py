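"""Derived risk factors and the ordered 10-feature clustering vector.

BMI, waist-to-height ratio and non-HDL cholesterol are simple ratios of raw
measurements.  Kidney function is summarized as eGFR from serum creatinine
with the CKD-EPI creatinine equation; the 2009 equation is the default (the
analysis period predates the 2021 race-free refit) with the race multiplier
off, and the 2021 refit is selectable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .schema import FEATURES

# CKD-EPI creatinine coefficients (kappa, alpha, shared exponent, age base,
# female multiplier, optional race multiplier), per published equation versions.
CKD_EPI_PARAMS = {
    "2009": {
        "scale": 141.0,
        "kappa": {"female": 0.7, "male": 0.9},
        "alpha": {"female": -0.329, "male": -0.411},
        "beta": -1.209,
        "age_base": 0.993,
        "female_mult": 1.018,
        "race_mult": 1.159,
    },
    "2021": {
        "scale": 142.0,
        "kappa": {"female": 0.7, "male": 0.9},
        "alpha": {"female": -0.241, "male": -0.302},
        "beta": -1.200,
        "age_base": 0.9938,
        "female_mult": 1.012,
        "race_mult": 1.0,
    },
}


def egfr_ckdepi(scr, age, sex, version="2009", race_coefficient=False, race_indicated=False):
    """eGFR (ml/min/1.73 m^2) from serum creatinine (mg/dL), age and sex.

    Piecewise power law: scale * min(scr/kappa, 1)^alpha * max(scr/kappa, 1)^beta
    * age_base^age * female multiplier, with sex-specific knot ``kappa`` and
    below-knot exponent ``alpha``.  Vectorized over ``scr``/``age``/``sex``.

    Parameters
    ----------
    race_coefficient : bool
        Apply the (2009-equation) race multiplier where ``race_indicated``.
        Off by default.
    """
    p = CKD_EPI_PARAMS[str(version)]
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0):
        raise ValueError("serum creatinine must be positive")
    sex_arr = np.asarray(sex, dtype=object)
    female = sex_arr == "female"
    kappa = np.where(female, p["kappa"]["female"], p["kappa"]["male"])
    alpha = np.where(female, p["alpha"]["female"], p["alpha"]["male"])
    ratio = scr / kappa
    g = (
        p["scale"]
        * np.minimum(ratio, 1.0) ** alpha
        * np.maximum(ratio, 1.0) ** p["beta"]
        * p["age_base"] ** age
        * np.where(female, p["female_mult"], 1.0)
    )
    if race_coefficient:
        g = g * np.where(np.asarray(race_indicated, dtype=bool), p["race_mult"], 1.0)
    if g.ndim == 0:
        return float(g)
    return g


def invert_egfr(target, age, sex, version="2009"):
    """Serum creatinine (mg/dL) whose eGFR equals ``target`` at given age/sex.

    eGFR is strictly decreasing in creatinine so the inverse is unique; the
    piecewise power law inverts in closed form on each branch (both branches
    meet at scr = kappa).  Vectorized over target/age/sex.
    """
    p = CKD_EPI_PARAMS[str(version)]
    target = np.asarray(target, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(target <= 0):
        raise ValueError("target eGFR must be positive")
    sex_arr = np.asarray(sex, dtype=object)
    female = sex_arr == "female"
    kappa = np.where(female, p["kappa"]["female"], p["kappa"]["male"])
    alpha = np.where(female, p["alpha"]["female"], p["alpha"]["male"])
    base = p["scale"] * p["age_base"] ** age * np.where(female, p["female_mult"], 1.0)
    r = target / base  # equals (scr/kappa)^beta above the knot, ^alpha below
    scr = np.where(r <= 1.0, kappa * r ** (1.0 / p["beta"]), kappa * r ** (1.0 / alpha))
    if scr.ndim == 0:
        return float(scr)
    return scr


def invert_egfr_numeric(target, age, sex, version="2009", lo=0.01, hi=50.0):
    """Root-finding inverse of eGFR (scalar); cross-check for invert_egfr."""
    return brentq(lambda s: egfr_ckdepi(s, age, sex, version=version) - target, lo, hi, xtol=1e-10)


def derive_ratios(df: pd.DataFrame) -> pd.DataFrame:
    """Append bmi, whtr and non_hdl columns computed from raw fields.

    bmi = body_weight / (height/100)^2; whtr = waist / height;
    non_hdl = tc - hdl.  Missing inputs propagate to missing outputs.
    """
    if (df["height"] <= 0).any():
        raise ValueError("height must be positive")
    out = df.copy()
    h_m = out["height"] / 100.0
    out["bmi"] = out["body_weight"] / (h_m**2)
    out["whtr"] = out["waist"] / out["height"]
    non_hdl = out["tc"] - out["hdl"]
    if (non_hdl < 0).any():
        raise ValueError("TC < HDL encountered; records must be cleaned upstream")
    out["non_hdl"] = non_hdl
    return out


def derive_egfr(df: pd.DataFrame, version="2009", race_coefficient=False) -> pd.DataFrame:
    """Append the egfr column from calibrated serum creatinine, age and sex."""
    out = df.copy()
    scr = out["scr"].to_numpy(dtype=float)
    ok = np.isfinite(scr) & (scr > 0)
    egfr = np.full(len(out), np.nan)
    if ok.any():
        race_ind = (
            (out["ethnicity"] == "non_hispanic_black").to_numpy()
            if "ethnicity" in out
            else np.zeros(len(out), bool)
        )
        egfr[ok] = egfr_ckdepi(
            scr[ok],
            out["age"].to_numpy(dtype=float)[ok],
            out["sex"].to_numpy()[ok],
            version=version,
            race_coefficient=race_coefficient,
            race_indicated=race_ind[ok],
        )
    out["egfr"] = egfr
    return out


def feature_matrix(df: pd.DataFrame, require_complete=True):
    """The n x 10 clustering matrix in canonical feature order.

    Returns ``(X, complete)`` where ``complete`` marks rows with all 10
    entries present.  With ``require_complete`` the matrix is restricted to
    complete rows.
    """
    missing = [f for f in FEATURES if f not in df.columns]
    if missing:
        raise KeyError(f"missing derived feature columns: {missing}")
    X = df[FEATURES].to_numpy(dtype=float)
    complete = np.isfinite(X).all(axis=1)
    if require_complete:
        return X[complete], complete
    return X, complete


def assemble_feature_vector(record: pd.Series):
    """Canonical-order 10-vector for one participant, or None if incomplete."""
    vals = np.array([record.get(f, np.nan) for f in FEATURES], dtype=float)
    if not np.isfinite(vals).all():
        return None
    return vals
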