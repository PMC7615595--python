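"""Data cleaning: plausibility filters, blood-pressure summarization,
internal-consistency checks, pairwise Mahalanobis outlier exclusion,
creatinine calibration and analysis-set restriction.

The cleaning stack mirrors the field-standard order for survey biomarker
data: summarize repeated BP readings (discard the first, average the rest),
null out values outside plausibility ranges, enforce SBP > DBP and
TC >= HDL, then screen bivariate relationships with a Mahalanobis distance
cut and finally restrict to complete-case adults (age >= 20).

The Mahalanobis screen targets records whose *pair* of values is jointly
implausible even though each value is individually in range (e.g. SBP 248
with DBP 40, or BMI 42 with waist 74 cm).  Variables are log-transformed
before screening except height and DBP, and the squared distance is compared
with the chi-square(2) quantile equivalent to a two-sided 6-SD univariate
tail (40.09).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from .schema import SBP_READING_COLS, DBP_READING_COLS, FEATURES

logger = logging.getLogger(__name__)

#: default per-variable plausibility bounds on natural scales (overridable).
DEFAULT_PLAUSIBILITY_RANGES = {
    "height": (100.0, 250.0),
    "body_weight": (25.0, 350.0),
    "waist": (40.0, 250.0),
    "bmi": (10.0, 80.0),
    "whtr": (0.2, 1.5),
    "sbp": (70.0, 270.0),
    "dbp": (30.0, 150.0),
    "rhr": (30.0, 200.0),
    "tc": (1.75, 20.0),
    "hdl": (0.4, 5.0),
    "hba1c": (3.0, 18.0),
    "scr": (0.2, 15.0),
}

#: variables screened in pairs: all anthropometric pairs, the BP pair, the lipid pair
DEFAULT_PAIR_GROUPS = {
    "anthropometric": ["height", "body_weight", "bmi", "waist", "whtr"],
    "blood_pressure": ["sbp", "dbp"],
    "lipids": ["tc", "hdl"],
}

#: log-transform everything except these before Mahalanobis screening
NO_LOG_VARS = {"height", "dbp"}

MIN_COMPLETE_PAIRS = 10


@dataclass
class CleaningReport:
    """Per-rule removal/nulling counts and per-record flags."""

    n_input: int = 0
    n_output: int = 0
    values_out_of_range: dict = field(default_factory=dict)
    bp_inconsistent: int = 0
    lipid_inconsistent: int = 0
    mahalanobis_flags: dict = field(default_factory=dict)
    removed_under_age: int = 0
    removed_incomplete: int = 0
    skipped_pairs: list = field(default_factory=list)

    def to_dict(self):
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "values_out_of_range": dict(self.values_out_of_range),
            "bp_inconsistent": self.bp_inconsistent,
            "lipid_inconsistent": self.lipid_inconsistent,
            "mahalanobis_flags": {f"{a}|{b}": v for (a, b), v in self.mahalanobis_flags.items()},
            "removed_under_age": self.removed_under_age,
            "removed_incomplete": self.removed_incomplete,
            "skipped_pairs": [f"{a}|{b}" for a, b in self.skipped_pairs],
        }


def summarize_blood_pressure(readings):
    """Summary BP from ordered repeated readings.

    The first reading is discarded (white-coat inflation) and the remaining
    readings averaged.  Fewer than two readings leaves nothing to average and
    yields missing; ``use_single_reading`` in :func:`summarize_bp_columns`
    relaxes that.
    """
    try:
        arr = np.asarray([np.nan if v is None else v for v in readings], dtype=float)
    except (TypeError, ValueError) as e:
        raise ValueError("non-numeric blood pressure reading") from e
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        return np.nan
    return float(arr[1:].mean())


def summarize_bp_columns(df: pd.DataFrame, use_single_reading=False) -> pd.DataFrame:
    """Append summarized sbp/dbp columns from the reading columns."""
    out = df.copy()
    for target, cols in (("sbp", SBP_READING_COLS), ("dbp", DBP_READING_COLS)):
        readings = out[cols].to_numpy(dtype=float)
        n_valid = np.isfinite(readings).sum(axis=1)
        # mean of readings after the first, ignoring missing entries
        rest = readings[:, 1:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_rest = np.nanmean(rest, axis=1)
        summary = np.where(n_valid >= 2, mean_rest, np.nan)
        if use_single_reading:
            first = readings[:, 0]
            summary = np.where(n_valid == 1, first, summary)
        out[target] = summary
    return out


def apply_plausibility_and_consistency(df: pd.DataFrame, ranges=None, report=None):
    """Null values outside plausibility ranges; enforce SBP > DBP and TC >= HDL.

    Offending consistency pairs are set missing as a pair.  Individually
    plausible but jointly discordant pairs (e.g. SBP 248 / DBP 40) are left
    for the Mahalanobis screen.
    """
    ranges = dict(DEFAULT_PLAUSIBILITY_RANGES if ranges is None else ranges)
    for var, (lo, hi) in ranges.items():
        if lo >= hi:
            raise ValueError(f"plausibility range for {var} has low >= high")
    report = report if report is not None else CleaningReport(n_input=len(df))
    out = df.copy()
    for var, (lo, hi) in ranges.items():
        if var not in out.columns:
            continue
        vals = out[var].to_numpy(dtype=float)
        bad = np.isfinite(vals) & ((vals < lo) | (vals > hi))
        if bad.any():
            vals[bad] = np.nan
            out[var] = vals
            report.values_out_of_range[var] = report.values_out_of_range.get(var, 0) + int(bad.sum())
    # internal consistency on summarized values
    bp_bad = (out["sbp"] <= out["dbp"]).fillna(False).to_numpy()
    out.loc[bp_bad, ["sbp", "dbp"]] = np.nan
    report.bp_inconsistent += int(bp_bad.sum())
    lipid_bad = (out["tc"] < out["hdl"]).fillna(False).to_numpy()
    out.loc[lipid_bad, ["tc", "hdl"]] = np.nan
    report.lipid_inconsistent += int(lipid_bad.sum())
    return out, report


def mahalanobis_threshold(sd_equiv=6.0, df=2):
    """Squared-Mahalanobis cutoff equivalent to a +/- ``sd_equiv``-SD univariate tail.

    chi-square(df) quantile at cumulative probability 1 - 2(1 - Phi(sd_equiv)).
    At sd_equiv=6, df=2 this is 40.09.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if sd_equiv <= 0:
        raise ValueError("sd_equiv must be positive")
    return float(chi2.isf(2.0 * norm.sf(sd_equiv), df))


def _pair_distances(x, y, keep=None):
    """Squared Mahalanobis distances of (x, y) pairs.

    Mean and covariance are estimated over the ``keep`` subset (default all
    pairs); distances are returned for every pair.
    """
    pts = np.column_stack([x, y])
    est = pts if keep is None else pts[keep]
    mu = est.mean(axis=0)
    cov = np.cov(est, rowvar=False)
    det = np.linalg.det(cov)
    if not np.isfinite(det) or det <= 0:
        raise np.linalg.LinAlgError("singular covariance")
    inv = np.linalg.inv(cov)
    d = pts - mu
    return np.einsum("ij,jk,ik->i", d, inv, d)


def _iterative_pair_flags(ta, tb, threshold, max_iter=10):
    """Flag pairs with squared distance above threshold, re-estimating the
    mean/covariance without flagged pairs until the flag set is stable.

    Extreme pairs inflate a one-shot covariance estimate and can mask one
    another; refreshing the estimate on the unflagged pairs removes that
    masking while leaving clean data (where nothing is flagged) untouched.
    """
    keep = np.ones(len(ta), dtype=bool)
    for _ in range(max_iter):
        d2 = _pair_distances(ta, tb, keep=keep)
        new_keep = d2 <= threshold
        if np.array_equal(new_keep, keep):
            break
        keep = new_keep
    return ~keep


def pairwise_mahalanobis_outliers(
    df: pd.DataFrame,
    pair_groups=None,
    threshold=None,
    stratify_by="sex",
    drop_records=False,
    report=None,
):
    """Screen variable pairs for jointly implausible values.

    For each pair within each group, members are log-transformed (except
    height and DBP), the bivariate mean and covariance are estimated over
    complete pairs (per stratum, default per sex, on the pooled-rounds
    sample), and records with squared Mahalanobis distance above
    ``threshold`` have both members set missing (or are dropped with
    ``drop_records``).

    Returns ``(df, report, flagged)`` where ``flagged`` is a boolean Series
    marking records flagged by any pair.
    """
    pair_groups = DEFAULT_PAIR_GROUPS if pair_groups is None else pair_groups
    threshold = mahalanobis_threshold() if threshold is None else threshold
    report = report if report is not None else CleaningReport(n_input=len(df))
    out = df.copy()
    any_flag = pd.Series(False, index=out.index)

    pairs = []
    for members in pair_groups.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j]))

    strata = [((None, out.index))] if stratify_by is None else [
        (lvl, out.index[out[stratify_by] == lvl]) for lvl in out[stratify_by].unique()
    ]
    for a, b in pairs:
        flags = pd.Series(False, index=out.index)
        for _lvl, idx in strata:
            xa = out.loc[idx, a].to_numpy(dtype=float)
            xb = out.loc[idx, b].to_numpy(dtype=float)
            ok = np.isfinite(xa) & np.isfinite(xb) & (xa > 0) & (xb > 0)
            if ok.sum() < MIN_COMPLETE_PAIRS:
                report.skipped_pairs.append((a, b))
                logger.warning("pair (%s, %s): fewer than %d complete pairs; skipped", a, b, MIN_COMPLETE_PAIRS)
                continue
            ta = xa[ok] if a in NO_LOG_VARS else np.log(xa[ok])
            tb = xb[ok] if b in NO_LOG_VARS else np.log(xb[ok])
            try:
                bad = _iterative_pair_flags(ta, tb, threshold)
            except np.linalg.LinAlgError as e:
                raise np.linalg.LinAlgError(f"singular covariance for pair ({a}, {b})") from e
            sub = np.zeros(len(idx), dtype=bool)
            sub[np.flatnonzero(ok)[bad]] = True
            flags.loc[idx] = sub
        n_flag = int(flags.sum())
        if n_flag:
            report.mahalanobis_flags[(a, b)] = report.mahalanobis_flags.get((a, b), 0) + n_flag
            out.loc[flags, [a, b]] = np.nan
            any_flag |= flags
    if drop_records:
        out = out.loc[~any_flag]
    return out, report, any_flag


def calibrate_creatinine(values, slope=1.0, intercept=0.0, floor=0.05):
    """Linear recalibration of serum creatinine: slope * value + intercept.

    The calibration coefficients come from an external cross-method
    comparison and default to the identity.  Calibrated values at or below
    zero are floored at a small positive constant with a warning.
    """
    vals = np.asarray(values, dtype=float)
    out = slope * vals + intercept
    low = np.isfinite(out) & (out <= floor)
    if low.any():
        warnings.warn(f"{int(low.sum())} calibrated creatinine values at or below {floor}; floored")
        out = np.where(low, floor, out)
    return out


def build_analysis_set(df: pd.DataFrame, min_age=20, report=None):
    """Restrict to adults (age >= min_age) with a complete 10-feature vector."""
    report = report if report is not None else CleaningReport(n_input=len(df))
    adult = df["age"] >= min_age
    report.removed_under_age += int((~adult).sum())
    sub = df.loc[adult]
    X = sub[FEATURES].to_numpy(dtype=float)
    complete = np.isfinite(X).all(axis=1)
    report.removed_incomplete += int((~complete).sum())
    out = sub.loc[complete]
    report.n_output = len(out)
    if len(out) == 0:
        raise ValueError("analysis set is empty; review cleaning configuration and input data")
    return out, report


def clean_cohort(
    df: pd.DataFrame,
    ranges=None,
    sd_equiv=6.0,
    pair_groups=None,
    creatinine_slope=1.0,
    creatinine_intercept=0.0,
    egfr_version="2009",
    egfr_race_coefficient=False,
    min_age=20,
    use_single_reading=False,
    drop_flagged_records=False,
):
    """Run the full cleaning stack and return (analysis set, CleaningReport).

    Order: BP summarization -> creatinine calibration -> ratio derivation ->
    plausibility + consistency -> eGFR derivation -> pairwise Mahalanobis
    screen -> adult complete-case restriction.
    """
    from .derived import derive_ratios, derive_egfr

    report = CleaningReport(n_input=len(df))
    out = summarize_bp_columns(df, use_single_reading=use_single_reading)
    out["scr"] = calibrate_creatinine(out["scr"], creatinine_slope, creatinine_intercept)
    out = derive_ratios_safe(out)
    out, report = apply_plausibility_and_consistency(out, ranges=ranges, report=report)
    # rebuild ratios after plausibility nulling so derived values track raw ones
    out = derive_ratios_safe(out)
    out = derive_egfr(out, version=egfr_version, race_coefficient=egfr_race_coefficient)
    thr = mahalanobis_threshold(sd_equiv=sd_equiv, df=2)
    out, report, _ = pairwise_mahalanobis_outliers(
        out, pair_groups=pair_groups, threshold=thr, report=report, drop_records=drop_flagged_records
    )
    out, report = build_analysis_set(out, min_age=min_age, report=report)
    return out, report


def derive_ratios_safe(df: pd.DataFrame) -> pd.DataFrame:
    """derive_ratios tolerant of missing/invalid raws (yields missing instead)."""
    out = df.copy()
    h = out["height"].to_numpy(dtype=float)
    w = out["body_weight"].to_numpy(dtype=float)
    wa = out["waist"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        bmi = np.where(h > 0, w / (h / 100.0) ** 2, np.nan)
        whtr = np.where(h > 0, wa / h, np.nan)
    out["bmi"] = bmi
    out["whtr"] = whtr
    non_hdl = out["tc"] - out["hdl"]
    non_hdl[non_hdl < 0] = np.nan
    out["non_hdl"] = non_hdl
    return out
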