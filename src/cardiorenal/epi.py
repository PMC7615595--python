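"""Survey-weighted prevalence, age standardization, trend and predictor
regressions, and Wilson score intervals.

Weights are prepared in two steps: (1) within each survey round, raw sample
weights are rescaled to a common total (the mean per-round sample size) so
every round contributes the same effective sample size; (2) within each
round, 5-year age-band multipliers post-stratify the weighted age
distribution to a reference population.  Trend and predictor models are
weighted logistic regressions (IRLS with frequency-style weights); p values
are two-sided large-sample Wald tests with no multiple-testing adjustment.
Design-based (strata/PSU) variance estimation is out of scope and SEs should
be read accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .schema import CATEGORICAL_LEVELS, age_band_labels, assign_age_band

logger = logging.getLogger(__name__)

#: pre-specified trend periods (boundary years inclusive on both ends)
DEFAULT_PERIODS = [(1988, 2000), (2000, 2010), (2010, 2018)]


@dataclass
class WeightScheme:
    raw: pd.Series
    rescaled: pd.Series  # per-round rescaled to the common total
    poststratified: pd.Series  # additionally age-standardized within round
    band: pd.Series  # 5-year age-band label per participant
    reference: dict  # band label -> reference proportion
    common_total: float


def uniform_reference():
    """Stylized reference age distribution: uniform over the 5-year bands."""
    labels = age_band_labels()
    return {b: 1.0 / len(labels) for b in labels}


def empirical_reference(df: pd.DataFrame, round_col="round"):
    """Pooled weighted age-band distribution, restricted to bands populated
    in every round (so per-round post-stratification is always feasible).

    The reference population of record (e.g. census counts by age) is
    external data and user-supplied; this pooled empirical distribution is
    the shipped default.
    """
    band = pd.Series(assign_age_band(df["age"].to_numpy()), index=df.index)
    w = df["weight_sample"].astype(float)
    pooled = w.groupby(band, observed=False).sum()
    n_rounds = df[round_col].nunique()
    present_everywhere = (
        df.assign(_band=band).groupby([round_col, "_band"], observed=False)["age"].size()
        .unstack(fill_value=0).gt(0).sum(axis=0) == n_rounds
    )
    ref = {b: (float(pooled[b]) if present_everywhere.get(b, False) else 0.0)
           for b in age_band_labels()}
    total = sum(ref.values())
    return {b: v / total for b, v in ref.items()}


def prepare_weights(df: pd.DataFrame, reference=None, round_col="round") -> WeightScheme:
    """Rescale weights per round to a common total, then post-stratify by age band."""
    w = df["weight_sample"].astype(float)
    if (w <= 0).any():
        raise ValueError("survey weights must be positive")
    if (df["age"] < 20).any():
        raise ValueError("weight preparation expects the adult analysis set (age >= 20)")
    reference = empirical_reference(df, round_col=round_col) if reference is None else dict(reference)
    ref_total = sum(reference.values())
    reference = {b: p / ref_total for b, p in reference.items()}

    round_sizes = df.groupby(round_col, observed=True).size()
    common_total = float(round_sizes.mean())
    round_sums = w.groupby(df[round_col], observed=True).transform("sum")
    rescaled = w * common_total / round_sums

    band = pd.Series(assign_age_band(df["age"].to_numpy()), index=df.index)
    post = rescaled.copy()
    for rnd, idx in df.groupby(round_col, observed=True).groups.items():
        wr = rescaled.loc[idx]
        br = band.loc[idx]
        band_mass = wr.groupby(br, observed=False).sum()
        total = wr.sum()
        mult = {}
        for b, p_ref in reference.items():
            mass = band_mass.get(b, 0.0)
            if mass == 0 and p_ref > 0:
                raise ValueError(f"round {rnd}: age band {b} has zero weighted mass but reference mass {p_ref}")
            mult[b] = (p_ref * total / mass) if mass > 0 else 0.0
        post.loc[idx] = wr * br.map(mult).astype(float)
    return WeightScheme(
        raw=w, rescaled=rescaled, poststratified=post, band=band,
        reference=reference, common_total=common_total,
    )


def weighted_prevalence_series(df, cluster_col, scheme: WeightScheme, round_col="round", standardized=True):
    """Per-round per-cluster weighted shares (rows sum to 1 per round).

    ``standardized`` uses the age post-stratified weights (age-standardized
    prevalence); otherwise the per-round rescaled weights (crude prevalence).
    """
    w = scheme.poststratified if standardized else scheme.rescaled
    tab = (
        pd.DataFrame({"round": df[round_col], "cluster": df[cluster_col], "w": w})
        .pivot_table(index="round", columns="cluster", values="w", aggfunc="sum", fill_value=0.0, observed=True)
    )
    return tab.div(tab.sum(axis=1), axis=0)


@dataclass
class TrendResult:
    cluster: object
    period: tuple
    coef_per_year: float
    percent_change_per_year: float
    se: float
    p_value: float
    converged: bool = True

    def to_dict(self):
        return {
            "cluster": self.cluster,
            "period_start": self.period[0],
            "period_end": self.period[1],
            "coef_per_year": self.coef_per_year,
            "percent_change_per_year": self.percent_change_per_year,
            "se": self.se,
            "p_value": self.p_value,
            "converged": self.converged,
        }


def _wald_p(coef, se):
    from scipy.stats import norm

    return float(2.0 * norm.sf(abs(coef / se)))


def _fit_weighted_logit(y, X, w):
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=np.asarray(w, dtype=float))
    return model.fit()


def trend_regression(df, member, scheme: WeightScheme, period=None, year_col="mid_year", cluster=None):
    """Weighted logistic trend for one cluster's membership.

    Regresses the membership indicator on calendar year (continuous) with
    5-year age-band indicators, using the age-standardized weights, over the
    given inclusive period.  Reports the yearly log-odds slope, the percent
    change in odds per year (100*(exp(b)-1)), its SE and two-sided Wald p.
    """
    member = np.asarray(member, dtype=float)
    years = df[year_col].astype(float)
    mask = np.ones(len(df), dtype=bool)
    if period is not None:
        mask = (years >= period[0]) & (years <= period[1])
    else:
        period = (float(years.min()), float(years.max()))
    sub = df.loc[mask]
    y = member[mask]
    if len(np.unique(sub[year_col])) < 2:
        raise ValueError("period must contain at least 2 distinct years")
    if y.min() == y.max():
        raise ValueError("membership indicator has a single class in the period")
    bands = pd.get_dummies(scheme.band.loc[sub.index], drop_first=True, dtype=float)
    X = pd.DataFrame({"const": 1.0, "year": sub[year_col].astype(float)})
    X = pd.concat([X.reset_index(drop=True), bands.reset_index(drop=True)], axis=1)
    w = scheme.poststratified.loc[sub.index].to_numpy()
    converged = True
    try:
        res = _fit_weighted_logit(y, X.to_numpy(), w)
        coef = float(res.params[1])
        se = float(res.bse[1])
        if not np.isfinite(coef) or not np.isfinite(se) or se > 1e3:
            converged = False
    except Exception:  # perfect separation and friends
        logger.warning("trend regression did not converge for cluster %s period %s", cluster, period)
        return TrendResult(cluster, tuple(period), np.nan, np.nan, np.nan, np.nan, converged=False)
    return TrendResult(
        cluster=cluster,
        period=(float(period[0]), float(period[1])),
        coef_per_year=coef,
        percent_change_per_year=100.0 * (np.exp(coef) - 1.0),
        se=se,
        p_value=_wald_p(coef, se),
        converged=converged,
    )


def trend_table(df, cluster_col, scheme, periods=None, year_col="mid_year"):
    """TrendResult per (cluster, period); default pre-specified periods plus overall."""
    periods = DEFAULT_PERIODS if periods is None else periods
    clusters = sorted(df[cluster_col].unique())
    out = []
    years = df[year_col].astype(float)
    all_periods = [(years.min(), years.max())] + list(periods)
    for c in clusters:
        member = (df[cluster_col] == c).to_numpy()
        for per in all_periods:
            try:
                out.append(trend_regression(df, member, scheme, period=per, year_col=year_col, cluster=c))
            except ValueError as e:
                logger.warning("cluster %s period %s: %s", c, per, e)
    return pd.DataFrame([t.to_dict() for t in out])


@dataclass
class PredictorModel:
    cluster: object
    table: pd.DataFrame  # index: term; columns: coef, se, p_value
    reference_levels: dict = field(default_factory=dict)
    converged: bool = True


#: declared reference levels for the predictor design
PREDICTOR_REFERENCES = {
    "age_band": "20-24",
    "ethnicity": "non_hispanic_white",
    "education": "below_high_school",
    "smoking": "never",
}
BINARY_PREDICTORS = [
    "med_antihypertensive", "med_statin", "med_oral_hypoglycemic", "med_insulin",
    "hist_mi", "hist_stroke", "hist_chf",
]


def _predictor_design(df, scheme: WeightScheme, year_col="mid_year"):
    parts = [pd.DataFrame({"const": 1.0, "year_per_decade": df[year_col].astype(float) / 10.0},
                          index=df.index)]
    band = pd.Categorical(scheme.band.loc[df.index], categories=age_band_labels())
    parts.append(pd.get_dummies(pd.Series(band, index=df.index), prefix="age", drop_first=True, dtype=float))
    for col, levels in CATEGORICAL_LEVELS.items():
        cat = pd.Categorical(df[col], categories=levels)
        parts.append(pd.get_dummies(pd.Series(cat, index=df.index), prefix=col, drop_first=True, dtype=float))
    for col in BINARY_PREDICTORS:
        parts.append(df[col].astype(float).rename(col))
    X = pd.concat(parts, axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name aliased columns by greedy QR-style elimination
        aliased = []
        keep = []
        for col in X.columns:
            trial = keep + [col]
            if np.linalg.matrix_rank(X[trial].to_numpy()) == len(trial):
                keep.append(col)
            else:
                aliased.append(col)
        raise ValueError(f"rank-deficient predictor design; aliased columns: {aliased}")
    return X


def membership_predictors(df, cluster_col, scheme: WeightScheme, clusters=None, year_col="mid_year"):
    """One weighted multivariate logistic regression per cluster.

    Covariates: age band (ref 20-24), survey year per decade, ethnicity (ref
    non-Hispanic White), education (ref below high school), smoking (ref
    never), medication use and disease-history flags.  Returns a
    PredictorModel per cluster with coefficients, SEs and two-sided Wald p.
    """
    X = _predictor_design(df, scheme, year_col=year_col)
    w = scheme.poststratified.loc[df.index].to_numpy()
    out = {}
    for c in sorted(df[cluster_col].unique()) if clusters is None else clusters:
        y = (df[cluster_col] == c).to_numpy(dtype=float)
        converged = True
        try:
            res = _fit_weighted_logit(y, X.to_numpy(), w)
            tab = pd.DataFrame(
                {"coef": res.params, "se": res.bse}, index=X.columns
            )
            tab["p_value"] = [_wald_p(b, s) for b, s in zip(tab["coef"], tab["se"])]
        except Exception:
            logger.warning("predictor regression did not converge for cluster %s", c)
            tab = pd.DataFrame(columns=["coef", "se", "p_value"])
            converged = False
        out[c] = PredictorModel(cluster=c, table=tab, reference_levels=dict(PREDICTOR_REFERENCES),
                                converged=converged)
    return out


def wilson_ci(count, n, level=0.95):
    """Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= count <= n:
        raise ValueError("count must be in [0, n]")
    lo, hi = proportion_confint(count, n, alpha=1 - level, method="wilson")
    # the Wilson bounds are exactly 0 / 1 at the extremes; avoid float fuzz
    lo = 0.0 if count == 0 else float(lo)
    hi = 1.0 if count == n else float(hi)
    return lo, hi


def age_pattern_table(df, cluster_col, scheme: WeightScheme, age_groups=None, round_col="round"):
    """Weighted binned prevalence per (round, age group) for each cluster.

    ``age_groups`` maps label -> (low, high) inclusive age bounds and must
    partition ages 20+.  Empty (round, group) cells are missing, not zero.
    """
    if age_groups is None:
        age_groups = {"20-39": (20, 39), "40-59": (40, 59), "60+": (60, 200)}
    age = df["age"].astype(float)
    group = pd.Series(pd.NA, index=df.index, dtype=object)
    for label, (lo, hi) in age_groups.items():
        group[(age >= lo) & (age <= hi)] = label
    if group.isna().any():
        raise ValueError("age_groups do not partition ages 20+")
    w = scheme.rescaled
    tab = (
        pd.DataFrame({"round": df[round_col], "group": group, "cluster": df[cluster_col], "w": w})
        .pivot_table(index=["round", "group"], columns="cluster", values="w",
                     aggfunc="sum", fill_value=0.0, observed=True)
    )
    totals = tab.sum(axis=1)
    out = tab.div(totals, axis=0)
    out[totals == 0] = np.nan
    return out
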