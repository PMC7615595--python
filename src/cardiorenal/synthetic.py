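"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: each sex
is a mixture of phenotype archetypes (multivariate normal on the natural
scales of the 10 risk factors, truncated to plausibility ranges by
resampling), with mixture weights evolving across survey rounds on the
log-odds scale, log-normal survey weights, per-archetype age distributions
over 5-year bands, and optional injected implausible/discordant/missing
records for exercising the cleaning stack.

Raw fields are back-derived from the drawn feature vector so that derived
measures are a true function of the raw data: body weight from BMI and
height, waist from WHtR and height, TC from non-HDL + HDL, serum creatinine
by inverting the eGFR equation at the drawn age and sex, and three BP
readings as the drawn value plus iid noise (SD 2 mmHg) with the first
reading biased +3 mmHg so that the first-reading-discarding rule matters.

The bundled archetype library is illustrative: mixture shares and the
defining feature levels follow published per-phenotype summaries, but the
within-cluster covariances are free parameters, so synthetic prevalence
tables are not estimates of any real population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .schema import (
    AGE_BAND_EDGES,
    BINARY_FLAGS,
    CATEGORICAL_LEVELS,
    FEATURES,
    age_band_labels,
)
from .derived import invert_egfr

#: truncation bounds for drawn features (natural scales); chosen inside the
#: cleaning plausibility ranges so an error-free cohort passes cleaning.
FEATURE_BOUNDS = {
    "height": (120.0, 210.0),
    "bmi": (14.0, 75.0),
    "whtr": (0.3, 1.1),
    "sbp": (80.0, 250.0),
    "dbp": (40.0, 140.0),
    "rhr": (40.0, 160.0),
    "hdl": (0.5, 4.5),
    "non_hdl": (1.4, 12.0),
    "hba1c": (3.5, 16.0),
    "egfr": (8.0, 170.0),  # upper bound keeps inverted creatinine above its plausibility floor
}
MIN_PULSE_PRESSURE = 10.0  # drawn SBP must exceed drawn DBP by this margin

BP_READING_NOISE_SD = 2.0
BP_FIRST_READING_BIAS = 3.0

DEFAULT_COVARIATE_PROBS = {
    "ethnicity": [0.45, 0.25, 0.22, 0.08],
    "education": [0.30, 0.35, 0.35],
    "smoking": [0.55, 0.25, 0.20],
}
DEFAULT_FLAG_PROBS = {
    "med_antihypertensive": 0.15,
    "med_statin": 0.10,
    "med_oral_hypoglycemic": 0.05,
    "med_insulin": 0.02,
    "hist_mi": 0.04,
    "hist_stroke": 0.03,
    "hist_chf": 0.03,
}


@dataclass
class ArchetypeSpec:
    """One phenotype archetype: a truncated MVN component of the mixture."""

    name: str
    mean_vector: np.ndarray  # 10 values in canonical feature order, natural scales
    covariance: np.ndarray  # 10x10 symmetric PSD
    base_weight: float
    weight_trend_per_round: float = 0.0  # additive change in mixture log-odds per round
    mean_age: float = 45.0
    age_sd: float = 13.0

    def validate(self):
        m = np.asarray(self.mean_vector, dtype=float)
        c = np.asarray(self.covariance, dtype=float)
        if m.shape != (len(FEATURES),):
            raise ValueError(f"{self.name}: mean_vector must have {len(FEATURES)} entries")
        if not np.isfinite(m).all():
            raise ValueError(f"{self.name}: mean_vector must be finite")
        if c.shape != (len(FEATURES), len(FEATURES)) or not np.allclose(c, c.T):
            raise ValueError(f"{self.name}: covariance must be symmetric 10x10")
        eig = np.linalg.eigvalsh(c)
        if eig.min() < -1e-8:
            raise ValueError(f"{self.name}: covariance is not positive semidefinite")
        if self.base_weight < 0:
            raise ValueError(f"{self.name}: base_weight must be nonnegative")

    def age_band_probs(self):
        """Discretized truncated-normal age distribution over 5-year bands."""
        edges = np.array(AGE_BAND_EDGES + [95], dtype=float)
        cdf = norm.cdf(edges, loc=self.mean_age, scale=self.age_sd)
        p = np.diff(cdf)
        return p / p.sum()


@dataclass
class CovariateEffect:
    """Binary covariate shifting one archetype's membership log-odds."""

    field: str
    prevalence: float
    archetype: int
    odds_ratio: float


@dataclass
class CohortConfig:
    sex: str
    archetypes: list
    n_per_round: int = 1000
    rounds: list = None  # list of (label, mid_year)
    weight_sigma: float = 0.5
    error_rates: dict = field(default_factory=dict)
    covariate_effects: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.rounds is None:
            self.rounds = default_rounds()

    def validate(self):
        if not self.archetypes:
            raise ValueError("archetype list is empty")
        for a in self.archetypes:
            a.validate()
        if self.n_per_round <= 0:
            raise ValueError("n_per_round must be positive")
        for key, rate in self.error_rates.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"error rate {key} must be in [0, 1]")


@dataclass
class SyntheticCohort:
    records: pd.DataFrame
    true_labels: np.ndarray
    features: np.ndarray  # drawn latent feature vectors, n x 10, canonical order
    config: CohortConfig
    artifact_ids: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.records) != len(self.true_labels):
            raise ValueError("records and true_labels length mismatch")


def default_rounds():
    """Eleven survey rounds: one 1988-1994 round then 2-year rounds to 2018."""
    rounds = [("1988-1994", 1991.0)]
    for start in range(1999, 2018, 2):
        rounds.append((f"{start}-{start + 1}", start + 0.5))
    return rounds


# ---------------------------------------------------------------------------
# default archetype library (illustrative profiles, not survey estimates)

_BASE_SD = {
    "height": 6.5, "bmi": 3.0, "whtr": 0.045, "sbp": 9.0, "dbp": 7.0,
    "rhr": 8.0, "hdl": 0.22, "non_hdl": 0.7, "hba1c": 0.45, "egfr": 11.0,
}

# name: (mean vector, base count share source, trend/round, mean age)
_WOMEN = {
    "low risk": ([163, 22.0, 0.44, 104, 66, 68, 1.75, 2.6, 5.0, 112], 4632, -0.015, 33),
    "mid risk short": ([155, 27.0, 0.52, 112, 69, 72, 1.40, 3.3, 5.4, 104], 3942, 0.02, 38),
    "mid risk tall": ([167, 27.5, 0.50, 118, 73, 70, 1.40, 3.5, 5.4, 95], 3715, 0.0, 45),
    "low BMI, high HDL": ([162, 21.5, 0.45, 119, 70, 68, 2.30, 3.0, 5.4, 90], 3027, 0.0, 55),
    "high heart rate": ([162, 26.0, 0.50, 112, 70, 95, 1.50, 3.2, 5.3, 106], 2591, 0.0, 33),
    "high cholesterol": ([161, 28.0, 0.54, 126, 76, 72, 1.40, 5.5, 5.7, 85], 2751, -0.06, 58),
    "high blood pressure": ([160, 29.0, 0.56, 159, 86, 74, 1.40, 3.9, 5.8, 80], 2522, -0.07, 64),
    "severe obesity": ([162, 41.1, 0.66, 122, 75, 76, 1.20, 3.7, 5.8, 96], 3247, 0.09, 46),
    "severe hyperglycemia": ([161, 31.8, 0.60, 128, 75, 78, 1.20, 4.2, 9.9, 90], 886, 0.0, 57),
    "low DBP, low eGFR": ([158, 27.0, 0.55, 136, 61, 70, 1.40, 3.7, 5.9, 63], 2867, 0.05, 74),
}
_MEN = {
    "low risk": ([176, 22.5, 0.44, 108, 67, 66, 1.45, 2.8, 5.0, 112], 3730, 0.0, 31),
    "mid risk short": ([168, 26.5, 0.52, 116, 71, 70, 1.15, 3.5, 5.4, 102], 3981, 0.02, 38),
    "mid risk tall": ([182, 27.0, 0.50, 121, 74, 68, 1.15, 3.6, 5.4, 95], 4028, 0.0, 44),
    "low BMI, high HDL": ([175, 21.5, 0.45, 122, 71, 66, 1.90, 3.1, 5.4, 88], 2174, 0.0, 54),
    "high heart rate": ([175, 26.5, 0.51, 118, 73, 92, 1.20, 3.6, 5.5, 98], 2401, 0.0, 45),
    "high cholesterol": ([175, 28.0, 0.54, 126, 78, 70, 1.10, 5.5, 5.6, 88], 2887, -0.05, 48),
    "high blood pressure": ([173, 28.5, 0.55, 159, 88, 72, 1.15, 3.9, 5.8, 78], 2396, -0.07, 66),
    "severe obesity": ([176, 38.2, 0.63, 126, 77, 74, 1.00, 3.9, 5.9, 94], 2613, 0.09, 48),
    "severe hyperglycemia": ([174, 29.7, 0.58, 130, 77, 76, 1.05, 4.4, 9.8, 88], 976, 0.0, 57),
    "low DBP, low eGFR": ([172, 27.0, 0.54, 138, 63, 68, 1.15, 3.8, 5.9, 61], 3086, 0.05, 73),
}
_SD_OVERRIDES = {
    "severe obesity": {"bmi": 4.0, "whtr": 0.055},
    "severe hyperglycemia": {"hba1c": 1.3},
    "high blood pressure": {"sbp": 11.0},
    "low DBP, low eGFR": {"egfr": 9.0, "dbp": 6.0},
}


def default_archetypes(sex: str) -> list:
    """Ten sex-specific archetypes with illustrative profile means."""
    table = {"female": _WOMEN, "male": _MEN}[sex]
    out = []
    for name, (mean, count, trend, mean_age) in table.items():
        sd = dict(_BASE_SD)
        sd.update(_SD_OVERRIDES.get(name, {}))
        cov = np.diag([sd[f] ** 2 for f in FEATURES])
        out.append(
            ArchetypeSpec(
                name=name,
                mean_vector=np.array(mean, dtype=float),
                covariance=cov,
                base_weight=float(count),
                weight_trend_per_round=trend,
                mean_age=mean_age,
                age_sd=13.0,
            )
        )
    return out


def default_config(sex="female", n_per_round=1000, seed=0, **kwargs) -> CohortConfig:
    return CohortConfig(sex=sex, archetypes=default_archetypes(sex), n_per_round=n_per_round, seed=seed, **kwargs)


def separated_archetypes(n_archetypes=4, separation=8.0, sd=1.0):
    """Synthetic archetypes with means separated by ``separation`` within-SDs.

    A test/benchmark library: archetype j offsets every feature by
    j * separation * sd from a physiological base profile, with spherical
    covariance sd^2.  Separation is in within-cluster SD units per feature.
    """
    base = np.array([150, 20, 0.40, 100, 55, 60, 1.0, 2.0, 4.5, 60], dtype=float)
    scale = np.array([1.0, 0.5, 0.005, 1.0, 0.8, 1.0, 0.03, 0.08, 0.1, 1.0])
    out = []
    for j in range(n_archetypes):
        mean = base + j * separation * sd * scale
        cov = np.diag((sd * scale) ** 2)
        out.append(
            ArchetypeSpec(
                name=f"archetype_{j}", mean_vector=mean, covariance=cov,
                base_weight=1.0, mean_age=45.0,
            )
        )
    return out


# ---------------------------------------------------------------------------
# generation

def generate_null_matrix(n, dim, seed=None):
    """n x dim iid standard normal draws (uncorrelated null data)."""
    if n <= 0 or dim <= 0:
        raise ValueError("n and dim must be positive")
    if n < dim:
        raise ValueError("need n >= dim")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, dim))


def _feature_valid(X):
    ok = np.ones(len(X), dtype=bool)
    for i, f in enumerate(FEATURES):
        lo, hi = FEATURE_BOUNDS[f]
        ok &= (X[:, i] >= lo) & (X[:, i] <= hi)
    i_sbp, i_dbp = FEATURES.index("sbp"), FEATURES.index("dbp")
    ok &= X[:, i_sbp] - X[:, i_dbp] >= MIN_PULSE_PRESSURE
    return ok


SCR_BOUNDS = (0.22, 13.0)  # back-derived creatinine kept inside its plausibility range


def _draw_truncated(rng, arch: ArchetypeSpec, ages, sex, max_rounds=200):
    n = len(ages)
    mean = np.asarray(arch.mean_vector, dtype=float)
    cov = np.asarray(arch.covariance, dtype=float)
    i_egfr = FEATURES.index("egfr")

    def valid(X):
        ok = _feature_valid(X)
        scr = invert_egfr(np.clip(X[:, i_egfr], 1e-6, None), ages, sex)
        return ok & (scr >= SCR_BOUNDS[0]) & (scr <= SCR_BOUNDS[1])

    X = rng.multivariate_normal(mean, cov, size=n)
    bad = ~valid(X)
    if bad.any() and cov.max() == 0:
        raise ValueError(f"{arch.name}: mean vector violates feature bounds; cannot truncate")
    tries = 0
    while bad.any():
        tries += 1
        if tries > max_rounds:
            raise RuntimeError(f"{arch.name}: truncation resampling did not converge")
        X[bad] = rng.multivariate_normal(mean, cov, size=int(bad.sum()))
        bad = ~valid(X)
    return X


def _mixture_weights(config: CohortConfig, round_index):
    logits = np.array(
        [np.log(max(a.base_weight, 1e-12)) + a.weight_trend_per_round * round_index
         for a in config.archetypes]
    )
    w = np.exp(logits - logits.max())
    return w / w.sum()


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_arch = len(config.archetypes)
    rows, labels, feats = [], [], []
    band_lows = np.array(AGE_BAND_EDGES)
    rid = 0
    for r_idx, (round_label, mid_year) in enumerate(config.rounds):
        n = config.n_per_round
        w = _mixture_weights(config, r_idx)
        # covariate effects shift per-person archetype log-odds
        cov_draws = {}
        logits = np.tile(np.log(w), (n, 1))
        for eff in config.covariate_effects:
            x = rng.random(n) < eff.prevalence
            cov_draws[eff.field] = x.astype(int)
            logits[:, eff.archetype] += np.log(eff.odds_ratio) * x
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(n)
        arch_idx = (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)
        arch_idx = np.clip(arch_idx, 0, n_arch - 1)

        X = np.empty((n, len(FEATURES)))
        ages = np.empty(n, dtype=int)
        for j, arch in enumerate(config.archetypes):
            mask = arch_idx == j
            m = int(mask.sum())
            if m == 0:
                continue
            bp = arch.age_band_probs()
            bands = rng.choice(len(bp), size=m, p=bp)
            within = rng.integers(0, 5, size=m)
            age = band_lows[bands] + within
            age[bands == len(band_lows) - 1] = 85 + rng.integers(0, 10, size=int((bands == len(band_lows) - 1).sum()))
            ages[mask] = age
            X[mask] = _draw_truncated(rng, arch, age, config.sex)

        df = pd.DataFrame(X, columns=FEATURES)
        df.insert(0, "id", [f"p{rid + i:07d}" for i in range(n)])
        rid += n
        df["sex"] = config.sex
        df["age"] = ages
        df["round"] = round_label
        df["mid_year"] = mid_year
        df["weight_sample"] = rng.lognormal(mean=0.0, sigma=config.weight_sigma, size=n)
        # back-derive raw fields so derived measures are functions of raws
        df["body_weight"] = df["bmi"] * (df["height"] / 100.0) ** 2
        df["waist"] = df["whtr"] * df["height"]
        df["tc"] = df["non_hdl"] + df["hdl"]
        df["scr"] = invert_egfr(df["egfr"].to_numpy(), ages, config.sex)
        noise = rng.normal(0.0, BP_READING_NOISE_SD, size=(n, 3, 2))
        for i in range(3):
            bias = BP_FIRST_READING_BIAS if i == 0 else 0.0
            df[f"sbp_{i + 1}"] = df["sbp"] + bias + noise[:, i, 0]
            df[f"dbp_{i + 1}"] = df["dbp"] + bias + noise[:, i, 1]
        for col, p in DEFAULT_COVARIATE_PROBS.items():
            df[col] = rng.choice(CATEGORICAL_LEVELS[col], size=n, p=p)
        for flag, p in DEFAULT_FLAG_PROBS.items():
            df[flag] = (rng.random(n) < p).astype(int)
        for fld, draws in cov_draws.items():
            df[fld] = draws
        # drop the latent summarized columns; cleaning re-derives them from raws
        latent = df[FEATURES].to_numpy().copy()
        df = df.drop(columns=["bmi", "whtr", "sbp", "dbp", "non_hdl", "egfr"])
        rows.append(df)
        labels.append(arch_idx)
        feats.append(latent)

    records = pd.concat(rows, ignore_index=True)
    cohort = SyntheticCohort(
        records=records,
        true_labels=np.concatenate(labels),
        features=np.vstack(feats),
        config=config,
    )
    if any(v > 0 for v in config.error_rates.values()):
        cohort = inject_artifacts(cohort, config.error_rates, seed=int(rng.integers(2**31)))
    return cohort


# ---------------------------------------------------------------------------
# artifact injection

def inject_artifacts(cohort: SyntheticCohort, error_rates, seed=None) -> SyntheticCohort:
    """Corrupt a flagged fraction of records; returns altered ids as ground truth.

    Rates (each in [0, 1], applied to disjoint record sets):

    - ``implausible``: one raw value pushed outside its plausibility range;
    - ``discordant``: the (SBP, DBP) pair moved >= 8 SDs along the minor axis
      of its bivariate (log SBP, DBP) distribution — each value individually
      plausible but the pair discordant (high SBP with very low DBP);
    - ``inconsistent``: BP readings set so summarized SBP <= DBP;
    - ``missing``: HbA1c deleted.
    """
    for key, rate in error_rates.items():
        if not 0 <= rate <= 1:
            raise ValueError(f"error rate {key} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    df = cohort.records.copy()
    n = len(df)
    order = rng.permutation(n)
    taken = 0
    chosen = {}
    for key in ("implausible", "discordant", "inconsistent", "missing"):
        m = int(round(error_rates.get(key, 0.0) * n))
        chosen[key] = order[taken : taken + m]
        taken += m

    sbp_cols = [f"sbp_{i}" for i in (1, 2, 3)]
    dbp_cols = [f"dbp_{i}" for i in (1, 2, 3)]

    idx = chosen["implausible"]
    if len(idx):
        fields = rng.choice(["height", "rhr", "hba1c"], size=len(idx))
        col_pos = {c: df.columns.get_loc(c) for c in ("height", "rhr", "hba1c")}
        bad_value = {"height": 400.0, "rhr": 260.0, "hba1c": 25.0}
        for i, fld in zip(idx, fields):
            df.iat[i, col_pos[fld]] = bad_value[fld]

    idx = chosen["discordant"]
    if len(idx):
        sbp = df[sbp_cols].to_numpy()[:, 1:].mean(axis=1)
        dbp = df[dbp_cols].to_numpy()[:, 1:].mean(axis=1)
        ok = np.isfinite(sbp) & np.isfinite(dbp) & (sbp > 0)
        pts = np.column_stack([np.log(sbp[ok]), dbp[ok]])
        mu = pts.mean(axis=0)
        sd = pts.std(axis=0, ddof=1)
        # SBP up / DBP down by ~5 marginal SDs each (capped at the plausibility
        # headroom): with non-negative SBP-DBP correlation the pair then sits
        # >= sqrt(50) ~ 7.1 SDs out, and in practice >= 8 since the discordant
        # direction opposes the correlation.
        a_max = (np.log(265.0) - mu[0]) / sd[0]
        b_max = (mu[1] - 33.0) / sd[1]
        for i in idx:
            a = a_max - 0.3 * rng.random()
            b = b_max - 0.3 * rng.random()
            new_sbp = float(np.exp(mu[0] + a * sd[0]))
            new_dbp = float(mu[1] - b * sd[1])
            for c in sbp_cols:
                df.iat[i, df.columns.get_loc(c)] = new_sbp + (BP_FIRST_READING_BIAS if c.endswith("_1") else 0.0)
            for c in dbp_cols:
                df.iat[i, df.columns.get_loc(c)] = new_dbp + (BP_FIRST_READING_BIAS if c.endswith("_1") else 0.0)

    idx = chosen["inconsistent"]
    if len(idx):
        for i in idx:
            for c in sbp_cols:
                df.iat[i, df.columns.get_loc(c)] = 100.0
            for c in dbp_cols:
                df.iat[i, df.columns.get_loc(c)] = 110.0

    idx = chosen["missing"]
    if len(idx):
        df.iloc[idx, df.columns.get_loc("hba1c")] = np.nan

    artifact_ids = {key: df["id"].to_numpy()[v] for key, v in chosen.items()}
    return SyntheticCohort(
        records=df,
        true_labels=cohort.true_labels,
        features=cohort.features,
        config=cohort.config,
        artifact_ids=artifact_ids,
    )
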