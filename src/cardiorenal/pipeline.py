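"""End-to-end pipeline: simulate (optional) -> clean -> derive -> cluster
per sex -> profile/name -> stability -> trends/predictors -> reports.

Every artifact directory carries a run manifest (config hash, seeds, stage
sizes) so a run can be reproduced exactly; all randomness flows from one
master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .cleaning import clean_cohort
from .clustering import cluster_profile_and_name, kmeans_lloyd, standardize
from .derived import feature_matrix
from .epi import prepare_weights, trend_table, weighted_prevalence_series, membership_predictors
from .stability import subsample_stability
from .synthetic import default_config, generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Defaults follow the analysis constants: k=10 clusters over the 5-12
    range, 50 random starts, 1,000 half-subsamples for stability, a 6-SD
    Mahalanobis cut, and the pre-specified trend periods."""

    seed: int = 0
    sexes: tuple = ("female", "male")
    k: int = 10
    k_range: tuple = (5, 12)
    n_starts: int = 50
    stability_B: int = 1000
    stability_fraction: float = 0.5
    stability_starts: int = 10
    mahalanobis_sd: float = 6.0
    egfr_version: str = "2009"
    egfr_race_coefficient: bool = False
    creatinine_slope: float = 1.0
    creatinine_intercept: float = 0.0
    min_age: int = 20
    plausibility_ranges: dict | None = None
    periods: list | None = None
    simulate: dict = field(default_factory=dict)  # e.g. {"n_per_round": 1000}

    @classmethod
    def from_dict(cls, d: dict):
        known = {f.name for f in cls.__dataclass_fields__.values()}
        return cls(**{k: v for k, v in d.items() if k in known})


def run_pipeline(config: PipelineConfig, out_dir, cohort: pd.DataFrame | None = None):
    """Run every stage and write artifacts under ``out_dir``.

    With no ``cohort`` given, a synthetic one is simulated per
    ``config.simulate``.  Returns a dict of in-memory results per sex.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(c.generate_state(1)[0] % (2**31))
             for name, c in zip(["simulate", "cluster", "stability"], ss.spawn(3))}

    if cohort is None:
        frames = []
        for i, sex in enumerate(config.sexes):
            cfg = default_config(sex=sex, seed=seeds["simulate"] + i,
                                 **{k: v for k, v in config.simulate.items() if k != "sex"})
            frames.append(generate_cohort(cfg).records)
        cohort = pd.concat(frames, ignore_index=True)
        cio.write_cohort(cohort, out / "cohort.csv")

    results = {}
    for sex in config.sexes:
        sub = cohort[cohort["sex"] == sex].reset_index(drop=True)
        if sub.empty:
            logger.warning("no records for sex %s; skipped", sex)
            continue
        clean, report = clean_cohort(
            sub,
            ranges=config.plausibility_ranges,
            sd_equiv=config.mahalanobis_sd,
            creatinine_slope=config.creatinine_slope,
            creatinine_intercept=config.creatinine_intercept,
            egfr_version=config.egfr_version,
            egfr_race_coefficient=config.egfr_race_coefficient,
            min_age=config.min_age,
        )
        clean = clean.reset_index(drop=True)
        X, _ = feature_matrix(clean)
        Z, params = standardize(X, sex=sex)
        model = kmeans_lloyd(Z, config.k, n_starts=config.n_starts, seed=seeds["cluster"])
        profile = cluster_profile_and_name(model.assignments, clean)
        stability = subsample_stability(
            Z, model, B=config.stability_B, fraction=config.stability_fraction,
            n_starts_sub=config.stability_starts, seed=seeds["stability"],
        )
        clean = clean.assign(
            cluster=model.assignments,
            cluster_name=[profile.names[c] for c in model.assignments],
        )
        scheme = prepare_weights(clean)
        trends = trend_table(clean, "cluster_name", scheme, periods=config.periods)
        prev_std = weighted_prevalence_series(clean, "cluster_name", scheme, standardized=True)
        prev_crude = weighted_prevalence_series(clean, "cluster_name", scheme, standardized=False)
        predictors = membership_predictors(clean, "cluster_name", scheme)

        sdir = out / sex
        sdir.mkdir(exist_ok=True)
        clean[["id", "cluster", "cluster_name"]].to_csv(sdir / "assignments.csv", index=False)
        cio.write_json(report.to_dict(), sdir / "cleaning_report.json")
        cio.write_json(
            {
                "k": model.k, "wcss": model.wcss, "seed": model.seed,
                "n_starts": model.n_starts,
                "standardization": {"mean": params.mean, "sd": params.sd},
                "centers": model.centers,
                "names": {str(c): n for c, n in profile.names.items()},
            },
            sdir / "model.json",
        )
        cio.write_json(stability.to_dict(), sdir / "stability.json")
        trends.to_csv(sdir / "trends.csv", index=False)
        prev_std.to_csv(sdir / "prevalence_age_standardized.csv")
        prev_crude.to_csv(sdir / "prevalence_crude.csv")
        pred_rows = []
        for c, pm in predictors.items():
            t = pm.table.reset_index(names="term")
            t.insert(0, "cluster", c)
            pred_rows.append(t)
        pd.concat(pred_rows, ignore_index=True).to_csv(sdir / "predictors.csv", index=False)
        results[sex] = {
            "clean": clean, "model": model, "profile": profile, "stability": stability,
            "trends": trends, "prevalence_standardized": prev_std,
            "prevalence_crude": prev_crude, "predictors": predictors, "report": report,
        }

    manifest = {
        "seed": config.seed, "stage_seeds": seeds,
        "config_hash": cio.config_hash(config.__dict__ | {"periods": config.periods or []}),
        "k": config.k, "n_starts": config.n_starts, "stability_B": config.stability_B,
        "n_records": int(len(cohort)),
    }
    cio.write_json(manifest, out / "manifest.json")
    return results
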