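"""Cluster stability: bootstrap Jaccard over half-subsamples, a null
calibration on uncorrelated normal data, and subperiod consistency.

The stability of each reference cluster is the average, over B subsamples of
a fraction of the data drawn without replacement, of the best Jaccard index
between the reference cluster (restricted to the subsample) and any cluster
of a re-clustering of the subsample.  Well-separated structure yields
averages near 1; k-means applied to a structureless isotropic Gaussian
yields unstable clusters, which calibrates the "no real structure" level of
the index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .clustering import (
    PhenotypeProfile,
    cluster_profile_and_name,
    kmeans_lloyd,
    jaccard_index,
    standardize,
)

logger = logging.getLogger(__name__)


@dataclass
class StabilityReport:
    per_cluster_mean: np.ndarray  # k
    replicate_values: np.ndarray  # B x k, matched Jaccard per replicate
    B: int
    fraction: float
    seed: int | None

    def to_dict(self):
        return {
            "per_cluster_mean": [float(v) for v in self.per_cluster_mean],
            "B": self.B,
            "fraction": self.fraction,
            "seed": self.seed,
        }


from .synthetic import generate_null_matrix  # noqa: F401  (re-export; defined with the generator)


def _replicate_jaccards(ref_sets, sub_ids, sub_labels, k, matching="max"):
    """Per reference cluster: Jaccard with its best-matching subsample cluster."""
    sub_id_set = set(sub_ids)
    ref_restricted = [s & sub_id_set for s in ref_sets]
    rep_labels = np.unique(sub_labels)
    rep_sets = [set(sub_ids[sub_labels == c]) for c in rep_labels]
    J = np.zeros((k, len(rep_sets)))
    for i, ra in enumerate(ref_restricted):
        for j, rb in enumerate(rep_sets):
            J[i, j] = jaccard_index(ra, rb)
    if matching == "max":
        return J.max(axis=1)
    ri, ci = linear_sum_assignment(-J)
    out = np.zeros(k)
    out[ri] = J[ri, ci]
    return out


def subsample_stability(
    Z,
    reference_model,
    B=1000,
    fraction=0.5,
    n_starts_sub=10,
    seed=None,
    matching="max",
    restandardize=False,
):
    """Average per-cluster Jaccard stability over B subsample re-clusterings.

    Each replicate draws floor(fraction * n) rows without replacement,
    re-runs k-means with the reference k, and records for each reference
    cluster the maximum Jaccard against any replicate cluster (or the
    globally matched Jaccard with ``matching='assignment'``).  Replicates
    use independent child seeds spawned from ``seed``.

    By default the subsample stays in the full-sample standardized space;
    ``restandardize`` re-centers and re-scales within each subsample.
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0]
    k = reference_model.k
    m = int(np.floor(fraction * n))
    if m < k:
        raise ValueError("subsample smaller than k")
    ids = np.arange(n)
    ref_sets = [set(ids[reference_model.assignments == c]) for c in range(k)]
    ss = np.random.SeedSequence(seed)
    values = np.zeros((B, k))
    for b, child in enumerate(ss.spawn(B)):
        rng = np.random.default_rng(child)
        sub_ids = rng.choice(n, size=m, replace=False)
        sub = Z[sub_ids]
        if restandardize:
            sub, _ = standardize(sub)
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        model = kmeans_lloyd(sub, k, n_starts=n_starts_sub, seed=rep_seed)
        values[b] = _replicate_jaccards(ref_sets, sub_ids, model.assignments, k, matching=matching)
    return StabilityReport(
        per_cluster_mean=values.mean(axis=0), replicate_values=values,
        B=B, fraction=fraction, seed=seed,
    )


def null_calibration(n, dim, k, B=50, seed=None, n_starts=10, n_starts_sub=10, fraction=0.5):
    """Stability of k-means clusters on structureless iid normal data.

    Generates an n x dim uncorrelated standard normal matrix, fits the
    reference clustering, and runs the subsample stability procedure.  On
    such data every cluster is an arbitrary partition of one Gaussian blob
    and its average Jaccard stays low, giving the calibration level against
    which real-structure stability is judged.
    """
    ss = np.random.SeedSequence(seed)
    s_data, s_fit, s_stab = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    X = generate_null_matrix(n, dim, seed=s_data)
    Z, _ = standardize(X)
    model = kmeans_lloyd(Z, k, n_starts=n_starts, seed=s_fit)
    return subsample_stability(
        Z, model, B=B, fraction=fraction, n_starts_sub=n_starts_sub, seed=s_stab
    )


def _positions_in(medians, pooled_df):
    """Risk-oriented percentile positions of cluster medians in a pooled sample."""
    from .clustering import _percentile_of
    from .schema import FEATURES, REVERSED_FEATURES

    out = np.zeros((len(medians), len(FEATURES)))
    for j, f in enumerate(FEATURES):
        vals = pooled_df[f].to_numpy()
        for i, m in enumerate(medians[f].to_numpy()):
            p = _percentile_of(vals, m)
            out[i, j] = 100.0 - p if f in REVERSED_FEATURES else p
    return out


def subperiod_consistency(
    df: pd.DataFrame,
    reference_profile: PhenotypeProfile,
    period_col,
    k,
    seed=None,
    n_starts=50,
    min_size_factor=10,
    match_threshold=12.0,
):
    """Recluster each subperiod and match its phenotypes to the pooled reference.

    Each period gets its own standardization and k-means fit; its clusters
    are profiled and matched one-to-one to the reference profile by the
    root-mean-square difference of risk-oriented percentile positions.
    Matches with RMS difference above ``match_threshold`` percentile points
    are reported as unmatched (an archetype absent from the period).
    """
    from .derived import feature_matrix

    results = {}
    ss = np.random.SeedSequence(seed)
    periods = list(pd.unique(df[period_col]))
    for period, child in zip(periods, ss.spawn(len(periods))):
        sub = df[df[period_col] == period]
        if len(sub) < min_size_factor * k:
            logger.warning("period %s below minimum size (%d); skipped", period, min_size_factor * k)
            continue
        X, _ = feature_matrix(sub)
        Z, _ = standardize(X)
        model = kmeans_lloyd(Z, k, n_starts=n_starts, seed=int(child.generate_state(1)[0] % (2**31)))
        profile = cluster_profile_and_name(model.assignments, sub.reset_index(drop=True))
        ref_pos = reference_profile.percentile_positions.to_numpy()
        # for matching, position the period cluster medians within the POOLED
        # distribution (the reference profile's scale): within-period ranks
        # would mask an archetype that is absent from the period
        per_pos = _positions_in(profile.medians, df)
        # RMS percentile-position distance, reference clusters x period clusters
        D = np.sqrt(
            ((ref_pos[:, None, :] - per_pos[None, :, :]) ** 2).mean(axis=2)
        )
        ri, ci = linear_sum_assignment(D)
        matches, unmatched = {}, []
        for i, j in zip(ri, ci):
            ref_c = reference_profile.cluster_ids[i]
            per_c = profile.cluster_ids[j]
            if D[i, j] <= match_threshold:
                matches[ref_c] = {
                    "period_cluster": int(per_c),
                    "period_name": profile.names[per_c],
                    "reference_name": reference_profile.names[ref_c],
                    "distance": float(D[i, j]),
                }
            else:
                unmatched.append(ref_c)
        results[period] = {"matches": matches, "unmatched": unmatched, "profile": profile}
    return results
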