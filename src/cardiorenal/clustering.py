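"""Sex-stratified standardized k-means phenotype discovery.

Participants are clustered on the standardized 10-feature risk-factor vector
with Lloyd's algorithm (Euclidean distance), taking the best of many random
starts to avoid local minima.  k is pre-specified; elbow (total
within-cluster sum of squares) and silhouette diagnostics over a k range
support its choice.  Clusters are profiled by per-feature medians positioned
as percentiles of the whole-sample distribution and named by a
priority-ordered deterministic rule set that formalizes the usual
inspection-based naming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import silhouette_samples

from .schema import FEATURES, REVERSED_FEATURES

logger = logging.getLogger(__name__)


@dataclass
class StandardizationParams:
    mean: np.ndarray
    sd: np.ndarray
    sex: str | None = None
    n: int = 0

    def apply(self, X):
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def invert(self, Z):
        return np.asarray(Z, dtype=float) * self.sd + self.mean


def standardize(X, params: StandardizationParams | None = None, sex=None, feature_names=None):
    """Center and scale each column to mean 0, SD 1.

    With ``params`` supplied the stored transform is applied unchanged
    (subsamples remain views of the full-sample space).
    """
    X = np.asarray(X, dtype=float)
    if params is None:
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to estimate standardization")
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            names = feature_names or FEATURES
            bad = [names[i] if i < len(names) else str(i) for i in np.flatnonzero(sd == 0)]
            raise ValueError(f"zero-variance feature(s): {bad}")
        params = StandardizationParams(mean=mean, sd=sd, sex=sex, n=X.shape[0])
    return params.apply(X), params


@dataclass
class ClusterModel:
    k: int
    centers: np.ndarray  # k x d, standardized space
    assignments: np.ndarray  # n, values in 0..k-1
    wcss: float
    n_starts: int
    seed: int | None
    iterations_per_start: list = field(default_factory=list)
    converged: list = field(default_factory=list)
    params: StandardizationParams | None = None


def _assign(X, centers):
    """Nearest-center assignment; exact ties go to the lowest center index."""
    d2 = cdist(X, centers, "sqeuclidean")
    return np.argmin(d2, axis=1), d2


def _lloyd_single(X, k, rng, max_iter, tol):
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_labels, d2 = _assign(X, centers)
        new_centers = np.empty_like(centers)
        for j in range(k):
            mask = new_labels == j
            if not mask.any():
                # reseed an emptied center at the point farthest from its center
                far = np.argmax(d2[np.arange(n), new_labels])
                new_centers[j] = X[far]
                new_labels[far] = j
            else:
                new_centers[j] = X[mask].mean(axis=0)
        shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        stable = np.array_equal(new_labels, labels)
        centers, labels = new_centers, new_labels
        if stable or shift < tol:
            converged = True
            break
    # final tightening: one assignment pass against final centers
    labels, d2 = _assign(X, centers)
    wcss = float(d2[np.arange(n), labels].sum())
    return centers, labels, wcss, it, converged


def kmeans_lloyd(X, k, n_starts=50, seed=None, max_iter=300, tol=1e-6):
    """Best-of-``n_starts`` Lloyd k-means with Euclidean distance.

    Initialization draws k distinct data points per start; empty clusters
    are reseeded at the point farthest from its center so k stays fixed.
    Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k < 1 or k >= n:
        raise ValueError("require 1 <= k < n")
    ss = np.random.SeedSequence(seed)
    best = None
    iters, conv = [], []
    for child in ss.spawn(n_starts):
        rng = np.random.default_rng(child)
        centers, labels, wcss, it, ok = _lloyd_single(X, k, rng, max_iter, tol)
        iters.append(it)
        conv.append(ok)
        if best is None or wcss < best[2]:
            best = (centers, labels, wcss)
    centers, labels, wcss = best
    # recompute centers as exact means of final assignments
    final_centers = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
    labels, d2 = _assign(X, final_centers)
    wcss = float(d2[np.arange(n), labels].sum())
    if len(np.unique(labels)) < k:
        # extremely degenerate data; fall back to the pre-tightened solution
        final_centers, labels = centers, best[1]
        wcss = best[2]
    return ClusterModel(
        k=k,
        centers=final_centers,
        assignments=labels,
        wcss=wcss,
        n_starts=n_starts,
        seed=seed,
        iterations_per_start=iters,
        converged=conv,
    )


@dataclass
class KDiagnostics:
    k_values: list
    wcss: list
    silhouette: list


def k_diagnostics(X, k_min=5, k_max=12, n_starts=50, seed=None):
    """Elbow (wcss) and mean silhouette width per k in [k_min, k_max]."""
    X = np.asarray(X, dtype=float)
    ks, wcss, sil = [], [], []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(k_max - k_min + 1)
    for k, child in zip(range(k_min, k_max + 1), children):
        model = kmeans_lloyd(X, k, n_starts=n_starts, seed=child.generate_state(1)[0] % (2**31))
        ks.append(k)
        wcss.append(model.wcss)
        if k == 1:
            sil.append(np.nan)
        else:
            sil.append(float(silhouette_samples(X, model.assignments).mean()))
    return KDiagnostics(k_values=ks, wcss=wcss, silhouette=sil)


# ---------------------------------------------------------------------------
# profiling and naming

#: priority-ordered naming rules on percentile positions of cluster medians.
#: Positions are risk-oriented: reversed for height, HDL and eGFR so that a
#: high position always means high risk.
#: The obesity threshold sits at P92 rather than P95 because a cluster that
#: holds ~10% of the sample caps its own median near P95; the hyperglycemia
#: cluster is small (~3%) so its median clears P95.  The low-risk rule spans
#: the modifiable factors (height excluded: a low-risk phenotype means
#: near-optimal levels, not tall stature).
DEFAULT_NAMING_RULES = [
    ("severe hyperglycemia", [("hba1c", ">=", 95)]),
    ("severe obesity", [("bmi", ">=", 92)]),
    ("high blood pressure", [("sbp", ">=", 90)]),
    ("high cholesterol", [("non_hdl", ">=", 90)]),
    ("high heart rate", [("rhr", ">=", 90)]),
    ("low DBP, low eGFR", [("dbp", "<=", 25), ("egfr_risk", ">=", 75)]),
    ("low risk", [("__all_risk__", "<=", 40)]),
    ("low BMI, high HDL", [("bmi", "<=", 25), ("hdl_risk", "<=", 25)]),
]


@dataclass
class PhenotypeProfile:
    cluster_ids: list
    medians: pd.DataFrame  # clusters x features, natural scale
    percentile_positions: pd.DataFrame  # clusters x features, risk-oriented [0,100]
    shares: pd.Series
    names: dict


def _percentile_of(values, x):
    """Percentile position (0-100) of x within the empirical distribution."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    below = np.searchsorted(values, x, side="left")
    equal = np.searchsorted(values, x, side="right") - below
    return 100.0 * (below + 0.5 * equal) / n


def cluster_profile_and_name(assignments, features_df: pd.DataFrame, naming_rules=None):
    """Per-cluster medians, risk-oriented percentile positions and names.

    Positions locate each cluster median within the whole-sample empirical
    distribution; the scale is reversed for height, HDL and eGFR because
    lower values mean higher risk.  The first matching rule in the priority
    list names the cluster; mid-risk clusters are split tall/short by the
    height median.
    """
    naming_rules = DEFAULT_NAMING_RULES if naming_rules is None else naming_rules
    assignments = np.asarray(assignments)
    if len(assignments) == 0:
        raise ValueError("no assignments: cannot profile empty clusters")
    clusters = np.unique(assignments)
    med_rows, pos_rows, shares = [], [], []
    n = len(assignments)
    for c in clusters:
        mask = assignments == c
        if not mask.any():
            raise ValueError(f"empty cluster {c}")
        med = features_df.loc[mask, FEATURES].median()
        pos = {}
        for f in FEATURES:
            p = _percentile_of(features_df[f].to_numpy(), med[f])
            pos[f] = 100.0 - p if f in REVERSED_FEATURES else p
        med_rows.append(med)
        pos_rows.append(pd.Series(pos))
        shares.append(mask.sum() / n)
    medians = pd.DataFrame(med_rows, index=clusters)
    positions = pd.DataFrame(pos_rows, index=clusters)
    shares = pd.Series(shares, index=clusters)

    sample_height_median = features_df["height"].median()
    names = {}
    for c in clusters:
        names[c] = _apply_naming_rules(
            positions.loc[c], medians.loc[c], sample_height_median, naming_rules
        )
    return PhenotypeProfile(
        cluster_ids=list(clusters), medians=medians, percentile_positions=positions,
        shares=shares, names=names,
    )


def _apply_naming_rules(pos, med, sample_height_median, rules):
    def value(key):
        if key == "egfr_risk":
            return pos["egfr"]  # already risk-oriented (reversed)
        if key == "hdl_risk":
            return pos["hdl"]
        return pos[key]

    risk_keys = [f for f in FEATURES if f != "height"]
    for name, conditions in rules:
        ok = True
        for key, op, thr in conditions:
            if key == "__all_risk__":
                vals = [pos[f] for f in risk_keys]
                v = max(vals)
            else:
                v = value(key)
            if op == ">=" and not v >= thr:
                ok = False
            elif op == "<=" and not v <= thr:
                ok = False
            if not ok:
                break
        if ok:
            return name
    return "mid risk tall" if med["height"] > sample_height_median else "mid risk short"


# ---------------------------------------------------------------------------
# correspondence, flow, distances

def match_clusters(assignments_a, assignments_b, ids_a=None, ids_b=None):
    """Optimal one-to-one cluster correspondence by total Jaccard.

    Returns ``(matching, jaccard_matrix)`` where ``matching`` maps cluster
    labels of ``a`` to labels of ``b`` (unmatched clusters absent) and the
    matrix is indexed by (a-labels, b-labels) over the shared id set.
    """
    a = pd.Series(np.asarray(assignments_a), index=ids_a if ids_a is not None else range(len(assignments_a)))
    b = pd.Series(np.asarray(assignments_b), index=ids_b if ids_b is not None else range(len(assignments_b)))
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("no overlapping ids between the two assignments")
    a, b = a.loc[shared], b.loc[shared]
    la, lb = np.unique(a), np.unique(b)
    J = np.zeros((len(la), len(lb)))
    for i, ca in enumerate(la):
        sa = set(shared[a == ca])
        for j, cb in enumerate(lb):
            sb = set(shared[b == cb])
            J[i, j] = jaccard_index(sa, sb)
    ri, ci = linear_sum_assignment(-J)
    matching = {la[i]: lb[j] for i, j in zip(ri, ci)}
    jdf = pd.DataFrame(J, index=la, columns=lb)
    return matching, jdf


def jaccard_index(set_a, set_b):
    """|A n B| / |A u B|; 0 when both sets are empty (convention)."""
    set_a, set_b = set(set_a), set(set_b)
    union = len(set_a | set_b)
    if union == 0:
        return 0.0
    return len(set_a & set_b) / union


def cluster_flow(assignments_a, assignments_b):
    """Contingency counts from clusters at one k to clusters at another k."""
    a = np.asarray(assignments_a)
    b = np.asarray(assignments_b)
    if len(a) != len(b):
        raise ValueError("assignments must cover the same participants")
    return pd.crosstab(pd.Series(a, name="from"), pd.Series(b, name="to"))


def intra_inter_distances(X, assignments, chunk=2000):
    """k x k matrix of average pairwise Euclidean distances.

    Diagonal: mean over all pairs within a cluster (0 for singletons, with a
    warning).  Off-diagonal: mean over all cross-cluster pairs.  Exact
    all-pairs averages, computed in chunks to bound memory.
    """
    X = np.asarray(X, dtype=float)
    assignments = np.asarray(assignments)
    labels = np.unique(assignments)
    k = len(labels)
    out = np.zeros((k, k))
    groups = {c: X[assignments == c] for c in labels}
    for i, ci in enumerate(labels):
        gi = groups[ci]
        if len(gi) == 1:
            logger.warning("singleton cluster %s: intra distance defined as 0", ci)
            out[i, i] = 0.0
        else:
            out[i, i] = pdist(gi).mean()
        for j in range(i + 1, k):
            gj = groups[labels[j]]
            total, count = 0.0, 0
            for start in range(0, len(gi), chunk):
                block = cdist(gi[start : start + chunk], gj)
                total += block.sum()
                count += block.size
            out[i, j] = out[j, i] = total / count
    return pd.DataFrame(out, index=labels, columns=labels)
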