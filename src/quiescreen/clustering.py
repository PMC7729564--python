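"""Phenotype assembly, Ward clustering and the Cubic Clustering Criterion.

Each strain is reduced to five phenotype features: extrapolated T_1/2 and
T_1/4 mortality times (days), G2% at day 0, and G0% after 1 and 7 days of
nitrogen starvation.  Features are z-scored (sample sd, n-1), clustered by
Ward's minimum-variance method on Euclidean distances, and the number of
clusters is chosen by the Cubic Clustering Criterion (CCC):

    CCC = ln[(1 - E(R²)) / (1 - R²)] * sqrt(n p*/2) / (0.001 + E(R²))^1.2

where R² = 1 - SS_within / SS_total for the k-cluster partition and E(R²)
is its expectation under a uniform-hypercube null whose edge lengths derive
from the singular values of the centered data (the classical SAS A-108
hypercube model).  p* is the effective dimensionality: the number of
singular values exceeding their mean.  The k maximizing CCC is chosen;
CCC values above ~2 conventionally indicate real structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind

FEATURES = ("t50", "t25", "g2_day0", "g0_day1", "g0_day7")


@dataclass(frozen=True)
class PhenotypeRecord:
    """The five clustering features for one strain."""

    strain_id: str
    t50: float
    t25: float
    g2_day0: float
    g0_day1: float
    g0_day7: float
    censored_t50: bool = False
    censored_t25: bool = False

    def feature_vector(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURES], dtype=float)


def build_phenotype_matrix(fit_table: pd.DataFrame, summaries: pd.DataFrame,
                           censored_policy: str = "horizon"
                           ) -> Tuple[List[PhenotypeRecord], Dict[str, str]]:
    """Assemble one PhenotypeRecord per strain with complete features.

    ``fit_table`` needs columns strain_id, t50, t25, t50_censored,
    t25_censored; ``summaries`` needs strain_id, day, g0_pct, g2_pct,
    qc_pass.  Censored threshold times enter at the horizon value with a
    flag (``censored_policy="horizon"``) or exclude the strain
    (``censored_policy="exclude"``).  Returns (records, exclusions) where
    exclusions maps strain_id -> reason.
    """
    if censored_policy not in ("horizon", "exclude"):
        raise ValueError("censored_policy must be 'horizon' or 'exclude'")
    records: List[PhenotypeRecord] = []
    exclusions: Dict[str, str] = {}
    summaries = summaries[summaries["qc_pass"].astype(bool)]
    by_strain = {s: g.set_index("day") for s, g in summaries.groupby("strain_id")}
    for row in fit_table.itertuples(index=False):
        sid = row.strain_id
        days = by_strain.get(sid)
        if days is None or not {0, 1, 7}.issubset(set(days.index)):
            exclusions[sid] = "incomplete features: missing day-0/1/7 summary"
            continue
        cens_t50 = bool(getattr(row, "t50_censored", False))
        cens_t25 = bool(getattr(row, "t25_censored", False))
        if censored_policy == "exclude" and (cens_t50 or cens_t25):
            exclusions[sid] = "censored threshold time"
            continue
        records.append(PhenotypeRecord(
            strain_id=sid, t50=float(row.t50), t25=float(row.t25),
            g2_day0=float(days.loc[0, "g2_pct"]),
            g0_day1=float(days.loc[1, "g0_pct"]),
            g0_day7=float(days.loc[7, "g0_pct"]),
            censored_t50=cens_t50, censored_t25=cens_t25))
    return records, exclusions


def records_to_matrix(records: Sequence[PhenotypeRecord]) -> np.ndarray:
    return np.vstack([r.feature_vector() for r in records])


def standardize_features(X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Z-score columns with sample sd (ddof=1).

    Zero-variance columns are left at 0 and flagged in the returned boolean
    array.  Standardizing an already-standardized matrix is a no-op.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 records")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero = sd < 1e-12
    Z = np.zeros_like(X)
    nz = ~zero
    Z[:, nz] = (X[:, nz] - mean[nz]) / sd[nz]
    return Z, zero


def ward_cluster(X: np.ndarray) -> np.ndarray:
    """Ward's minimum-variance agglomeration; returns a scipy linkage matrix.

    Merge heights are the Lance–Williams Ward distances (monotone
    nondecreasing); cutting the result at any k gives nested partitions.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need >= 2 records to cluster")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    return linkage(X, method="ward")


def cut_assignments(Z: np.ndarray, k: int) -> np.ndarray:
    """Cluster labels (1..k) from cutting the dendrogram into k groups."""
    return fcluster(Z, t=k, criterion="maxclust")


def partition_r2(X: np.ndarray, labels: np.ndarray) -> float:
    """R² = 1 - within-group SS / total SS for a partition."""
    X = np.asarray(X, dtype=float)
    total = float(np.sum((X - X.mean(axis=0)) ** 2))
    if total == 0.0:
        return 1.0
    within = 0.0
    for lab in np.unique(labels):
        sub = X[labels == lab]
        within += float(np.sum((sub - sub.mean(axis=0)) ** 2))
    return 1.0 - within / total


def effective_dimensionality(sv: np.ndarray, k: int) -> int:
    """p* for the hypercube null at a k-cluster partition (SAS A-108 rule).

    p* is the largest integer below k such that, with hypercube edge scale
    c = (prod(s_1..s_p*) / k)^(1/p*), the scaled singular value u_{p*} =
    s_{p*}/c is at least 1 — i.e. only dimensions wider than one cluster
    diameter count as clusterable.
    """
    s = np.asarray(sv, dtype=float)
    s = s[s > 1e-12]
    for pstar in range(min(s.size, k - 1), 1, -1):
        c = (float(np.prod(s[:pstar])) / k) ** (1.0 / pstar)
        if s[pstar - 1] / c >= 1.0:
            return pstar
    return 1


def _hypercube_expected_r2(sv: np.ndarray, n: int, k: int, pstar: int) -> float:
    """E(R²) under the uniform-hypercube null (SAS A-108 formulation).

    ``sv`` are the square roots of the eigenvalues of the covariance matrix
    of the centered data (i.e. singular values / sqrt(n-1)).
    """
    s = np.asarray(sv, dtype=float)
    s = s[s > 1e-12]
    pstar = min(max(pstar, 1), s.size)
    vstar = float(np.prod(s[:pstar]))
    c = (vstar / k) ** (1.0 / pstar)
    u = s / c
    num = float(np.sum(1.0 / (n + u[:pstar]))) + float(
        np.sum(u[pstar:] ** 2 / (n + u[pstar:])))
    den = float(np.sum(u ** 2))
    e = 1.0 - (num / den) * ((n - k) ** 2 / n) * (1.0 + 4.0 / n)
    return min(e, 1.0 - 1e-12)


@dataclass
class ClusterModel:
    """Ward merge sequence with CCC-chosen cluster number."""

    linkage: np.ndarray
    chosen_k: int
    assignments: np.ndarray
    ccc_by_k: Dict[int, float]
    pstar: int


def compute_ccc(X: np.ndarray, Z: np.ndarray,
                k_range: Sequence[int] = range(2, 16)
                ) -> Tuple[Dict[int, float], int]:
    """CCC for each candidate k on a fixed Ward dendrogram; returns
    (ccc_by_k, chosen_k) with chosen_k = argmax CCC.

    A partition with R² exactly 1 gets a +inf marker and is chosen.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    k_range = [k for k in k_range if 2 <= k <= n - 1]
    if not k_range:
        raise ValueError("k_range empty after restricting to [2, n-1]")
    centered = X - X.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False) / math.sqrt(n - 1)
    ccc: Dict[int, float] = {}
    for k in k_range:
        labels = cut_assignments(Z, k)
        r2 = partition_r2(X, labels)
        if r2 >= 1.0 - 1e-15:
            ccc[k] = float("inf")
            continue
        pstar = effective_dimensionality(sv, k)
        e_r2 = _hypercube_expected_r2(sv, n, k, pstar)
        ccc[k] = (math.log((1.0 - e_r2) / (1.0 - r2))
                  * math.sqrt(n * pstar / 2.0) / (0.001 + e_r2) ** 1.2)
    chosen = max(ccc, key=lambda k: (ccc[k], -k))
    return ccc, chosen


def cluster_phenotypes(records: Sequence[PhenotypeRecord],
                       k_range: Sequence[int] = range(2, 16),
                       standardize: bool = True) -> ClusterModel:
    """Standardize, Ward-cluster and CCC-select k for a set of records."""
    X = records_to_matrix(records)
    if standardize:
        X, _ = standardize_features(X)
    Z = ward_cluster(X)
    ccc, chosen = compute_ccc(X, Z, k_range)
    sv = np.linalg.svd(X - X.mean(axis=0), compute_uv=False) / math.sqrt(len(X) - 1)
    return ClusterModel(Z, chosen, cut_assignments(Z, chosen), ccc,
                        effective_dimensionality(sv, chosen))


def compare_to_control(control: Sequence[float], mutant: Sequence[float]
                       ) -> Tuple[float, float]:
    """Welch's two-sample t-test comparing a mutant to the control strain.

    Returns (t statistic, two-sided p).  Identical samples give t = 0,
    p = 1.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(mutant, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    if np.array_equal(a, b):
        return 0.0, 1.0
    res = ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
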