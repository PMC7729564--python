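"""Per-cluster protein-complex / GO-category enrichment statistics.

For a category with K members in a background universe of N analyzed genes,
and a cluster of n genes containing k category members:

* fold enrichment = (k/n) / (K/N)
* point probability p = P(X = k), hypergeometric
* tail probability  p = P(X >= k), the classical one-sided enrichment test

Both are reported.  Published complex-level screen statistics of this kind
print the point probability (e.g. Ino80: P(X=5 | N=684, K=10, n=108) ~ 1e-2)
rather than the tail, so the point column is the headline statistic here.
A Benjamini–Hochberg column over all (cluster, category) pairs is appended
as a supplementary diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd
from scipy.stats import false_discovery_control, hypergeom


@dataclass(frozen=True)
class CategoryCatalog:
    """Category -> member genes, with the analyzed background universe."""

    categories: Mapping[str, frozenset]
    background: frozenset

    def __post_init__(self):
        if len(self.background) < 1:
            raise ValueError("background universe must be nonempty")
        for name, members in self.categories.items():
            extra = set(members) - set(self.background)
            if extra:
                raise ValueError(
                    f"category {name!r} has members outside the background: "
                    f"{sorted(extra)[:5]}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]],
                   background: Iterable[str]) -> "CategoryCatalog":
        cats: Dict[str, Set[str]] = {}
        for cat, gene in pairs:
            cats.setdefault(cat, set()).add(gene)
        return cls({c: frozenset(g) for c, g in cats.items()},
                   frozenset(background))


def read_catalog(path, background_path=None) -> CategoryCatalog:
    """Read a catalog from two-column delimited text (category, gene) or
    GMT (name, description, genes...); the background is a one-column list,
    defaulting to the union of all category members."""
    path = Path(path)
    pairs: List[Tuple[str, str]] = []
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            pairs.extend((parts[0], g) for g in parts[2:] if g)
    else:
        df = pd.read_csv(path, sep=None, engine="python", header=None,
                         comment="#")
        if df.shape[1] < 2:
            raise ValueError("catalog needs two columns: category, gene_id")
        pairs = list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
    if background_path is not None:
        bg = [ln.strip() for ln in Path(background_path).read_text().splitlines()
              if ln.strip() and not ln.startswith("#")]
    else:
        bg = [g for _, g in pairs]
    return CategoryCatalog.from_pairs(pairs, bg)


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts: n={n}, K={K} with N={N}")
    if not (max(0, n + K - N) <= k <= min(n, K)):
        raise ValueError(
            f"inconsistent counts: k={k} outside [{max(0, n + K - N)}, "
            f"{min(n, K)}] for n={n}, K={K}, N={N}")


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): category concentration in the cluster vs background."""
    _check_counts(k, n, K, N)
    if n == 0 or K == 0:
        raise ValueError("fold enrichment undefined for n=0 or K=0")
    return (k / n) / (K / N)


def hypergeom_point(k: int, n: int, K: int, N: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n) (computed in log space)."""
    _check_counts(k, n, K, N)
    if max(0, n + K - N) == min(n, K):  # degenerate single-point support
        return 1.0
    return float(hypergeom.pmf(k, N, K, n))


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k); equals 1 at k = 0."""
    _check_counts(k, n, K, N)
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    cluster: int
    k: int
    n: int
    K: int
    N: int
    fold: float
    p_point: float
    p_tail: float


def cluster_enrichment(assignments: Mapping[str, int],
                       catalog: CategoryCatalog) -> pd.DataFrame:
    """Enrichment of every catalog category in every cluster.

    ``assignments`` maps gene id -> cluster label; all genes must belong to
    the catalog background.  One row per (cluster, category) pair with at
    least one member present (k >= 1), sorted by p_point, with a
    Benjamini–Hochberg column over all reported pairs.
    """
    missing = sorted(set(assignments) - set(catalog.background))
    if missing:
        raise ValueError(
            f"genes in assignments missing from background: {missing[:10]}")
    N = len(catalog.background)
    clusters: Dict[int, Set[str]] = {}
    for gene, lab in assignments.items():
        clusters.setdefault(int(lab), set()).add(gene)
    rows: List[EnrichmentResult] = []
    for lab, members in sorted(clusters.items()):
        n = len(members)
        for cat, cat_genes in catalog.categories.items():
            k = len(members & cat_genes)
            if k == 0:
                continue
            K = len(cat_genes)
            rows.append(EnrichmentResult(
                cat, lab, k, n, K, N, fold_enrichment(k, n, K, N),
                hypergeom_point(k, n, K, N), hypergeom_tail(k, n, K, N)))
    df = pd.DataFrame([r.__dict__ for r in rows],
                      columns=["category", "cluster", "k", "n", "K", "N",
                               "fold", "p_point", "p_tail"])
    if len(df):
        df["p_bh"] = false_discovery_control(df["p_tail"], method="bh")
        df = df.sort_values("p_point", kind="stable").reset_index(drop=True)
    else:
        df["p_bh"] = pd.Series(dtype=float)
    return df
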