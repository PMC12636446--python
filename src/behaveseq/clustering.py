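"""Temporal-pattern clustering of active genes.

Transform chain: hour-bin means -> log2(n+1) -> per-gene z-score ->
optional first-bin normalization.  Genes are agglomerated under Ward's
criterion on the correlation distance D = 2*(1 - r), with D treated as a
squared distance ("presquared" variant, the main profile pipeline) or with
1 - r treated as the metric (the marker-selection pipeline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .expression_io import ExpressionMatrix

__all__ = [
    "BinnedProfileSet",
    "ClusterResult",
    "RepresentativeSet",
    "bin_and_transform",
    "correlation_distance",
    "pairwise_correlation_distance",
    "hcluster",
    "cluster_means",
    "representative_genes",
    "PRESETS",
]

#: Presets mirroring the two clustering pipelines: hour-binned z-scored
#: profiles with presquared Ward (k=20), and per-sample log2 profiles with
#: a correlation metric (k=30) for marker selection.
PRESETS = {
    "profiles": {"variant": "presquared-ward", "k": 20, "first_bin_norm": True},
    "markers": {"variant": "correlation-ward", "k": 30, "first_bin_norm": False},
}


@dataclass
class BinnedProfileSet:
    """Gene x time-bin matrix with the transform provenance."""

    values: pd.DataFrame  # genes x bin index
    bin_edges_min: np.ndarray
    log: list[str] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def bin_and_transform(
    matrix: ExpressionMatrix | pd.DataFrame,
    ages_since_l4: pd.Series,
    bin_min: float = 60.0,
    first_bin_norm: bool = True,
) -> BinnedProfileSet:
    """Per-gene hour-bin means, log2(n+1), z-score, optional first-bin shift.

    Bins are half-open ``[k*bin_min, (k+1)*bin_min)`` from stage onset.
    Zero-variance genes at the z-score step become all-zero rows (kept,
    with a warning) so gene accounting is preserved.
    """
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    a = ages_since_l4.loc[vals.columns].to_numpy(float)
    bins = np.floor(a / bin_min).astype(int)
    uniq = np.unique(bins)
    edges = np.concatenate([uniq * bin_min, [(uniq[-1] + 1) * bin_min]])

    binned = np.column_stack(
        [vals.to_numpy(float)[:, bins == b].mean(axis=1) for b in uniq]
    )
    logv = np.log2(binned + 1.0)
    mu = logv.mean(axis=1, keepdims=True)
    sd = logv.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s) set to all-zero profiles")
    z = np.where(flat[:, None], 0.0, (logv - mu) / np.where(sd > 0, sd, 1.0))
    log = ["bin_mean", "log2(n+1)", "zscore"]
    if first_bin_norm:
        z = z - z[:, [0]]
        log.append("first_bin_norm")
    return BinnedProfileSet(
        values=pd.DataFrame(z, index=vals.index, columns=uniq),
        bin_edges_min=edges,
        log=log,
    )


# ---------------------------------------------------------------------------
# distance


def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """D = 2*(1 - Pearson r); zero-variance input gives r=0 (D=2) with a warning."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0 or b.std() == 0:
        warnings.warn("zero-variance profile in correlation_distance; treating r as 0")
        return 2.0
    r = float(np.corrcoef(a, b)[0, 1])
    return 2.0 * (1.0 - r)


def pairwise_correlation_distance(profiles: np.ndarray) -> np.ndarray:
    """Condensed matrix of D = 2*(1-r) over profile rows (zero-variance rows -> r=0)."""
    x = np.asarray(profiles, float)
    sd = x.std(axis=1)
    flat = sd == 0
    xz = np.where(
        flat[:, None], 0.0, (x - x.mean(1, keepdims=True)) / np.where(sd > 0, sd, 1.0)[:, None]
    )
    r = xz @ xz.T / x.shape[1]
    np.fill_diagonal(r, 1.0)
    d = 2.0 * (1.0 - np.clip(r, -1.0, 1.0))
    np.fill_diagonal(d, 0.0)
    return squareform(d, checks=False)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    k: int
    labels: pd.Series  # gene -> 1..k
    linkage: np.ndarray
    profiles: pd.DataFrame

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def members(self, cluster: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster])


def hcluster(
    profiles: BinnedProfileSet | pd.DataFrame,
    k: int,
    variant: str = "presquared-ward",
) -> ClusterResult:
    """Ward agglomeration on correlation distances, cut into ``k`` clusters.

    ``presquared-ward`` treats D = 2*(1-r) values as already-squared
    distances (scipy's Ward squares its input, so sqrt(D) is passed);
    ``correlation-ward`` treats 1-r as the metric.
    """
    vals = profiles.values if isinstance(profiles, BinnedProfileSet) else profiles
    n = vals.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside [1, {n}]")
    d = pairwise_correlation_distance(vals.to_numpy(float))
    if variant == "presquared-ward":
        y = np.sqrt(d)
    elif variant == "correlation-ward":
        y = d / 2.0  # 1 - r
    else:
        raise ValueError(f"unknown variant {variant!r}")
    Z = hierarchy.linkage(y, method="ward")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        k=k,
        labels=pd.Series(labels, index=vals.index, name="cluster"),
        linkage=Z,
        profiles=vals.copy() if isinstance(vals, pd.DataFrame) else pd.DataFrame(vals),
    )


def ward_merge_order(condensed_sq: np.ndarray, n: int) -> list[tuple[int, int]]:
    """Merge order of Ward agglomeration on presquared distances.

    Reference implementation of the Lance-Williams recurrence on squared
    distances; used as an oracle target.  Returns the merged pair of
    current-cluster representative indices (original leaf labels per scipy
    convention: new clusters get indices n, n+1, ...).
    """
    d2 = squareform(condensed_sq).astype(float)
    active = {i: (i, 1) for i in range(n)}  # slot -> (scipy label, size)
    dist = {frozenset((i, j)): d2[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int]] = []
    next_label = n
    slots = list(range(n))
    while len(slots) > 1:
        best = min(
            (
                (dist[frozenset((slots[a], slots[b]))], slots[a], slots[b])
                for a in range(len(slots))
                for b in range(a + 1, len(slots))
            ),
            key=lambda t: (t[0], min(active[t[1]][0], active[t[2]][0])),
        )
        _, i, j = best
        li, ni = active[i]
        lj, nj = active[j]
        merges.append((min(li, lj), max(li, lj)))
        dij = dist[frozenset((i, j))]
        for kslot in slots:
            if kslot in (i, j):
                continue
            nk = active[kslot][1]
            dik = dist[frozenset((i, kslot))]
            djk = dist[frozenset((j, kslot))]
            new = ((ni + nk) * dik + (nj + nk) * djk - nk * dij) / (ni + nj + nk)
            dist[frozenset((i, kslot))] = new
        active[i] = (next_label, ni + nj)
        next_label += 1
        slots.remove(j)
    return merges


# ---------------------------------------------------------------------------
# summaries


def cluster_means(
    result: ClusterResult, profiles: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Elementwise mean and SD trajectory of each cluster's member rows."""
    vals = result.profiles if profiles is None else profiles
    grouped = vals.groupby(result.labels)
    return grouped.mean(), grouped.std(ddof=0)


@dataclass
class RepresentativeSet:
    """Per cluster: the member gene most correlated with the cluster mean."""

    table: pd.DataFrame  # columns: cluster, gene_id, r

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])


def representative_genes(
    result: ClusterResult, profiles: pd.DataFrame | None = None
) -> RepresentativeSet:
    """Pick each cluster's highest-r member; ties go to the smaller gene id."""
    vals = result.profiles if profiles is None else profiles
    rows = []
    for c in sorted(result.labels.unique()):
        members = result.members(c)
        sub = vals.loc[members].to_numpy(float)
        mean = sub.mean(axis=0)
        if len(members) == 1:
            rows.append({"cluster": c, "gene_id": members[0], "r": 1.0})
            continue
        msd = mean.std()
        rs = np.zeros(len(members))
        for i, row in enumerate(sub):
            if row.std() == 0 or msd == 0:
                rs[i] = 0.0
            else:
                rs[i] = np.corrcoef(row, mean)[0, 1]
        order = sorted(range(len(members)), key=lambda i: (-round(rs[i], 12), members[i]))
        best = order[0]
        rows.append({"cluster": c, "gene_id": members[best], "r": float(rs[best])})
    return RepresentativeSet(pd.DataFrame(rows))
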