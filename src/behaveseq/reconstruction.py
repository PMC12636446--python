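"""Trajectory reconstruction from age-sorted single-animal profiles.

Quantifies how tightly expression is locked to developmental time:
pairwise correlation vs age gap, close-vs-far pair comparison (KS),
alignment-coordinate comparison, sliding-window trajectory smoothing, 2-D
embedding, artificial hourly pooling and reference comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE

from .expression_io import ExpressionMatrix

__all__ = [
    "GapCorrelationCurve",
    "SmoothedTrajectory",
    "PooledMatrix",
    "default_gap_edges",
    "pairwise_gap_correlations",
    "compare_gap_groups",
    "compare_alignments",
    "smooth_trajectory",
    "embed_samples",
    "artificial_pool",
    "compare_to_reference",
]


def default_gap_edges(max_gap: float = 600.0, step: float = 5.0) -> np.ndarray:
    """Half-open gap-bin edges every ``step`` minutes, first bin [0, step)."""
    return np.arange(0.0, max_gap + step, step)


def _prepare_values(matrix: ExpressionMatrix | pd.DataFrame, log_transform: bool) -> pd.DataFrame:
    vals = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    return np.log2(vals + 1.0) if log_transform else vals


@dataclass
class GapCorrelationCurve:
    """Mean pairwise Pearson r per |age-gap| bin."""

    edges: np.ndarray
    mean_r: np.ndarray
    sem_r: np.ndarray
    n_pairs: np.ndarray
    pair_gaps: np.ndarray = field(repr=False)
    pair_r: np.ndarray = field(repr=False)

    @property
    def total_pairs(self) -> int:
        return int(self.n_pairs.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gap_lo_min": self.edges[:-1],
                "gap_hi_min": self.edges[1:],
                "mean_r": self.mean_r,
                "sem_r": self.sem_r,
                "n_pairs": self.n_pairs,
            }
        )


def _pair_correlations(values: pd.DataFrame, ages: pd.Series):
    """Pearson r across genes and |age gap| for every unordered sample pair."""
    ages = ages.loc[values.columns]
    x = values.to_numpy(float)
    sd = x.std(axis=0)
    # tolerance absorbs float error when a profile is constant but its
    # accumulated mean differs from the value by an ulp
    ok = sd > 1e-12 * np.maximum(1.0, np.abs(x).max(axis=0))
    if not ok.all():
        warnings.warn(
            f"excluding {int((~ok).sum())} constant-profile sample(s) from pair correlations"
        )
        x = x[:, ok]
    a = ages.to_numpy(float)[ok]
    r = np.corrcoef(x, rowvar=False)
    iu, ju = np.triu_indices(x.shape[1], k=1)
    return np.abs(a[iu] - a[ju]), r[iu, ju]


def pairwise_gap_correlations(
    matrix: ExpressionMatrix | pd.DataFrame,
    ages: pd.Series,
    gap_edges: np.ndarray | None = None,
    log_transform: bool = True,
) -> GapCorrelationCurve:
    """Bin every unordered sample pair's Pearson r by its age gap.

    Bins are half-open ``[lo, hi)`` except the last, which includes its
    upper edge so that pair accounting is exact.
    """
    values = _prepare_values(matrix, log_transform)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if gap_edges is None:
        gap_edges = default_gap_edges(float(np.ptp(ages.to_numpy())))
    gap_edges = np.asarray(gap_edges, dtype=float)

    gaps, r = _pair_correlations(values, ages)
    idx = np.digitize(gaps, gap_edges) - 1
    idx[gaps == gap_edges[-1]] = len(gap_edges) - 2  # close the last bin
    nbin = len(gap_edges) - 1
    mean_r = np.full(nbin, np.nan)
    sem_r = np.full(nbin, np.nan)
    n_pairs = np.zeros(nbin, dtype=int)
    for b in range(nbin):
        sel = idx == b
        n = int(sel.sum())
        n_pairs[b] = n
        if n:
            mean_r[b] = r[sel].mean()
            sem_r[b] = r[sel].std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    return GapCorrelationCurve(gap_edges, mean_r, sem_r, n_pairs, gaps, r)


def compare_gap_groups(
    curve: GapCorrelationCurve, cutoff_min: float = 5.0
) -> tuple[float, float]:
    """Two-sample KS between close-pair (<= cutoff) and far-pair r values."""
    close = curve.pair_r[curve.pair_gaps <= cutoff_min]
    far = curve.pair_r[curve.pair_gaps > cutoff_min]
    if len(close) == 0 or len(far) == 0:
        raise ValueError("both gap groups must be non-empty")
    if min(len(close), len(far)) < 5:
        warnings.warn("fewer than 5 pairs in a gap group; KS test is underpowered")
    res = stats.ks_2samp(close, far)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AlignmentComparison:
    mean_r_l4: float
    mean_r_hatch: float
    r_close_l4: np.ndarray
    r_close_hatch: np.ndarray

    @property
    def advantage(self) -> float:
        return self.mean_r_l4 - self.mean_r_hatch


def compare_alignments(
    matrix: ExpressionMatrix | pd.DataFrame,
    ages_l4: pd.Series,
    ages_hatch: pd.Series,
    cutoff_min: float = 5.0,
    log_transform: bool = True,
) -> AlignmentComparison:
    """Mean close-pair r under stage-relative vs hatch-relative alignment."""
    values = _prepare_values(matrix, log_transform)
    gaps_l4, r = _pair_correlations(values, ages_l4)
    gaps_h, _ = _pair_correlations(values, ages_hatch)
    close_l4 = r[gaps_l4 <= cutoff_min]
    close_h = r[gaps_h <= cutoff_min]
    if len(close_l4) == 0 or len(close_h) == 0:
        raise ValueError("no close pairs under one of the alignments")
    return AlignmentComparison(
        mean_r_l4=float(close_l4.mean()),
        mean_r_hatch=float(close_h.mean()),
        r_close_l4=close_l4,
        r_close_hatch=close_h,
    )


# ---------------------------------------------------------------------------
# smoothing


@dataclass
class SmoothedTrajectory:
    gene_id: str
    times_min: np.ndarray
    values: np.ndarray  # NaN where a window is empty
    window_h: float
    step_h: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_min": self.times_min, self.gene_id or "value": self.values}
        )


def smooth_trajectory(
    gene_values: np.ndarray | pd.Series,
    ages: np.ndarray | pd.Series,
    window_h: float = 1.45,
    step_h: float = 0.17,
    gene_id: str = "",
) -> SmoothedTrajectory:
    """Sliding-window (boxcar) mean on a fixed grid anchored at age 0.

    The value at grid time ``t`` averages the samples with
    ``|age - t| <= window_h/2`` (hours); empty windows are NaN, never
    interpolated.
    """
    v = np.asarray(gene_values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if len(v) != len(a) or len(v) == 0:
        raise ValueError("values and ages must be equal-length and non-empty")
    grid = np.arange(0.0, a.max() / 60.0 + step_h / 2, step_h) * 60.0
    half = window_h * 30.0  # minutes
    out = np.full(len(grid), np.nan)
    for i, t in enumerate(grid):
        sel = np.abs(a - t) <= half
        if sel.any():
            out[i] = v[sel].mean()
    if np.all(np.isnan(out)):
        raise ValueError("no sample falls inside any smoothing window")
    return SmoothedTrajectory(gene_id, grid, out, window_h, step_h)


# ---------------------------------------------------------------------------
# embedding


def embed_samples(
    matrix: ExpressionMatrix | pd.DataFrame,
    ages: pd.Series | None = None,
    perplexity: float = 40.0,
    learning_rate: float = 110.0,
    seed: int = 0,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Seeded 2-D t-SNE of samples; optional 5-NN age-gap quality column.

    Returns a frame (sample_id, dim1, dim2[, age, knn_age_gap]).  When
    fewer than ``3 * perplexity`` samples are available the perplexity is
    reduced with a warning.
    """
    values = _prepare_values(matrix, log_transform)
    n = values.shape[1]
    if n <= 3:
        raise ValueError("need more than 3 samples to embed")
    if n <= 3 * perplexity:
        new_p = max(2.0, (n - 1) / 3.0)
        warnings.warn(
            f"n_samples={n} <= 3*perplexity; reducing perplexity {perplexity} -> {new_p:.1f}"
        )
        perplexity = new_p
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        learning_rate=learning_rate,
        init="pca",
        random_state=seed,
    ).fit_transform(values.to_numpy(float).T)
    out = pd.DataFrame(
        {"sample_id": values.columns, "dim1": coords[:, 0], "dim2": coords[:, 1]}
    )
    if ages is not None:
        a = ages.loc[values.columns].to_numpy(float)
        out["age_min"] = a
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        k = min(5, n - 1)
        nn = np.argsort(d, axis=1)[:, :k]
        out["knn_age_gap"] = np.abs(a[nn] - a[:, None]).mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# artificial pooling and reference comparison


@dataclass
class PooledMatrix:
    """Gene x hourly-bin means (+-30 min window on the hatch-age axis)."""

    values: pd.DataFrame  # genes x bin centers (hours); NaN = empty bin
    bin_centers_h: np.ndarray
    n_per_bin: np.ndarray
    half_width_min: float = 30.0

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers_h)


def artificial_pool(
    matrix: ExpressionMatrix | pd.DataFrame,
    ages_since_hatch: pd.Series,
    half_width_min: float = 30.0,
    log_transform: bool = False,
) -> PooledMatrix:
    """Average single-animal profiles within +-30 min of each hourly center.

    Emulates conventional hourly population pooling.  Bin centers are the
    integer hours covered by the observed age range.
    """
    values = _prepare_values(matrix, log_transform)
    a = ages_since_hatch.loc[values.columns].to_numpy(float)
    if np.ptp(a) < 60.0:
        raise ValueError("ages must span at least 2 hourly bin centers")
    centers = np.arange(np.ceil(a.min() / 60.0), np.floor(a.max() / 60.0) + 1)
    cols, counts = [], []
    for c in centers:
        sel = np.abs(a - c * 60.0) <= half_width_min
        counts.append(int(sel.sum()))
        cols.append(
            values.loc[:, sel].mean(axis=1) if sel.any() else pd.Series(np.nan, index=values.index)
        )
    pooled = pd.concat(cols, axis=1)
    pooled.columns = centers
    return PooledMatrix(pooled, centers, np.array(counts), half_width_min)


@dataclass
class ReferenceComparison:
    gene_r: pd.Series
    shuffled_r: pd.Series
    t_statistic: float
    p_value: float
    n_bins_used: int

    @property
    def mean_r(self) -> float:
        return float(self.gene_r.mean())

    @property
    def mean_shuffled_r(self) -> float:
        return float(self.shuffled_r.mean())


def compare_to_reference(
    pooled: PooledMatrix,
    reference: PooledMatrix,
    hour_offset: float = 0.0,
    seed: int = 0,
) -> ReferenceComparison:
    """Gene-wise r between matched hourly profiles vs a shuffled-bin control.

    Bin center ``h`` in ``pooled`` is matched to ``h - hour_offset`` in the
    reference.  The control independently permutes each reference gene's
    bins; significance is an unpaired t-test between the two r sets.
    """
    shared = pooled.values.index.intersection(reference.values.index)
    if len(shared) < 2:
        raise ValueError("need at least 2 shared genes")
    ref_centers = set(reference.bin_centers_h.tolist())
    match = [
        (h, h - hour_offset)
        for h in pooled.bin_centers_h
        if (h - hour_offset) in ref_centers
    ]
    if len(match) < 3:
        raise ValueError("need at least 3 shared bins after offset alignment")
    ours = pooled.values.loc[shared, [m[0] for m in match]].to_numpy(float)
    theirs = reference.values.loc[shared, [m[1] for m in match]].to_numpy(float)
    keep = ~(np.isnan(ours).any(axis=1) | np.isnan(theirs).any(axis=1))
    const = (np.nanstd(ours, axis=1) == 0) | (np.nanstd(theirs, axis=1) == 0)
    if (keep & const).any():
        warnings.warn(
            f"excluding {int((keep & const).sum())} constant gene profile(s) from reference comparison"
        )
    keep &= ~const
    ours, theirs = ours[keep], theirs[keep]
    genes = shared[keep]

    rng = np.random.default_rng(seed)
    shuffled = np.array([rng.permutation(row) for row in theirs])

    def rowwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        az = (a - a.mean(1, keepdims=True)) / a.std(1, keepdims=True)
        bs = b.std(1, keepdims=True)
        bz = np.where(bs > 0, (b - b.mean(1, keepdims=True)) / np.where(bs > 0, bs, 1.0), 0.0)
        return (az * bz).mean(axis=1)

    r_real = rowwise_r(ours, theirs)
    r_ctrl = rowwise_r(ours, shuffled)
    t, p = stats.ttest_ind(r_real, r_ctrl, equal_var=False)
    return ReferenceComparison(
        gene_r=pd.Series(r_real, index=genes),
        shuffled_r=pd.Series(r_ctrl, index=genes),
        t_statistic=float(t),
        p_value=float(p),
        n_bins_used=len(match),
    )
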