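"""Per-time-window differential expression between two genotypes.

Each 1-hour developmental window (stage-relative age) is tested
independently: per-gene two-sided Mann-Whitney U with Benjamini-Hochberg
correction across genes within the window, plus pseudocounted log2 fold
changes and persistence counting across windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import ExpressionMatrix

__all__ = [
    "BinwiseDEResult",
    "PersistenceSummary",
    "binwise_fold_change",
    "binwise_test",
    "window_persistence",
]


def _bin_assign(ages: pd.Series, bin_min: float) -> pd.Series:
    return np.floor(ages / bin_min).astype(int)


def _values(matrix: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, ExpressionMatrix) else matrix


@dataclass
class BinwiseDEResult:
    """Long-format per-gene per-bin test results."""

    table: pd.DataFrame  # gene, bin, log2fc, u_stat, p, q, n_cond, n_ref
    alpha: float
    bin_min: float

    @property
    def bins(self) -> list[int]:
        return sorted(self.table["bin"].unique())


def binwise_fold_change(
    cond: ExpressionMatrix | pd.DataFrame,
    ref: ExpressionMatrix | pd.DataFrame,
    ages_cond: pd.Series,
    ages_ref: pd.Series,
    bin_min: float = 60.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2((mean_cond + pc) / (mean_ref + pc)) per shared gene per hour bin.

    Bins empty in either cohort are reported NaN.  Returns genes x bins.
    """
    cv, rv = _values(cond), _values(ref)
    shared = cv.index.intersection(rv.index)
    if len(shared) == 0:
        raise ValueError("no shared genes")
    bc = _bin_assign(ages_cond.loc[cv.columns], bin_min)
    br = _bin_assign(ages_ref.loc[rv.columns], bin_min)
    bins = sorted(set(bc.unique()) | set(br.unique()))
    out = pd.DataFrame(np.nan, index=shared, columns=bins)
    for b in bins:
        cs = cv.loc[shared, bc.index[bc == b]]
        rs = rv.loc[shared, br.index[br == b]]
        if cs.shape[1] == 0 or rs.shape[1] == 0:
            continue
        out[b] = np.log2(
            (cs.mean(axis=1) + pseudocount) / (rs.mean(axis=1) + pseudocount)
        )
    return out


def binwise_test(
    cond: ExpressionMatrix | pd.DataFrame,
    ref: ExpressionMatrix | pd.DataFrame,
    ages_cond: pd.Series,
    ages_ref: pd.Series,
    bin_min: float = 60.0,
    alpha: float = 0.01,
    min_per_group: int = 3,
    pseudocount: float = 1.0,
) -> BinwiseDEResult:
    """Two-sided Mann-Whitney per gene, BH-corrected within each hour bin.

    Bins with fewer than ``min_per_group`` samples in either cohort are
    skipped with a warning.  All-tied gene values give p = 1.
    """
    cv, rv = _values(cond), _values(ref)
    shared = cv.index.intersection(rv.index)
    if len(shared) == 0:
        raise ValueError("no shared genes")
    bc = _bin_assign(ages_cond.loc[cv.columns], bin_min)
    br = _bin_assign(ages_ref.loc[rv.columns], bin_min)
    fc = binwise_fold_change(cond, ref, ages_cond, ages_ref, bin_min, pseudocount)

    rows = []
    for b in sorted(set(bc.unique()) & set(br.unique())):
        x = cv.loc[shared, bc.index[bc == b]].to_numpy(float)
        y = rv.loc[shared, br.index[br == b]].to_numpy(float)
        if x.shape[1] < min_per_group or y.shape[1] < min_per_group:
            warnings.warn(
                f"bin {b}: {x.shape[1]} vs {y.shape[1]} samples < {min_per_group}; skipped"
            )
            continue
        u = np.empty(len(shared))
        p = np.empty(len(shared))
        for gi in range(len(shared)):
            xv, yv = x[gi], y[gi]
            if np.ptp(np.concatenate([xv, yv])) == 0:
                u[gi], p[gi] = len(xv) * len(yv) / 2.0, 1.0
            else:
                res = stats.mannwhitneyu(xv, yv, alternative="two-sided")
                u[gi], p[gi] = res.statistic, res.pvalue
        q = multipletests(p, method="fdr_bh")[1]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": shared,
                    "bin": b,
                    "log2fc": fc.loc[shared, b].to_numpy(),
                    "u_stat": u,
                    "p": p,
                    "q": q,
                    "n_cond": x.shape[1],
                    "n_ref": y.shape[1],
                }
            )
        )
    if not rows:
        raise ValueError("no bin had enough samples in both cohorts")
    return BinwiseDEResult(pd.concat(rows, ignore_index=True), alpha=alpha, bin_min=bin_min)


@dataclass
class PersistenceSummary:
    """Genes significant in >= k windows, for every k."""

    counts: pd.Series  # index k = 1..n_bins
    half_or_more_genes: list[str]
    alpha: float
    use_adjusted: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.counts.index, "n_genes": self.counts.to_numpy()})


def window_persistence(
    result: BinwiseDEResult, alpha: float = 0.01, use_adjusted: bool = True
) -> PersistenceSummary:
    """Count genes significant in at least k bins, for k = 1..n_bins.

    Also emits the list of genes significant in at least half of the
    tested windows.  ``use_adjusted`` selects BH q-values (default) or raw
    p-values for the threshold.
    """
    col = "q" if use_adjusted else "p"
    sig = result.table[result.table[col] < alpha]
    n_bins = result.table["bin"].nunique()
    per_gene = sig.groupby("gene_id")["bin"].nunique()
    counts = pd.Series(
        [(per_gene >= k).sum() for k in range(1, n_bins + 1)],
        index=pd.RangeIndex(1, n_bins + 1, name="k"),
        dtype=int,
    )
    half = int(np.ceil(n_bins / 2))
    return PersistenceSummary(
        counts=counts,
        half_or_more_genes=sorted(per_gene.index[per_gene >= half]),
        alpha=alpha,
        use_adjusted=use_adjusted,
    )
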