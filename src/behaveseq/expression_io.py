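"""Count-matrix ingest, RPM normalization, filtering and age joining."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior_staging import DevelopmentalTimeline

__all__ = [
    "ExpressionMatrix",
    "SampleTable",
    "rpm_normalize",
    "drop_dead_genes",
    "active_gene_filter",
    "attach_ages",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix with a unit flag and a transform log.

    ``values`` is a pandas DataFrame indexed by gene id with sample ids as
    columns; ``unit`` is ``"counts"`` or ``"rpm"``.
    """

    values: pd.DataFrame
    unit: str = "counts"
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "rpm"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.columns.is_unique:
            raise ValueError("sample ids must be unique")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = set(gene_ids) - set(self.values.index)
        if missing:
            raise KeyError(f"genes not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            values=self.values.loc[list(gene_ids)].copy(),
            unit=self.unit,
            log=self.log + [f"subset_genes(n={len(list(gene_ids))})"],
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = set(sample_ids) - set(self.values.columns)
        if missing:
            raise KeyError(f"samples not in matrix: {sorted(missing)[:5]}")
        return ExpressionMatrix(
            values=self.values[list(sample_ids)].copy(),
            unit=self.unit,
            log=self.log + [f"subset_samples(n={len(list(sample_ids))})"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path, unit: str = "counts") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id", comment="#")
        return cls(values=df, unit=unit, log=[f"read({Path(path).name})"])


@dataclass
class SampleTable:
    """Per-sample metadata: individual, genotype and both age coordinates."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "individual_id", "genotype", "age_since_hatch", "age_since_l4")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample table")
        ages = self.table[["age_since_hatch", "age_since_l4"]].to_numpy(float)
        if not np.all(np.isfinite(ages)):
            raise ValueError("sample ages must be finite")

    def __len__(self) -> int:
        return len(self.table)

    def ages(self, align: str = "l4") -> pd.Series:
        col = {"l4": "age_since_l4", "hatch": "age_since_hatch"}[align]
        return self.table.set_index("sample_id")[col]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


# ---------------------------------------------------------------------------


def rpm_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Reads-per-million: counts / per-sample total x 1e6 (column sums 1e6)."""
    if matrix.unit != "counts":
        raise ValueError("rpm_normalize expects a counts matrix")
    totals = matrix.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    rpm = matrix.values.div(totals, axis=1) * 1e6
    return ExpressionMatrix(values=rpm, unit="rpm", log=matrix.log + ["rpm_normalize"])


def drop_dead_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes that are all-zero or contain missing values."""
    vals = matrix.values
    has_na = vals.isna().any(axis=1)
    all_zero = (vals.fillna(0.0) == 0).all(axis=1)
    keep = ~(has_na | all_zero)
    dropped = int((~keep).sum())
    return ExpressionMatrix(
        values=vals.loc[keep].copy(),
        unit=matrix.unit,
        log=matrix.log + [f"drop_dead_genes(removed={dropped})"],
    )


def active_gene_filter(
    counts: ExpressionMatrix, min_reads: float = 7, min_fraction: float = 0.30
) -> list[str]:
    """Genes with >= ``min_reads`` counts in >= ``min_fraction`` of samples.

    The sample threshold is ``ceil(min_fraction * n_samples)``; the read
    boundary is inclusive (a count of exactly ``min_reads`` qualifies).
    """
    if counts.unit != "counts":
        raise ValueError("active_gene_filter expects a counts matrix")
    if counts.n_samples == 0 or counts.n_genes == 0:
        raise ValueError("empty matrix")
    need = math.ceil(min_fraction * counts.n_samples)
    n_hit = (counts.values >= min_reads).sum(axis=1)
    return list(counts.values.index[n_hit >= need])


def attach_ages(
    matrix: ExpressionMatrix,
    timelines: list[DevelopmentalTimeline],
    genotype: str | dict[str, str] = "N2",
    collection_times: dict[str, float] | None = None,
) -> SampleTable:
    """Join matrix samples to staged timelines, producing both age coordinates.

    Sample ids must equal the timelines' individual ids (one sample per
    individual).  Collection time defaults to each timeline's own
    ``collection_time``.
    """
    by_id: dict[str, DevelopmentalTimeline] = {}
    for tl in timelines:
        if tl.individual_id in by_id:
            raise ValueError(f"duplicate timeline for individual {tl.individual_id!r}")
        by_id[tl.individual_id] = tl
    unmatched = [s for s in matrix.sample_ids if s not in by_id]
    if unmatched:
        raise ValueError(f"samples without a timeline: {unmatched[:10]}")

    rows = []
    for sid in matrix.sample_ids:
        tl = by_id[sid]
        t = tl.collection_time if collection_times is None else collection_times[sid]
        gt = genotype[sid] if isinstance(genotype, dict) else genotype
        rows.append(
            {
                "sample_id": sid,
                "individual_id": sid,
                "genotype": gt,
                "age_since_hatch": tl.age_since_hatch(t),
                "age_since_l4": tl.age_since_l4(t),
            }
        )
    return SampleTable(pd.DataFrame(rows))
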