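"""End-to-end pipeline orchestration with config, logging and provenance.

Stages communicate only through files in the run directory; every numeric
output carries a header comment with the tool version, config hash and
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .behavior_staging import stage_track, timelines_to_tsv
from .clustering import PRESETS, bin_and_transform, cluster_means, hcluster, representative_genes
from .expression_io import active_gene_filter, drop_dead_genes, rpm_normalize
from .reconstruction import artificial_pool, pairwise_gap_correlations
from .synthetic_data import (
    BehaviorSimConfig,
    ExpressionSimConfig,
    gen_expression_cohort,
    gen_locomotion_cohort,
)
from .age_model import AgeModelConfig, run_trials

log = logging.getLogger("behaveseq")


class PipelineValidationError(ValueError):
    """Configuration invalid; raised before any compute."""


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    behavior: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)
    n_behavior_individuals: int = 20
    cluster_preset: str = "profiles"
    cluster_k: int = 8
    model_trials: int = 3
    stages: tuple[str, ...] = (
        "simulate",
        "stage",
        "normalize",
        "reconstruct",
        "cluster",
        "agepredict",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw["out_dir"] = Path(raw.get("out_dir", "behaveseq_run"))
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - {
            "simulate", "stage", "normalize", "reconstruct", "cluster", "diffexp", "agepredict",
        }
        if unknown:
            raise PipelineValidationError(f"unknown stages: {sorted(unknown)}")
        if self.cluster_preset not in PRESETS:
            raise PipelineValidationError(f"unknown cluster preset {self.cluster_preset!r}")
        try:
            BehaviorSimConfig(**{**self.behavior, "seed": self.seed})
            ExpressionSimConfig(**{**self.expression, "seed": self.seed})
        except (TypeError, ValueError) as exc:
            raise PipelineValidationError(str(exc)) from exc

    def hash(self) -> str:
        # out_dir is deployment detail, not provenance: identical runs into
        # different directories must hash identically
        payload = {k: str(v) for k, v in sorted(self.__dict__.items()) if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: Path, config_hash: str, seed: int, **kwargs) -> None:
    """Write a TSV with a provenance header comment line."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# behaveseq v{__version__} config={config_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", **kwargs)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages into ``config.out_dir``.

    On any stage failure the partial outputs are kept and a ``failed``
    marker names the offending stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.hash()
    logging.basicConfig(level=logging.INFO, format="%(asctime)s %(name)s: %(message)s")
    log.info("run start: config=%s seed=%d stages=%s", h, config.seed, config.stages)
    state: dict = {}
    current = ""
    try:
        for current in config.stages:
            _STAGE_FUNCS[current](config, out, h, state)
            log.info("stage %s done", current)
    except Exception as exc:
        (out / "failed").write_text(f"stage={current}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc
    (out / "run.json").write_text(
        json.dumps({"version": __version__, "config_hash": h, "seed": config.seed,
                    "stages": list(config.stages)}, indent=1)
    )
    return out


def _simulate(config: PipelineConfig, out: Path, h: str, state: dict) -> None:
    bcfg = BehaviorSimConfig(**{**config.behavior, "seed": config.seed})
    tracks, btruth = gen_locomotion_cohort(bcfg, config.n_behavior_individuals)
    tdir = out / "tracks"
    tdir.mkdir(exist_ok=True)
    for tr in tracks:
        tr.to_tsv(tdir / f"{tr.individual_id}.tsv")
    btruth.to_json(out / "behavior_truth.json")

    ecfg = ExpressionSimConfig(**{**config.expression, "seed": config.seed})
    counts, samples, etruth = gen_expression_cohort(ecfg)
    write_tsv(counts.values, out / "counts.tsv", h, config.seed, index_label="gene_id")
    write_tsv(samples.table, out / "samples.tsv", h, config.seed, index=False)
    etruth.to_json(out / "expression_truth.json")
    state.update(tracks=tracks, counts=counts, samples=samples)
    log.info("simulated %d tracks, %d genes x %d samples",
             len(tracks), counts.n_genes, counts.n_samples)


def _stage(config: PipelineConfig, out: Path, h: str, state: dict) -> None:
    timelines = [stage_track(tr) for tr in state["tracks"]]
    timelines_to_tsv(timelines, out / "timelines.tsv")
    state["timelines"] = timelines


def _normalize(config: PipelineConfig, out: Path, h: str, state: dict) -> None:
    counts = drop_dead_genes(state["counts"])
    active = active_gene_filter(counts)
    rpm = rpm_normalize(counts).subset_genes(active)
    write_tsv(rpm.values, out / "rpm_active.tsv", h, config.seed, index_label="gene_id")
    state["rpm"] = rpm
    log.info("genes: %d total -> %d after dead-gene drop -> %d active",
             state["counts"].n_genes, counts.n_genes, len(active))


def _reconstruct(config: PipelineConfig, out: Path, h: str, state: dict) -> None:
    samples = state["samples"]
    curve = pairwise_gap_correlations(state["rpm"], samples.ages("l4"))
    write_tsv(curve.to_frame(), out / "gap_curve.tsv", h, config.seed, index=False)
    pooled = artificial_pool(state["rpm"], samples.ages("hatch"))
    write_tsv(pooled.values, out / "pooled_hourly.tsv", h, config.seed, index_label="gene_id")


def _cluster(config: PipelineConfig, out: Path, h: str, state: dict) -> None:
    preset = PRESETS[config.cluster_preset]
    profiles = bin_and_transform(
        state["rpm"], state["samples"].ages("l4"), first_bin_norm=preset["first_bin_norm"]
    )
    result = hcluster(profiles, k=config.cluster_k, variant=preset["variant"])
    write_tsv(result.labels.to_frame(), out / "clusters.tsv", h, config.seed,
              index_label="gene_id")
    means, _ = cluster_means(result)
    write_tsv(means, out / "cluster_means.tsv", h, config.seed, index_label="cluster")
    reps = representative_genes(result)
    write_tsv(reps.table, out / "representatives.tsv", h, config.seed, index=False)
    state["representatives"] = reps


def _agepredict(config: PipelineConfig, out: Path, h: str, state: dict) -> None:
    mcfg = AgeModelConfig(seed=config.seed)
    trials = run_trials(
        state["rpm"], state["samples"].ages("l4"), None, mcfg,
        n_trials=config.model_trials, seed=config.seed,
    )
    write_tsv(trials, out / "age_model_trials.tsv", h, config.seed, index=False)
    log.info("age model: mean MAE %.1f min over %d trials",
             trials["mae"].mean(), len(trials))


def _diffexp(config: PipelineConfig, out: Path, h: str, state: dict) -> None:
    from .differential import binwise_test, window_persistence
    from .expression_io import SampleTable

    ecfg = ExpressionSimConfig(**{**config.expression, "seed": config.seed})
    mut_counts, mut_samples, _ = gen_expression_cohort(ecfg, genotype="mutant")
    cond = rpm_normalize(drop_dead_genes(mut_counts))
    ref = state["rpm"]
    result = binwise_test(
        cond, ref, mut_samples.ages("l4"), state["samples"].ages("l4")
    )
    write_tsv(result.table, out / "diffexp.tsv", h, config.seed, index=False)
    persistence = window_persistence(result)
    write_tsv(persistence.to_frame(), out / "persistence.tsv", h, config.seed, index=False)


_STAGE_FUNCS = {
    "simulate": _simulate,
    "stage": _stage,
    "normalize": _normalize,
    "reconstruct": _reconstruct,
    "cluster": _cluster,
    "diffexp": _diffexp,
    "agepredict": _agepredict,
}
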