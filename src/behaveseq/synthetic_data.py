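"""Synthetic locomotion tracks and expression cohorts with planted truth.

The behavioral simulator emits centroid tracks whose speed alternates
between active and quiescent regimes around a planted stage schedule; the
expression simulator draws per-individual collection ages uniformly over a
stage and evaluates a library of parametric temporal archetypes (ramps,
two-rate decays, oscillations, ON/OFF switches, localized bursts) at each
individual's stage-relative age, adding negative-binomial count noise.
Every output is paired with a :class:`SyntheticTruth` record.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .behavior_staging import LocomotionTrack
from .expression_io import ExpressionMatrix, SampleTable

__all__ = [
    "BehaviorSimConfig",
    "ExpressionSimConfig",
    "GenotypeEffect",
    "SyntheticTruth",
    "Archetype",
    "DEFAULT_ARCHETYPES",
    "archetype_curve",
    "gen_locomotion_track",
    "gen_locomotion_cohort",
    "gen_expression_cohort",
]


# ---------------------------------------------------------------------------
# configs


@dataclass
class BehaviorSimConfig:
    """Parameters of the locomotion simulator.

    ``stage_durations`` are the four active periods (L1..L4, minutes) and
    ``bout_durations`` the three quiescence bouts between them.
    ``jitter_sd`` is the SD of a per-individual, per-stage multiplicative
    factor on stage durations.
    """

    frame_rate: float = 3.0
    stage_durations: tuple[float, ...] = (150.0, 120.0, 120.0, 600.0)
    bout_durations: tuple[float, ...] = (25.0, 25.0, 25.0)
    hatch_delay: float = 30.0
    active_speed_mean: float = 0.10
    quiescent_speed_mean: float = 0.004
    jitter_sd: float = 0.0
    arena_radius: float = 5.0
    heading_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.stage_durations = tuple(float(d) for d in self.stage_durations)
        self.bout_durations = tuple(float(d) for d in self.bout_durations)
        if len(self.stage_durations) != 4 or len(self.bout_durations) != 3:
            raise ValueError("need 4 stage durations and 3 bout durations")
        if min(self.stage_durations) <= 0 or min(self.bout_durations) <= 0:
            raise ValueError("all durations must be positive")
        if self.hatch_delay < 0:
            raise ValueError("hatch_delay must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.quiescent_speed_mean < self.active_speed_mean:
            raise ValueError("quiescent speed must be below active speed")


@dataclass
class GenotypeEffect:
    """Multiplicative expression shift on selected genes in selected hour bins."""

    n_genes: int
    bins: tuple[int, ...]
    fold: float

    def __post_init__(self) -> None:
        self.bins = tuple(int(b) for b in self.bins)
        if self.n_genes < 1 or self.fold <= 0:
            raise ValueError("invalid genotype effect")


@dataclass
class Archetype:
    """A named parametric temporal shape with its parameter dict."""

    name: str
    params: dict = field(default_factory=dict)


#: The 8 documented temporal shapes exercised by the cohort simulator.
DEFAULT_ARCHETYPES: tuple[Archetype, ...] = (
    Archetype("ramp_up"),
    Archetype("ramp_down"),
    Archetype("two_rate_decay", {"rate1": 1.0, "rate2": 5.0, "switch_frac": 0.5}),
    Archetype("oscillation", {"period_min": 240.0, "phase": 0.0}),
    Archetype("switch_on", {"switch_frac": 0.5, "width_frac": 0.04}),
    Archetype("switch_off", {"switch_frac": 0.5, "width_frac": 0.04}),
    Archetype("burst", {"center_frac": 0.5, "width_frac": 0.08}),
    Archetype(
        "burst_asym",
        {"center_frac": 0.45, "rise_frac": 0.05, "decay_frac": 0.18},
    ),
)

_FLOOR = 0.05  # relative expression floor keeps archetype genes above the read filter


def archetype_curve(arch: Archetype, t_min: np.ndarray, span: float) -> np.ndarray:
    """Relative expression (dimensionless, O(1)) of ``arch`` at stage ages ``t_min``."""
    u = np.asarray(t_min, dtype=float) / span
    p = arch.params
    if arch.name == "constant":
        rel = np.ones_like(u)
    elif arch.name == "ramp_up":
        rel = 0.2 + 0.8 * u
    elif arch.name == "ramp_down":
        rel = 1.0 - 0.8 * u
    elif arch.name == "two_rate_decay":
        u0 = p.get("switch_frac", 0.5)
        k1, k2 = p.get("rate1", 1.0), p.get("rate2", 5.0)
        rel = np.where(
            u < u0, np.exp(-k1 * u), np.exp(-k1 * u0) * np.exp(-k2 * (u - u0))
        )
    elif arch.name == "oscillation":
        period = p.get("period_min", 240.0)
        phase = p.get("phase", 0.0)
        rel = 0.55 + 0.45 * np.sin(2 * np.pi * np.asarray(t_min) / period + phase)
    elif arch.name == "switch_on":
        u0, w = p.get("switch_frac", 0.5), p.get("width_frac", 0.04)
        rel = _FLOOR + (1 - _FLOOR) / (1.0 + np.exp(-(u - u0) / w))
    elif arch.name == "switch_off":
        u0, w = p.get("switch_frac", 0.5), p.get("width_frac", 0.04)
        rel = _FLOOR + (1 - _FLOOR) / (1.0 + np.exp((u - u0) / w))
    elif arch.name == "burst":
        c, w = p.get("center_frac", 0.5), p.get("width_frac", 0.08)
        rel = _FLOOR + np.exp(-0.5 * ((u - c) / w) ** 2)
    elif arch.name == "burst_asym":
        c = p.get("center_frac", 0.45)
        wr, wd = p.get("rise_frac", 0.05), p.get("decay_frac", 0.18)
        rel = _FLOOR + np.where(
            u < c,
            np.exp(-0.5 * ((u - c) / wr) ** 2),
            np.exp(-0.5 * ((u - c) / wd) ** 2),
        )
    else:
        raise ValueError(f"unknown archetype {arch.name!r}")
    return np.maximum(rel, 0.0)


@dataclass
class ExpressionSimConfig:
    """Parameters of the expression-cohort simulator."""

    n_individuals: int = 193
    stage_span: float = 600.0
    n_genes_per_archetype: int = 50
    archetypes: tuple[Archetype, ...] = DEFAULT_ARCHETYPES
    baseline_mean: float = 200.0
    dispersion: float = 0.1
    dispersion_spread: float = 0.0
    amplitude_range: tuple[float, float] = (1.0, 1.0)
    library_size_range: tuple[float, float] = (1.0e6, 1.0e6)
    prestage_mean: float = 300.0
    prestage_jitter_sd: float = 0.0
    genotype_effects: tuple[GenotypeEffect, ...] = ()
    reference_genotype: str = "N2"
    plant_exemplars: bool = False
    param_diversity: bool = False
    sampling: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        self.archetypes = tuple(
            a if isinstance(a, Archetype) else Archetype(**a) for a in self.archetypes
        )
        if self.n_individuals < 2:
            raise ValueError("need at least 2 individuals")
        if self.stage_span <= 0:
            raise ValueError("stage_span must be positive")
        if not self.archetypes:
            raise ValueError("archetype list must be non-empty")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n_genes_per_archetype < 1:
            raise ValueError("need at least one gene per archetype")
        if self.sampling not in ("uniform", "grid", "clustered"):
            raise ValueError(f"unknown sampling design {self.sampling!r}")


@dataclass
class SyntheticTruth:
    """Ground truth paired with a simulated artifact (all times in minutes)."""

    hatch_times: dict[str, float] = field(default_factory=dict)
    transition_times: dict[str, list[float]] = field(default_factory=dict)
    collection_times: dict[str, float] = field(default_factory=dict)
    stage_ages: dict[str, float] = field(default_factory=dict)
    hatch_ages: dict[str, float] = field(default_factory=dict)
    gene_archetype: dict[str, str] = field(default_factory=dict)
    gene_params: dict[str, dict] = field(default_factory=dict)
    effect_genes: dict[str, list[int]] = field(default_factory=dict)
    exemplar_genes: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# locomotion simulator


def _fold(coord: np.ndarray, half: float) -> np.ndarray:
    """Reflect an unbounded random walk into [-half, half] (triangle wave)."""
    period = 4.0 * half
    w = np.mod(coord + half, period)
    return np.where(w < 2 * half, w - half, 3 * half - w)


def gen_locomotion_track(
    config: BehaviorSimConfig, individual_seed: int
) -> tuple[LocomotionTrack, SyntheticTruth]:
    """Simulate one individual's centroid track plus its truth schedule.

    The schedule is hatch-delay, then alternating active stages and
    quiescence bouts.  Per-stage durations are scaled by a multiplicative
    jitter factor ``max(0.1, 1 + N(0, jitter_sd))``.  Speeds are
    half-normal around the configured regime means; positions perform a
    heading-persistent walk reflected inside the circular arena's
    inscribed square.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, individual_seed)))
    factors = np.maximum(0.1, 1.0 + rng.normal(0.0, config.jitter_sd, size=4))
    stages = [d * f for d, f in zip(config.stage_durations, factors)]

    segments: list[tuple[float, bool]] = [(config.hatch_delay, False)]
    for i in range(3):
        segments.append((stages[i], True))
        segments.append((config.bout_durations[i], False))
    segments.append((stages[3], True))

    hatch = config.hatch_delay
    t_cursor = hatch
    transitions = []
    for i in range(3):
        t_cursor += stages[i]
        transitions.append(t_cursor + 0.5 * config.bout_durations[i])
        t_cursor += config.bout_durations[i]
    collection = t_cursor + stages[3]

    total_s = collection * 60.0
    n_frames = int(round(total_s * config.frame_rate))
    time_s = np.arange(n_frames) / config.frame_rate

    active = np.zeros(n_frames, dtype=bool)
    edge = 0.0
    for dur, is_active in segments:
        lo = int(round(edge * 60 * config.frame_rate))
        edge += dur
        hi = int(round(edge * 60 * config.frame_rate))
        active[lo:hi] = is_active

    dt = 1.0 / config.frame_rate
    hatched = time_s >= hatch * 60.0
    speed = np.where(
        active,
        np.abs(rng.normal(config.active_speed_mean, 0.25 * config.active_speed_mean, n_frames)),
        np.abs(rng.normal(0.0, config.quiescent_speed_mean * np.sqrt(np.pi / 2.0), n_frames)),
    )
    speed[~hatched] = 0.0  # egg

    # active crawling keeps heading; quiescent motion is in-place jiggle
    heading_sd = np.where(active, config.heading_sd, 2.0)
    heading = np.cumsum(rng.normal(0.0, 1.0, n_frames) * heading_sd)
    step = speed * dt
    half = config.arena_radius / np.sqrt(2.0)
    x = _fold(np.cumsum(step * np.cos(heading)), half)
    y = _fold(np.cumsum(step * np.sin(heading)), half)

    iid = f"ind_{individual_seed:04d}"
    track = LocomotionTrack(
        frame_index=np.arange(n_frames),
        time=time_s,
        x=x,
        y=y,
        frame_rate=config.frame_rate,
        individual_id=iid,
    )
    truth = SyntheticTruth(
        hatch_times={iid: hatch},
        transition_times={iid: transitions},
        collection_times={iid: collection},
    )
    return track, truth


def gen_locomotion_cohort(
    config: BehaviorSimConfig, n_individuals: int
) -> tuple[list[LocomotionTrack], SyntheticTruth]:
    """Simulate ``n_individuals`` tracks sharing one config, merged truth."""
    tracks, truth = [], SyntheticTruth()
    for i in range(n_individuals):
        tr, t = gen_locomotion_track(config, i)
        tracks.append(tr)
        truth.hatch_times.update(t.hatch_times)
        truth.transition_times.update(t.transition_times)
        truth.collection_times.update(t.collection_times)
    return tracks, truth


# ---------------------------------------------------------------------------
# expression simulator


def _diversify(arch: Archetype, rng: np.random.Generator) -> Archetype:
    """Per-gene parameter draw spreading event times across the stage.

    Makes the gene ensemble approximately translation-invariant, so the
    population correlation-vs-gap kernel decays smoothly with gap.
    """
    p = dict(arch.params)
    if arch.name == "two_rate_decay":
        p["switch_frac"] = rng.uniform(0.2, 0.8)
        p["rate1"] = p.get("rate1", 1.0) * float(np.exp(rng.normal(0, 0.3)))
        p["rate2"] = p.get("rate2", 5.0) * float(np.exp(rng.normal(0, 0.3)))
    elif arch.name == "oscillation":
        p["period_min"] = rng.uniform(120.0, 480.0)
        p["phase"] = rng.uniform(0.0, 2 * np.pi)
    elif arch.name in ("switch_on", "switch_off"):
        p["switch_frac"] = rng.uniform(0.05, 0.95)
        p["width_frac"] = rng.uniform(0.02, 0.08)
    elif arch.name == "burst":
        p["center_frac"] = rng.uniform(0.1, 0.9)
        p["width_frac"] = rng.uniform(0.05, 0.15)
    elif arch.name == "burst_asym":
        p["center_frac"] = rng.uniform(0.1, 0.9)
        p["rise_frac"] = rng.uniform(0.03, 0.08)
        p["decay_frac"] = rng.uniform(0.10, 0.25)
    return Archetype(arch.name, p)


def _gene_table(config: ExpressionSimConfig, rng: np.random.Generator):
    """Per-gene archetype assignment, amplitude, dispersion, exemplar flag."""
    genes, arch_of, amp, disp, exemplars = [], {}, [], [], []
    lo, hi = config.amplitude_range
    for arch in config.archetypes:
        for i in range(config.n_genes_per_archetype):
            gid = f"{arch.name}_{i:03d}"
            genes.append(gid)
            arch_of[gid] = _diversify(arch, rng) if config.param_diversity else arch
            amp.append(rng.uniform(lo, hi))
            d = config.dispersion
            if config.dispersion_spread > 0:
                d *= float(np.exp(rng.normal(0.0, config.dispersion_spread)))
            if config.plant_exemplars and i == 0:
                d = 0.0
                exemplars.append(gid)
            disp.append(d)
    return genes, arch_of, np.array(amp), np.array(disp), exemplars


def gen_expression_cohort(
    config: ExpressionSimConfig, genotype: str = "N2"
) -> tuple[ExpressionMatrix, SampleTable, SyntheticTruth]:
    """Simulate a cohort of single-individual count profiles.

    Stage-relative collection ages are uniform on [0, stage_span]; the
    hatch-relative age adds a per-individual jittered pre-stage duration, so
    hatch alignment is strictly noisier than stage alignment whenever
    ``prestage_jitter_sd > 0``.  Genotype effects multiply the expected
    expression of their target genes inside the configured hour bins when
    ``genotype`` differs from the reference genotype.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence((config.seed, zlib.crc32(genotype.encode())))
    )
    n = config.n_individuals
    span = config.stage_span

    if config.sampling == "clustered":
        centers = rng.uniform(0, span, size=max(2, n // 20))
        stage_age = np.clip(
            rng.choice(centers, size=n) + rng.normal(0, span * 0.02, size=n), 0, span
        )
    elif config.sampling == "grid":
        stage_age = np.linspace(0.0, span, n)
    else:
        stage_age = rng.uniform(0.0, span, size=n)
    prestage = config.prestage_mean * np.maximum(
        0.05, 1.0 + rng.normal(0.0, config.prestage_jitter_sd, size=n)
    )
    hatch_age = stage_age + prestage

    genes, arch_of, amp, disp, exemplars = _gene_table(config, rng)
    n_genes = len(genes)

    rel = np.empty((n_genes, n))
    for gi, gid in enumerate(genes):
        rel[gi] = archetype_curve(arch_of[gid], stage_age, span)

    lib = rng.uniform(*config.library_size_range, size=n)
    mu = config.baseline_mean * amp[:, None] * rel * (lib / np.mean(lib))[None, :]

    effect_genes: dict[str, list[int]] = {}
    if genotype != config.reference_genotype and config.genotype_effects:
        gene_pool = list(range(n_genes))
        rng_eff = np.random.default_rng(np.random.SeedSequence((config.seed, 7_777)))
        hour_bin = np.floor(stage_age / 60.0).astype(int)
        for ei, eff in enumerate(config.genotype_effects):
            chosen = rng_eff.choice(gene_pool, size=eff.n_genes, replace=False)
            gene_pool = [g for g in gene_pool if g not in set(chosen.tolist())]
            in_window = np.isin(hour_bin, eff.bins)
            mu[np.ix_(chosen, np.flatnonzero(in_window))] *= eff.fold
            effect_genes[f"effect_{ei}"] = sorted(int(g) for g in chosen)

    counts = np.where(disp[:, None] > 0, np.nan, mu)
    noisy = disp > 0
    if noisy.any():
        size = 1.0 / disp[noisy]  # NB: var = mu + disp * mu^2
        mu_n = np.maximum(mu[noisy], 1e-9)
        p = size[:, None] / (size[:, None] + mu_n)
        counts[noisy] = rng.negative_binomial(size[:, None], p).astype(float)

    sample_ids = [f"ind_{i:04d}" for i in range(n)]
    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=sample_ids),
        unit="counts",
        log=[f"simulated(seed={config.seed}, genotype={genotype})"],
    )
    samples = SampleTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "individual_id": sample_ids,
                "genotype": genotype,
                "age_since_hatch": hatch_age,
                "age_since_l4": stage_age,
            }
        )
    )
    truth = SyntheticTruth(
        collection_times={s: float(h) for s, h in zip(sample_ids, hatch_age)},
        stage_ages={s: float(a) for s, a in zip(sample_ids, stage_age)},
        hatch_ages={s: float(a) for s, a in zip(sample_ids, hatch_age)},
        gene_archetype={g: arch_of[g].name for g in genes},
        gene_params={g: dict(arch_of[g].params) for g in genes},
        effect_genes=effect_genes,
        exemplar_genes=exemplars,
    )
    return matrix, samples, truth
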