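"""Synthetic datasets with planted ground truth.

The generator emulates a time-series RNA-seq experiment downstream of a
known TF activity programme: each planted TF follows a configurable
waveform (rhythmic with a chosen peak phase, or constant), its target
genes respond through the transcription/splicing kinetics of
:mod:`introflow.simulate`, and read counts are drawn as Poisson around
depth-scaled unspliced (intron layer) and spliced (exon layer) levels —
making explicit the modelling assumption that intronic reads report
unspliced mRNA. Off-target genes provide a constant background, some
genes are deliberately intronless to exercise the eligibility rules,
and optional binomial thinning emulates finite capture efficiency.

Everything is driven by one top-level seed, split deterministically per
stage, so a fixture is reproducible byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import CountMatrix, write_count_table
from .regulons import RegulonSet, write_regulons
from .simulate import (
    SimulationGrid,
    TFWaveformParams,
    sample_gene_kinetics,
    simulate_ode,
    steady_state,
    thin_detection,
    tf_waveform,
)

__all__ = ["TFSpec", "FixtureConfig", "GroundTruth", "Fixture", "generate_fixture", "write_fixture"]


@dataclass(frozen=True)
class TFSpec:
    """Planted activity programme of one TF."""

    name: str
    rhythmic: bool = True
    phase: float = 0.0  # peak time, h
    halflife_min: float = 600.0  # mean target mRNA half-life, min
    module: int | None = None  # planted co-activity module label


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a bulk circadian time course: samples every 2 h
    over one 24 h cycle with four biological replicates, a sequencing
    depth of two million intron+exon reads per sample, and off-target
    background genes with log-normal constant expression (median
    half-life 100 min, sigma_log 1).
    """

    tf_specs: tuple[TFSpec, ...] = (
        TFSpec("TF1", rhythmic=True, phase=6.0, halflife_min=600.0, module=1),
        TFSpec("TF2", rhythmic=False, phase=0.0, halflife_min=100.0, module=None),
    )
    targets_per_tf: int = 8
    intronless_per_tf: int = 1  # of the targets_per_tf, how many lack introns
    n_offtarget_genes: int = 50
    times: tuple[float, ...] = tuple(float(t) for t in range(0, 24, 2))
    replicates: int = 4
    period: float = 24.0
    a_basal: float = 0.06
    a_max: float = 0.5
    depth: float = 2e6  # expected intron+exon reads per sample
    detection_p: float | None = None
    offtarget_halflife_median: float = 100.0
    offtarget_sigma_log: float = 1.0
    # background genes carry this share of the library in expectation, so a
    # planted regulon is a small minority of reads as in a real transcriptome
    offtarget_library_fraction: float = 0.95
    # inter-replicate biological variability: log-normal, mean-preserving,
    # shared between the intron and exon layer of a gene
    bio_noise_cv: float = 0.2
    burn_in_periods: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.targets_per_tf < 1 or self.replicates < 1 or self.n_offtarget_genes < 0:
            raise ValueError("counts must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.intronless_per_tf < self.targets_per_tf):
            raise ValueError("intronless_per_tf must leave at least one intron-bearing target")
        if self.detection_p is not None and not (0 < self.detection_p <= 1):
            raise ValueError("detection_p must lie in (0, 1]")
        if len({s.name for s in self.tf_specs}) != len(self.tf_specs):
            raise ValueError("TF names must be unique")
        if not (0.0 <= self.offtarget_library_fraction < 1.0):
            raise ValueError("offtarget_library_fraction must lie in [0, 1)")
        if self.bio_noise_cv < 0:
            raise ValueError("bio_noise_cv must be non-negative")


@dataclass
class GroundTruth:
    """What was planted: activities, phases, kinetics, modules."""

    activity: pd.DataFrame  # tf x time, planted TF concentration
    phases: dict[str, float | None]
    modules: dict[str, int | None]
    target_halflives: pd.Series
    rhythmic: dict[str, bool]
    seed: int


@dataclass
class Fixture:
    """In-memory synthetic dataset plus its ground truth."""

    counts: CountMatrix
    regulons: RegulonSet
    half_lives: pd.Series
    tss: pd.DataFrame
    peaks: pd.DataFrame
    surrogate: pd.DataFrame  # time x tf, planted activity series
    truth: GroundTruth
    config: FixtureConfig


def _planted_activity(spec: TFSpec, wf: TFWaveformParams, times: np.ndarray) -> np.ndarray:
    """Planted TF concentration at the sampling times.

    The base waveform peaks at T/2; shifting the evaluation time places
    the peak at the spec's phase. Constant TFs sit at the waveform
    midpoint so rhythmic and flat TFs share the same mean scale.
    """
    if spec.rhythmic:
        shifted = (times - spec.phase + wf.period / 2.0) % wf.period
        return np.asarray(tf_waveform(wf, shifted))
    return np.full_like(times, (wf.a_basal + wf.a_max) / 2.0, dtype=float)


def generate_fixture(cfg: FixtureConfig) -> Fixture:
    """Build a complete synthetic dataset from one config.

    Target levels come from the deterministic kinetic model evaluated in
    its periodic regime (a few periods of burn-in discard the initial
    transient); counts are Poisson draws around depth-scaled levels,
    independently per replicate, optionally thinned at the configured
    capture efficiency.
    """
    master = np.random.SeedSequence(cfg.seed)
    rng_kin, rng_counts, rng_bg = [np.random.default_rng(s) for s in master.spawn(3)]

    wf = TFWaveformParams(a_basal=cfg.a_basal, a_max=cfg.a_max, period=cfg.period)
    times = np.asarray(cfg.times, dtype=float)

    # ODE solved once per target on a fine grid covering burn-in plus one
    # cycle; sample-time values are read from the final cycle
    grid = SimulationGrid(duration=(cfg.burn_in_periods + 1) * cfg.period, dt=0.01)

    gene_rows = []  # (gene, has_intron, u_levels, s_levels)
    regulon_rows = []
    halflife_entries = {}
    truth_activity = {}
    phases: dict[str, float | None] = {}
    modules: dict[str, int | None] = {}
    rhythmic: dict[str, bool] = {}

    for spec in cfg.tf_specs:
        truth_activity[spec.name] = _planted_activity(spec, wf, times)
        phases[spec.name] = spec.phase if spec.rhythmic else None
        modules[spec.name] = spec.module
        rhythmic[spec.name] = spec.rhythmic
        for j in range(cfg.targets_per_tf):
            gene = f"{spec.name}_tgt{j + 1}"
            half_life = float(rng_kin.uniform(0.8, 1.2) * spec.halflife_min)
            kin = sample_gene_kinetics(rng_kin, half_life)
            halflife_entries[gene] = half_life
            if spec.rhythmic:
                traj = simulate_ode(kin, wf, grid)
                eval_t = cfg.burn_in_periods * cfg.period + (
                    (times - spec.phase + cfg.period / 2.0) % cfg.period
                )
                u = np.interp(eval_t, traj.times, traj.u)
                s = np.interp(eval_t, traj.times, traj.s)
            else:
                u_star, s_star = steady_state(kin, (cfg.a_basal + cfg.a_max) / 2.0)
                u = np.full_like(times, u_star)
                s = np.full_like(times, s_star)
            has_intron = j >= cfg.intronless_per_tf
            gene_rows.append((gene, has_intron, u, s))
            regulon_rows.append((spec.name, gene, "activation", "A" if j % 2 == 0 else "B"))
        # decoy edges exercising the confidence/mode filters: they point
        # at background genes and must be dropped by default settings
        regulon_rows.append((spec.name, f"bg{1 + cfg.tf_specs.index(spec)}", "activation", "C"))
        regulon_rows.append((spec.name, f"bg{10 + cfg.tf_specs.index(spec)}", "repression", "A"))

    for i in range(cfg.n_offtarget_genes):
        gene = f"bg{i + 1}"
        base = float(np.exp(rng_bg.normal(np.log(50.0), 1.0)))
        half_life = float(np.exp(rng_bg.normal(
            np.log(cfg.offtarget_halflife_median), cfg.offtarget_sigma_log
        )))
        halflife_entries[gene] = half_life
        has_intron = i % 7 != 3  # a sprinkle of intronless background genes
        u = np.full_like(times, 0.1 * base)
        s = np.full_like(times, base)
        gene_rows.append((gene, has_intron, u, s))

    genes = [g for g, _, _, _ in gene_rows]
    has_intron = pd.Series({g: h for g, h, _, _ in gene_rows}, name="has_intron")
    is_planted = np.array([not g.startswith("bg") for g in genes])
    u_levels = np.vstack([u for _, _, u, _ in gene_rows])  # genes x times
    s_levels = np.vstack([s for _, _, _, s in gene_rows])
    u_levels = u_levels * has_intron.to_numpy()[:, None]  # intronless: no intronic signal

    # rescale the background so it carries its configured share of the
    # library: a planted regulon is a small minority of a real transcriptome
    planted_total = float(np.mean((u_levels + s_levels)[is_planted].sum(axis=0)))
    bg_total = float(np.mean((u_levels + s_levels)[~is_planted].sum(axis=0)))
    if bg_total > 0 and planted_total > 0 and cfg.offtarget_library_fraction > 0:
        f = cfg.offtarget_library_fraction
        bg_factor = (f / (1.0 - f)) * planted_total / bg_total
        u_levels[~is_planted] *= bg_factor
        s_levels[~is_planted] *= bg_factor

    # one scale factor for the whole experiment keeps relative depth honest
    depth_scale = cfg.depth / float(np.mean(u_levels.sum(axis=0) + s_levels.sum(axis=0)))

    sigma_log = float(np.sqrt(np.log1p(cfg.bio_noise_cv**2)))
    sample_ids, sample_time, sample_rep = [], {}, {}
    intron_cols, exon_cols = {}, {}
    for r in range(cfg.replicates):
        if sigma_log > 0:
            # per gene and time point, shared between layers (expression-level
            # fluctuation of the gene, not measurement noise)
            bio = np.exp(rng_counts.normal(-sigma_log**2 / 2, sigma_log, size=u_levels.shape))
        else:
            bio = 1.0
        lam_u = depth_scale * u_levels * bio
        lam_s = depth_scale * s_levels * bio
        draws_u = rng_counts.poisson(lam_u)
        draws_s = rng_counts.poisson(lam_s)
        if cfg.detection_p is not None:
            draws_u = thin_detection(draws_u, cfg.detection_p, rng_counts)
            draws_s = thin_detection(draws_s, cfg.detection_p, rng_counts)
        for ti, t in enumerate(times):
            sid = f"t{t:g}_r{r + 1}"
            sample_ids.append(sid)
            sample_time[sid] = float(t)
            sample_rep[sid] = f"r{r + 1}"
            intron_cols[sid] = draws_u[:, ti]
            exon_cols[sid] = draws_s[:, ti]

    counts = CountMatrix(
        intron=pd.DataFrame(intron_cols, index=genes),
        exon=pd.DataFrame(exon_cols, index=genes),
        has_intron=has_intron,
        sample_time=pd.Series(sample_time),
        sample_replicate=pd.Series(sample_rep),
    )

    regulons = RegulonSet(entries=pd.DataFrame(
        regulon_rows, columns=["tf", "target", "mode", "confidence"]
    ))

    tss = pd.DataFrame(
        {
            "chrom": ["chr1"] * len(genes),
            "strand": ["+" if i % 2 == 0 else "-" for i in range(len(genes))],
            "tss": [10_000 * (i + 1) for i in range(len(genes))],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    # peaks over the first half of each TF's targets, plus decoys in gene deserts
    peak_rows = []
    for spec in cfg.tf_specs:
        for j in range(cfg.targets_per_tf // 2):
            gene = f"{spec.name}_tgt{j + 1}"
            center = int(tss.loc[gene, "tss"])
            peak_rows.append(("chr1", center - 150, center + 150))
    peak_rows.append(("chr1", 10_000 * (len(genes) + 5), 10_000 * (len(genes) + 5) + 300))
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end"])

    surrogate = pd.DataFrame(truth_activity, index=pd.Index(times, name="time"))

    truth = GroundTruth(
        activity=surrogate.T,
        phases=phases,
        modules=modules,
        target_halflives=pd.Series(halflife_entries),
        rhythmic=rhythmic,
        seed=cfg.seed,
    )
    return Fixture(
        counts=counts,
        regulons=regulons,
        half_lives=pd.Series(halflife_entries, name="half_life_min"),
        tss=tss,
        peaks=peaks,
        surrogate=surrogate,
        truth=truth,
        config=cfg,
    )


def write_fixture(fixture: Fixture, outdir) -> dict[str, Path]:
    """Serialise a fixture to the documented plain-text dialects.

    Returns the mapping of logical names to written paths; a JSON ground
    truth record (seed included) sits alongside the data files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "regulons": outdir / "regulons.tsv",
        "half_lives": outdir / "halflives.tsv",
        "tss": outdir / "tss.tsv",
        "peaks": outdir / "peaks.bed",
        "surrogate": outdir / "surrogate.tsv",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_count_table(fixture.counts, paths["counts"], samples_path=paths["samples"])
    write_regulons(fixture.regulons, paths["regulons"])
    hl = fixture.half_lives.rename("half_life_min")
    hl.index.name = "gene_id"
    hl.to_csv(paths["half_lives"], sep="\t")
    fixture.tss.to_csv(paths["tss"], sep="\t")
    fixture.peaks.to_csv(paths["peaks"], sep="\t", header=False, index=False)
    sur = fixture.surrogate.copy()
    sur.index.name = "time"
    sur.to_csv(paths["surrogate"], sep="\t")
    truth = {
        "seed": fixture.truth.seed,
        "phases": fixture.truth.phases,
        "modules": fixture.truth.modules,
        "rhythmic": fixture.truth.rhythmic,
        "activity": {tf: list(map(float, row))
                     for tf, row in fixture.truth.activity.iterrows()},
        "times": [float(t) for t in fixture.config.times],
        "config": {k: v for k, v in asdict(fixture.config).items() if k != "tf_specs"},
    }
    paths["ground_truth"].write_text(json.dumps(truth, indent=2))
    return paths
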