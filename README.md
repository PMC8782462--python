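# introflow

Estimate **instantaneous transcription factor (TF) activity** from RNA-seq by
reading the *intronic* (unspliced) signal of the TF's regulon, with a kinetic
simulator that shows why this works and time-series analyses (circadian
rhythmicity, phase, surrogate validation, TF modules) built on top.

## The problem and who this is for

A TF's activity is usually inferred from the expression of its known target
genes (its *regulon*). Standard pipelines use exon-level expression — mature
mRNA — which integrates transcription over each target's mRNA half-life.
For dynamic processes (stress response, circadian rhythm, T-cell activation)
that integration blurs and delays the readout. Intronic reads come mostly
from unspliced pre-mRNA, which turns over in minutes, so intron-level
expression of the regulon tracks what the TF is doing *now*.

`introflow` is for computational biologists with per-gene intron/exon count
tables (from any intron-aware quantifier) who want per-sample TF activities
and their dynamics. Read assignment/alignment is out of scope: counts are
the input boundary.

## Model and estimator

Transcription and splicing of a target gene driven by TF concentration
`TF(t)`:

    du/dt = α · TFⁿ / (TFⁿ + K_dⁿ) − β·u        (unspliced pre-mRNA)
    ds/dt = β·u − γ·s                            (spliced mRNA)

with splicing rate `β = ln10 / t_splice` (90% spliced within `t_splice`,
5–10 min) and decay rate `γ = ln2 / t_half`. Because `β ≫ γ`, `u` follows
`TF(t)` with a lag of minutes while `s` low-pass filters it with a time
constant of hours. The simulator integrates these ODEs and also runs a
τ-leap stochastic version (Poisson event counts per reaction per step) for
single-cell ensembles, with binomial thinning for finite capture efficiency.

Quantification uses counts-per-million with a **shared** denominator:

    CPM_intron(g, j) = 10⁶ · intron(g, j) / Σ_g' [intron(g', j) + exon(g', j)]

(and likewise for the exon layer), so both layers of a sample sum to 10⁶.
No length normalisation is applied — intronic priming makes effective
intron length unknown.

The activity estimate is the unweighted mean CPM of the regulon's
activating, high-confidence (grade A/B) targets; intronless genes are
excluded from the intron layer. A rank-based recovery-curve (AUC) variant,
z-scoring, fold-changes and a random-regulon empirical null are included.
Rhythmicity uses a fixed-period cosinor regression (F-test of the harmonic
terms; phase = fitted peak time).

## Worked example

```
$ python examples/01_simulation_benchmark.py
half-life (min)   corr(u, TF)   corr(s, TF)
            20         0.938         0.816
           100         0.917         0.281
           500         0.930         0.026
          1000         0.937         0.009
          2000         0.940        -0.001

regulon-mean estimate: corr(u-based, TF) = 0.948, corr(s-based, TF) = 0.049
```

Each row is one mRNA half-life bin: the correlation of a target's unspliced
level with the driving TF stays ≈0.93 everywhere, while the spliced level
decorrelates from 0.82 to ≈0 as half-life grows — mature mRNA remembers the
past instead of reporting the present. The regulon-mean activity estimate
inherits the same contrast.

```
$ python examples/03_circadian_rhythm.py
intron layer: p = 2.31e-04, peak phase = 6.06 h
exon layer:   p = 2.89e-05, peak phase = 10.49 h
class: class1 (both layers rhythmic)
phase difference (exon - intron) = +4.43 h
```

On a synthetic circadian dataset with a TF planted to peak at 6 h, the
intron-based phase lands at 6.06 h while the exon-based phase lags by
4.4 h — the signature the method is designed to expose.

The other examples cover CPM/activity estimation (`02`), surrogate
validation with a random-regulon null (`04`) and anti-phase TF module
discovery (`05`). A thin CLI mirrors the library
(`introflow fixture|quantify|regulon|tfa|rhythm|correlate|cluster|run`).

## Layout

- `src/introflow/simulate.py` — waveform, kinetics, ODE and τ-leap simulators, benchmarks
- `src/introflow/quantify.py` — count tables, shared-denominator CPM, replicate averaging
- `src/introflow/regulons.py` — regulon loading/filtering, half-life splits, random nulls, ChIP-peak refinement
- `src/introflow/activity.py` — mean and rank-AUC activity estimators, null percentile, summaries
- `src/introflow/dynamics.py` — cosinor, phase arithmetic, surrogate correlation, robustness, TF modules
- `src/introflow/fixtures.py` — synthetic datasets with planted ground truth
- `src/introflow/pipeline.py`, `src/introflow/cli.py` — orchestration and the CLI
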