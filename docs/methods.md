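# Methods

## Kinetic model

A TF concentration `TF(t)` drives each target gene through a Hill input
function; unspliced pre-mRNA `u` and spliced mRNA `s` follow

    du/dt = α · TFⁿ / (TFⁿ + K_dⁿ) − β·u
    ds/dt = β·u − γ·s

The TF waveform interpolates between a basal and a maximal concentration,

    TF(t) = A_basal·(1 + cos(2πt/T))/2 + A_max·(1 − cos(2πt/T))/2 + ε,

with `ε ~ N(0, σ²)` when noise is enabled, clipped at zero — concentrations
cannot be negative, and the clip is the only defensible completion of an
additive-Gaussian model near zero.

Default parameters model an oscillatory stress-response TF:
`A_basal = 0.06 µM`, `A_max = 0.5 µM`, `T = 5.5 h`, `σ = 0.2·A_basal`;
per gene, `α ~ U(100, 200) h⁻¹`, `K_d ~ U(0.05, 0.25) µM`, `n = 2`,
splicing time `~ U(5, 10) min` with `β = ln10/t_splice` (90% of pre-mRNA
spliced within `t_splice`), and `γ = ln2/t_half` from the gene's mRNA
half-life. Simulations start at the basal-TF steady state
`u* = α·hill(A_basal)/β`, `s* = β·u*/γ` and run 20 h at 0.001 h steps.

### Integrators

*Deterministic:* LSODA with rtol 1e-8 / atol 1e-10, sampled on the fixed
grid. `β` up to ≈28 h⁻¹ against `γ` down to ≈0.02 h⁻¹ makes the system
moderately stiff; a fixed-step explicit scheme at 0.001 h would also work
but the adaptive integrator is used as the reference oracle elsewhere, so
its tolerance is kept tight.

*Stochastic (τ-leap):* per step, each reaction fires a Poisson-distributed
number of times (production `α·hill·Ω·dt`, splicing `β·u·dt`, degradation
`γ·s·dt`); counts are floored at zero. The model is written in
concentrations, so a conversion factor Ω (molecules per µM, default 100)
sets the count scale; it is configurable, and a warning is raised when
expected events per step exceed 10% of the basal unspliced count (the
τ-leap accuracy condition). With Ω = 100 the 1000-cell ensemble mean of
both `u` and `s` agrees with the ODE solution to ≪1% after burn-in.

### Correlation convention

All simulator benchmarks correlate levels with the (per-cell, noisy) TF
trajectory after discarding the first waveform period as burn-in, **and
truncate the analysis window to a whole number of periods**. The second
clause matters: long-lived spliced mRNA approaches its periodic regime
with a time constant `1/γ` that can exceed the simulation length, leaving
a slow ramp through the whole window. Over a fractional number of periods
a monotone ramp has a non-zero Pearson correlation with the waveform
(≈0.14 for a linear ramp on a 2.64-period window; exactly 0 on whole
periods). That leakage floor otherwise dominates, and can invert, the
genuine half-life ordering of `corr(s, TF)` at half-lives ≥1000 min.

### Half-life bins

The benchmark reports per-bin means over several genes sampled per
half-life bin (6 by default) rather than a single gene per bin: with one
draw per bin, the per-gene `α`/`K_d`/splicing lottery dominates the bin
value and bin-to-bin comparisons compare draws, not half-lives. This
mirrors how per-bin averages over regulon genes are normally presented.

### Capture-efficiency sweep

Finite mRNA capture is modelled as independent binomial thinning of
counts. The sweep over efficiencies uses *nested* thinning — counts at a
lower efficiency are a further subsample of the counts at the next higher
one — so all efficiencies share the same underlying trajectories and
differences reflect capture rate alone. The single-gene sweep conditions
are `α = 100 h⁻¹` with a 100-min half-life; a 1000-min gene is used to
show that the unspliced readout keeps its advantage (its spliced
correlation sits at the noise floor there, so only the ratio, not
monotonicity, is meaningful for that gene).

## Quantification

Counts-per-million with the denominator shared between layers: intron CPM
and exon CPM of a sample jointly sum to 10⁶, and a gene's intron CPM
responds to changes in any gene's exon counts. This is deliberate (it
keeps the two layers on one scale) and documented because it has a real
consequence: CPM is compositional, and a strongly oscillating minority of
the library imprints a small anti-phase oscillation on everyone else. No
length normalisation is applied: intronic reads can arise from internal
priming, so effective intron length is unknown. Replicates are averaged
on CPM, not raw counts, so deeper replicates do not dominate. Genes
without annotated introns are flagged structurally (`has_intron`), never
encoded as zero counts, so exclusion rules stay explicit.

## Activity estimation

`tfa_mean` is the unweighted mean CPM of the regulon's eligible targets:
activating edges with confidence grade A or B by default (loosenable to
C), intronless genes excluded on the intron layer. Whether the exon layer
should drop intronless genes too is genuinely ambiguous; the default
keeps them (literal reading of the layer's semantics) and a
`matched_gene_set` switch forces identical gene sets for head-to-head
layer comparisons. Missing targets warn rather than fail — public
regulons routinely cite genes absent from a given annotation.

`tfa_rank_auc` scores a regulon by the area under its recovery curve over
the expression ranking of *all* genes in the matrix, truncated at a top
fraction (default 0.05, the conventional choice for recovery-curve
scoring), normalised to [0, 1] by the maximal achievable area, with ties
broken by gene id for determinism. It is invariant under monotone
transforms of expression.

The random-regulon null draws size-matched regulons (matching the real
regulon's size keeps the ensemble averaging comparable) from the universe
minus the TF's own targets; the empirical p-value uses the add-one rule
`p = (1 + #{null ≥ actual}) / (1 + n)`.

## Dynamics

Rhythmicity: single-harmonic cosinor at fixed period (24 h for circadian
data), `x(t) = m + a·cos(ωt) + b·sin(ωt)` by least squares; p-value from
the exact F-test of `(a, b) = 0`; amplitude `√(a² + b²)`; phase = fitted
peak time in `[0, period)`. Constant series are reported non-rhythmic
(p = 1) with a warning rather than NaN. A TF is class 1 if both layers
are rhythmic at α = 0.05, class 2 intron-only, class 3 exon-only. Phase
differences are wrapped to `(−period/2, period/2]` with positive =
exon lags intron. An ensembled multi-test detector would be more
sensitive on non-sinusoidal shapes; absolute counts of rhythmic TFs are
therefore not comparable across detectors, and none are claimed.

Surrogate validation interpolates both series linearly onto a shared
0.5 h grid over the overlapping time range (configurable); extrapolation
is refused. Replicate robustness re-runs the cosinor on every
leave-one-out replicate subset by default (all proper subsets of size ≥2
optionally) and reports the fraction of rhythmic calls. TF modules come
from average-linkage agglomerative clustering on `1 − r` correlation
distance, cut at k = 2; constant series are excluded with a warning.
Average linkage at k = 2 is a documented substitution for an unspecified
linkage/cut rule.

## Synthetic data generator

`generate_fixture` emulates a bulk time-series experiment downstream of a
known TF programme: planted TFs follow the waveform (peak phase
configurable) or stay constant; targets respond through the kinetic model
evaluated in its periodic regime (3 periods of burn-in); intron-layer
counts are Poisson around depth-scaled `u`, exon-layer counts around
depth-scaled `s` — which states the core modelling assumption (intronic
reads ≈ unspliced mRNA) explicitly. Defaults: samples every 2 h over one
24 h cycle, 4 replicates, 2·10⁶ expected reads per sample, 8 targets per
TF (one intronless, to exercise the eligibility rules), log-normal
constant background genes.

Two generator conditions model what Poisson sampling alone misses:

* **Background library share** (default 0.95): background genes are
  scaled so the planted regulon is a small minority of reads, as a real
  regulon is of a transcriptome. Without this, CPM compositionality makes
  *every* constant gene oscillate measurably in anti-phase with the
  planted regulon.
* **Biological noise** (default CV 0.2): mean-preserving log-normal
  factor per gene and sample, shared between a gene's intron and exon
  layers — inter-replicate expression variability, not measurement noise.
  Pure Poisson counts at 2M depth are so clean that a ≈1% compositional
  ripple is called rhythmic essentially always; overdispersion at the
  level routinely seen in bulk replicates restores an honest null
  (planted flat TFs classified non-rhythmic in ≈94% of seeds).

What the generator does **not** emulate: mapping ambiguity and intronic
poly-T priming artefacts, gene length effects, batch structure, shared
library-preparation noise across genes, single-cell dropout beyond
binomial thinning, and repressive regulation. Passing the recovery tests
therefore shows the estimators are correct under the stated kinetic and
sampling model — not that any particular real dataset will behave as
cleanly.

One top-level seed is split deterministically per stage (kinetics,
counts, background), so fixtures reproduce byte-for-byte.

## Problem sizes

The shipped studies use 100 τ-leap cells for the half-life benchmark
(6 genes per bin), 1000 cells for the τ-leap/ODE cross-check, 20-cell
sweeps per capture efficiency, 20 generator seeds for the end-to-end and
clustering recoveries, and 1000 draws for the random-regulon and
type-I-error calibrations — sizes at which every reported contrast is
far larger than its standard error.

## Known limitations

* The regulon-mean estimator ignores edge weights and repression; signed
  or weighted variants are deliberately out of scope.
* CPM compositionality couples genes; on real data a strongly induced
  pathway can masquerade as coordinated repression elsewhere.
* The cosinor tests one harmonic at one fixed period; non-sinusoidal
  rhythms are under-called relative to ensemble detectors.
* Phase differences saturate near ±period/2 and wrap; a TF whose exon lag
  exceeds half a period would appear to lead.
* The τ-leap scheme needs `dt` small against `1/β`; at the default grid
  and Ω this holds, and a warning fires when it does not.
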