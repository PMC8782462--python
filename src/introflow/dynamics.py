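"""Time-series analyses of TF activity: rhythmicity, phase, surrogate
correlation, per-gene performance, replicate robustness and modules.

Rhythmicity is assessed by a single-harmonic cosinor regression at a
fixed period (24 h for circadian data): x(t) = m + a*cos(wt) + b*sin(wt)
fitted by least squares, with the F-test of (a, b) = 0 giving the
p-value, amplitude sqrt(a^2 + b^2) and the fitted peak time as phase.
This is a transparent closed-form detector; ensemble detectors that
combine several period tests can be more sensitive on non-sinusoidal
shapes, so absolute counts of rhythmic TFs are not comparable across
detectors.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "RhythmResult",
    "CorrelationResult",
    "ModulePartition",
    "cosinor_test",
    "classify_tf",
    "phase_difference",
    "interpolate_linear",
    "correlate_with_surrogate",
    "per_gene_performance",
    "replicate_robustness",
    "cluster_modules",
    "target_intron_length_association",
]


@dataclass
class RhythmResult:
    """Fixed-period rhythmicity call for one series."""

    tf: str
    p_value: float
    amplitude: float
    phase: float  # fitted peak time, in [0, period)
    period: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")
        if not (0.0 <= self.phase < self.period):
            raise ValueError(f"phase {self.phase} outside [0, {self.period})")


@dataclass
class CorrelationResult:
    """Pearson correlation between two (possibly resampled) series."""

    label: str
    r: float
    n: int
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("correlation needs at least 3 points")
        if not (np.isnan(self.r) or -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"correlation out of range: {self.r}")


@dataclass
class ModulePartition:
    """Two-module partition of TFs from correlation-distance clustering."""

    labels: pd.Series  # tf -> 1 or 2
    linkage_matrix: np.ndarray

    def __post_init__(self) -> None:
        counts = self.labels.value_counts()
        if len(counts) != 2 or (counts == 0).any():
            raise ValueError("partition must contain exactly two non-empty modules")

    def module(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])


def cosinor_test(series, times, period: float = 24.0, tf: str = "") -> RhythmResult:
    """Single-harmonic cosinor fit at fixed ``period``.

    Requires >= 5 points spanning at least half a period. A constant
    series is reported as non-rhythmic (p = 1, amplitude 0) with a
    warning rather than an error.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("series and times must have the same length")
    if len(y) < 5:
        raise ValueError(f"need >= 5 time points, got {len(y)}")
    if t.max() - t.min() < period / 2:
        raise ValueError(
            f"time span {t.max() - t.min():g} h is below half the period ({period / 2:g} h)"
        )
    if np.ptp(y) == 0:
        warnings.warn("constant series: reported as non-rhythmic", stacklevel=2)
        return RhythmResult(tf=tf, p_value=1.0, amplitude=0.0, phase=0.0, period=period)

    omega = 2.0 * np.pi / period
    design = np.column_stack([np.ones_like(t), np.cos(omega * t), np.sin(omega * t)])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    sse_full = float(np.sum((y - fitted) ** 2))
    sse_null = float(np.sum((y - y.mean()) ** 2))
    df_resid = len(y) - 3
    if df_resid <= 0:
        raise ValueError("not enough degrees of freedom for the cosinor F-test")
    if sse_full <= 1e-14 * sse_null:
        p_value = 0.0
    else:
        f_stat = ((sse_null - sse_full) / 2.0) / (sse_full / df_resid)
        p_value = float(stats.f.sf(f_stat, 2, df_resid))
    a, b = coef[1], coef[2]
    amplitude = float(np.hypot(a, b))
    phase = float((period * np.arctan2(b, a) / (2.0 * np.pi)) % period)
    return RhythmResult(tf=tf, p_value=p_value, amplitude=amplitude, phase=phase, period=period)


def classify_tf(intron: RhythmResult, exon: RhythmResult, alpha: float = 0.05) -> str:
    """Concordance class of intron- vs exon-based rhythmicity calls:
    ``class1`` both rhythmic, ``class2`` intron only, ``class3`` exon
    only, ``none`` neither."""
    if intron.tf and exon.tf and intron.tf != exon.tf:
        raise ValueError(f"mismatched TFs: {intron.tf!r} vs {exon.tf!r}")
    in_r = intron.p_value < alpha
    ex_r = exon.p_value < alpha
    if in_r and ex_r:
        return "class1"
    if in_r:
        return "class2"
    if ex_r:
        return "class3"
    return "none"


def phase_difference(phase_exon: float, phase_intron: float, period: float = 24.0) -> float:
    """Signed circular phase offset, wrapped to (-period/2, period/2].

    Positive values mean the exon-based phase lags behind the
    intron-based phase.
    """
    for name, p in (("phase_exon", phase_exon), ("phase_intron", phase_intron)):
        if not (0.0 <= p < period):
            raise ValueError(f"{name} must lie in [0, {period}), got {p}")
    diff = (phase_exon - phase_intron) % period
    if diff > period / 2:
        diff -= period
    return diff


def interpolate_linear(series, times, target_times) -> np.ndarray:
    """Piecewise-linear resampling; extrapolation is refused."""
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    tt = np.asarray(target_times, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    if tt.min() < t[0] or tt.max() > t[-1]:
        raise ValueError(
            f"target times [{tt.min():g}, {tt.max():g}] extend beyond the observed "
            f"range [{t[0]:g}, {t[-1]:g}]"
        )
    return np.interp(tt, t, y)


def correlate_with_surrogate(
    activity,
    activity_times,
    surrogate,
    surrogate_times,
    grid: np.ndarray | None = None,
    step: float = 0.5,
    label: str = "activity_vs_surrogate",
) -> CorrelationResult:
    """Pearson correlation of an activity series with an independent
    surrogate of TF activity (e.g. genome-wide DNA-binding signal),
    after linear interpolation of both onto a shared grid (default:
    ``step``-spaced points over the overlapping time range)."""
    at = np.asarray(activity_times, dtype=float)
    st = np.asarray(surrogate_times, dtype=float)
    if grid is None:
        lo = max(at.min(), st.min())
        hi = min(at.max(), st.max())
        grid = lo + step * np.arange(int(np.floor((hi - lo) / step + 1e-9)) + 1)
    grid = np.asarray(grid, dtype=float)
    if len(grid) < 3:
        raise ValueError(f"shared grid has {len(grid)} points; need >= 3")
    a = interpolate_linear(activity, at, grid)
    s = interpolate_linear(surrogate, st, grid)
    r, p = stats.pearsonr(a, s)
    return CorrelationResult(label=label, r=float(r), n=len(grid), p_value=float(p))


def per_gene_performance(
    intron_cpm: pd.DataFrame,
    exon_cpm: pd.DataFrame,
    surrogate,
    half_lives: pd.Series | None = None,
    min_cpm: float = 1.0,
) -> tuple[pd.DataFrame, CorrelationResult | None]:
    """Per-gene comparison of intron vs exon tracking of a TF surrogate.

    Genes must be high-expressing (mean intron CPM and mean exon CPM
    above ``min_cpm``). Per gene, the Pearson correlations of the intron
    and exon series with the surrogate are computed; genes with both
    correlations positive get ratio r_intron / r_exon. When half-lives
    are supplied, the correlation of that ratio with half-life is
    reported (longer-lived mRNA should degrade the exon readout more,
    giving a positive association).
    """
    if intron_cpm.shape[1] < 3:
        raise ValueError("need >= 3 time points")
    surrogate = np.asarray(surrogate, dtype=float)
    high = (intron_cpm.mean(axis=1) > min_cpm) & (exon_cpm.mean(axis=1) > min_cpm)
    rows = []
    for gene in intron_cpm.index[high]:
        iv = intron_cpm.loc[gene].to_numpy(dtype=float)
        ev = exon_cpm.loc[gene].to_numpy(dtype=float)
        if np.ptp(iv) == 0 or np.ptp(ev) == 0:
            continue
        r_i = float(stats.pearsonr(iv, surrogate)[0])
        r_e = float(stats.pearsonr(ev, surrogate)[0])
        ratio = r_i / r_e if (r_i > 0 and r_e > 0) else np.nan
        hl = float(half_lives.get(gene, np.nan)) if half_lives is not None else np.nan
        rows.append((gene, r_i, r_e, ratio, hl))
    table = pd.DataFrame(rows, columns=["gene", "r_intron", "r_exon", "ratio", "half_life"])
    table = table.set_index("gene")
    usable = table.dropna(subset=["ratio"])
    if usable.empty:
        warnings.warn("no gene with both correlations positive", stacklevel=2)
        return table, None
    summary = None
    if half_lives is not None:
        with_hl = usable.dropna(subset=["half_life"])
        if len(with_hl) >= 3:
            r, p = stats.pearsonr(with_hl["ratio"], with_hl["half_life"])
            summary = CorrelationResult(label="ratio_vs_half_life", r=float(r),
                                        n=len(with_hl), p_value=float(p))
    return table, summary


def replicate_robustness(
    replicate_series: pd.DataFrame,
    times,
    period: float = 24.0,
    alpha: float = 0.05,
    subsets: str = "leave-one-out",
) -> float:
    """Fraction of replicate-downsampling attempts calling the series
    rhythmic.

    ``replicate_series`` is replicates x time points. Each attempt drops
    replicates (default: leave-one-out; ``subsets='all'`` uses every
    proper subset of size >= 2), averages the remainder, and runs the
    cosinor test; the returned fraction is #(p < alpha) / #attempts.
    """
    reps = np.asarray(replicate_series, dtype=float)
    if reps.shape[0] < 3:
        raise ValueError(f"need >= 3 replicates, got {reps.shape[0]}")
    n = reps.shape[0]
    if subsets == "leave-one-out":
        combos = [tuple(j for j in range(n) if j != i) for i in range(n)]
    elif subsets == "all":
        combos = [
            c for k in range(2, n) for c in itertools.combinations(range(n), k)
        ]
    else:
        raise ValueError(f"unknown subsets rule {subsets!r}")
    hits = 0
    for combo in combos:
        mean_series = reps[list(combo)].mean(axis=0)
        res = cosinor_test(mean_series, times, period=period)
        hits += res.p_value < alpha
    return hits / len(combos)


def cluster_modules(activity: pd.DataFrame, k: int = 2) -> ModulePartition:
    """Partition TFs into co-active modules by correlation distance.

    Pairwise Pearson correlation between TF activity series, distance
    1 - r, agglomerative average-linkage clustering, tree cut at ``k``
    (default two modules). Constant series are excluded with a warning.
    """
    if activity.shape[1] < 3:
        raise ValueError("need >= 3 time points")
    constant = activity.std(axis=1, ddof=0) == 0
    if constant.any():
        warnings.warn(
            f"constant activity series excluded from clustering: {list(activity.index[constant])}",
            stacklevel=2,
        )
        activity = activity.loc[~constant]
    if activity.shape[0] < 4:
        raise ValueError(f"need >= 4 non-constant TFs, got {activity.shape[0]}")
    corr = np.corrcoef(activity.to_numpy(dtype=float))
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="average")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ModulePartition(labels=pd.Series(labels, index=activity.index), linkage_matrix=z)


def target_intron_length_association(
    phase_diffs,
    mean_intron_lengths,
    label: str = "phase_diff_vs_intron_length",
) -> CorrelationResult:
    """Pearson association between per-TF exon-minus-intron phase
    differences and the mean intron length of the TF's targets (a check
    that phase shifts are not a trivial transcript-length artefact)."""
    x = np.asarray(phase_diffs, dtype=float)
    y = np.asarray(mean_intron_lengths, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must have equal length")
    if len(x) < 4:
        raise ValueError(f"need >= 4 TFs, got {len(x)}")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(label=label, r=float(r), n=len(x), p_value=float(p))
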