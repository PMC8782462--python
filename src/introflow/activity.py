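"""TF activity estimation from CPM matrices and regulons.

The core estimator is deliberately simple: a TF's activity in a sample
is the unweighted mean CPM of its regulon targets. Run on the intron
layer it reads out instantaneous transcription (intronic reads proxy
unspliced pre-mRNA); on the exon layer it reads out the mRNA pool, which
integrates transcription over the targets' half-lives. A rank-based
recovery-curve (AUC) variant is provided for comparison, along with
z-scoring, fold-change and empirical-null utilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import CPMMatrix

__all__ = [
    "ActivityMatrix",
    "tfa_mean",
    "tfa_matrix",
    "tfa_rank_auc",
    "rank_auc_matrix",
    "zscore_series",
    "fold_change",
    "null_percentile",
    "expressed_tf_filter",
]


@dataclass
class ActivityMatrix:
    """TFs x samples activity estimates with method/layer provenance."""

    values: pd.DataFrame  # tf x sample
    method: str  # "mean" or "rank_auc"
    layer: str  # "intron", "exon" or "total"
    regulon_targets: dict[str, list[str]] = field(default_factory=dict)
    sample_time: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.method not in ("mean", "rank_auc"):
            raise ValueError(f"unknown method {self.method!r}")
        if not np.isfinite(self.values.values).all():
            raise ValueError("activity values must be finite")
        if self.method == "rank_auc":
            v = self.values.values
            if (v < 0).any() or (v > 1).any():
                raise ValueError("rank_auc activities must lie in [0, 1]")


def _eligible_targets(
    cpm: CPMMatrix, targets, matched_gene_set: bool
) -> list[str]:
    present = [t for t in targets if t in cpm.gene_ids]
    dropped = [t for t in targets if t not in cpm.gene_ids]
    if dropped:
        warnings.warn(
            f"{len(dropped)} regulon target(s) absent from the expression matrix: {dropped}",
            stacklevel=3,
        )
    if cpm.layer == "intron" or matched_gene_set:
        # intronless genes carry no intronic signal; the matched_gene_set
        # switch applies the same exclusion to other layers so that
        # layer-vs-layer comparisons use identical gene sets
        if cpm.has_intron is None:
            raise ValueError("intron-eligibility filter requires has_intron annotation")
        present = [t for t in present if bool(cpm.has_intron.get(t, False))]
    return present


def tfa_mean(
    cpm: CPMMatrix,
    targets,
    tf: str = "TF",
    matched_gene_set: bool = False,
) -> pd.Series:
    """Mean-CPM activity of one TF across samples.

    Unweighted mean of the layer's CPM over eligible targets. On the
    intron layer, intronless genes are excluded (they cannot produce
    intronic reads); with ``matched_gene_set`` the same exclusion is
    applied on any layer, for head-to-head layer comparisons. Targets
    absent from the matrix are dropped with a warning.
    """
    eligible = _eligible_targets(cpm, targets, matched_gene_set)
    if not eligible:
        raise ValueError(f"no eligible target of TF {tf!r} present in the {cpm.layer} matrix")
    return cpm.values.loc[eligible].mean(axis=0)


def tfa_matrix(
    cpm: CPMMatrix,
    regulon_map: dict[str, list[str]],
    matched_gene_set: bool = False,
) -> ActivityMatrix:
    """Mean-method activities for several TFs; TFs with no eligible
    target are dropped with a warning rather than failing the batch."""
    rows = {}
    used = {}
    for tf, targets in regulon_map.items():
        try:
            rows[tf] = tfa_mean(cpm, targets, tf=tf, matched_gene_set=matched_gene_set)
        except ValueError:
            warnings.warn(f"TF {tf!r} skipped: no eligible target in matrix", stacklevel=2)
            continue
        used[tf] = _eligible_targets(cpm, targets, matched_gene_set)
    if not rows:
        raise ValueError("no TF had any eligible target")
    values = pd.DataFrame(rows).T
    values = values.loc[list(rows)]
    return ActivityMatrix(values=values, method="mean", layer=cpm.layer,
                          regulon_targets=used, sample_time=cpm.sample_time)


def tfa_rank_auc(expression: pd.Series, targets, top_fraction: float = 0.05) -> float:
    """Recovery-curve AUC activity score for one sample.

    Genes are ranked by descending expression (ties broken by gene id);
    the recovery curve counts regulon hits along the ranking, truncated
    at ``top_fraction`` of all genes; the area is normalised by the
    maximum achievable area so the score lies in [0, 1]. Invariant under
    any strictly increasing transform of the expression values.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError(f"top_fraction must lie in (0, 1], got {top_fraction}")
    expression = pd.Series(expression)
    target_set = set(targets) & set(expression.index)
    if not target_set:
        warnings.warn("no regulon target in the expression universe; score 0", stacklevel=2)
        return 0.0
    order = expression.sort_index().sort_values(ascending=False, kind="stable").index
    k = max(1, math.ceil(top_fraction * len(order)))
    hits = np.fromiter((g in target_set for g in order[:k]), dtype=float, count=k)
    recovery = np.cumsum(hits)
    m = len(target_set)
    max_recovery = np.minimum(np.arange(1, k + 1), m)
    return float(recovery.sum() / max_recovery.sum())


def rank_auc_matrix(
    cpm: CPMMatrix,
    regulon_map: dict[str, list[str]],
    top_fraction: float = 0.05,
) -> ActivityMatrix:
    """Per-sample rank-AUC activities for several TFs."""
    values = pd.DataFrame(
        {
            sample: {
                tf: tfa_rank_auc(cpm.values[sample], targets, top_fraction)
                for tf, targets in regulon_map.items()
            }
            for sample in cpm.sample_ids
        }
    )
    values = values.loc[list(regulon_map), list(cpm.sample_ids)]
    return ActivityMatrix(values=values, method="rank_auc", layer=cpm.layer,
                          regulon_targets={t: list(g) for t, g in regulon_map.items()},
                          sample_time=cpm.sample_time)


def zscore_series(x) -> np.ndarray:
    """(x - mean) / SD across ordered samples; a constant series yields
    zeros with a warning rather than NaNs."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples to z-score")
    sd = x.std(ddof=0)
    if sd == 0:
        warnings.warn("constant series: z-scores set to 0", stacklevel=2)
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def fold_change(x, baseline_index: int = 0) -> float:
    """Max activity over samples divided by the baseline sample's value."""
    x = np.asarray(x, dtype=float)
    baseline = x[baseline_index]
    if baseline <= 0:
        raise ValueError(f"baseline value must be positive, got {baseline}")
    return float(x.max() / baseline)


def null_percentile(actual: float, null_stats) -> tuple[float, float]:
    """Empirical percentile and one-sided p-value of ``actual`` within a
    null distribution (e.g. statistics of random regulons).

    p = (1 + #{null >= actual}) / (1 + n_null), the add-one rule that
    never returns zero; the percentile uses mid-ranking for ties.
    """
    nulls = np.asarray(null_stats, dtype=float)
    if nulls.size < 100:
        raise ValueError(f"need >= 100 null statistics, got {nulls.size}")
    n = nulls.size
    greater_eq = int(np.sum(nulls >= actual))
    below = int(np.sum(nulls < actual))
    equal = int(np.sum(nulls == actual))
    percentile = 100.0 * (below + 0.5 * equal) / n
    p_value = (1.0 + greater_eq) / (1.0 + n)
    return percentile, p_value


def expressed_tf_filter(
    intron_cpm: CPMMatrix, exon_cpm: CPMMatrix, tf_list
) -> list[str]:
    """Retain TFs whose own gene shows non-zero expression (intron CPM +
    exon CPM > 0) in at least one sample; absent TF genes are treated as
    unexpressed with a warning."""
    kept = []
    missing = []
    for tf in tf_list:
        if tf not in intron_cpm.gene_ids or tf not in exon_cpm.gene_ids:
            missing.append(tf)
            continue
        total = intron_cpm.values.loc[tf] + exon_cpm.values.loc[tf]
        if (total > 0).any():
            kept.append(tf)
    if missing:
        warnings.warn(
            f"TF gene(s) absent from the matrix treated as unexpressed: {missing}",
            stacklevel=2,
        )
    return kept
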