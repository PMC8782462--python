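"""Regulon handling: loading, confidence filtering, half-life splits,
random null regulons and ChIP-peak refinement.

A regulon is the set of target genes of one transcription factor, each
edge carrying a regulation mode (activation/repression) and a curation
confidence grade A-E (A strongest). Following common practice with
literature-curated networks, activity estimation uses activating edges
of grade A or B by default; loosening to grade C is supported.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GRADES",
    "RegulonSet",
    "load_regulons",
    "write_regulons",
    "filter_regulon",
    "split_by_halflife",
    "random_regulons",
    "refine_by_peaks",
    "load_halflife_table",
    "load_tss_table",
    "load_tss_from_gtf",
    "load_peaks_bed",
]

GRADES = ("A", "B", "C", "D", "E")
MODES = ("activation", "repression")


@dataclass
class RegulonSet:
    """TF -> signed, confidence-graded target edges."""

    entries: pd.DataFrame  # columns: tf, target, mode, confidence

    def __post_init__(self) -> None:
        required = {"tf", "target", "mode", "confidence"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"regulon table missing columns {sorted(missing)}")
        bad_mode = ~self.entries["mode"].isin(MODES)
        if bad_mode.any():
            raise ValueError(
                f"unknown regulation mode(s): {sorted(self.entries.loc[bad_mode, 'mode'].unique())}"
            )
        bad_grade = ~self.entries["confidence"].isin(GRADES)
        if bad_grade.any():
            raise ValueError(
                f"unknown confidence grade(s): {sorted(self.entries.loc[bad_grade, 'confidence'].unique())}"
            )
        dup = self.entries.duplicated(subset=["tf", "target"])
        if dup.any():
            pairs = self.entries.loc[dup, ["tf", "target"]].itertuples(index=False)
            raise ValueError(f"duplicate (tf, target) pairs: {[tuple(p) for p in pairs]}")
        self.entries = self.entries.reset_index(drop=True)

    def tfs(self) -> list[str]:
        return list(pd.unique(self.entries["tf"]))

    def targets(self, tf: str, max_grade: str = "B", activation_only: bool = True) -> list[str]:
        return filter_regulon(self, tf, max_grade=max_grade, activation_only=activation_only)

    def all_targets(self) -> list[str]:
        return list(pd.unique(self.entries["target"]))


def load_regulons(path) -> RegulonSet:
    """Read a regulon TSV with columns tf, target, mode, confidence."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    return RegulonSet(entries=table)


def write_regulons(regulons: RegulonSet, path) -> None:
    regulons.entries.to_csv(path, sep="\t", index=False)


def filter_regulon(
    regulons: RegulonSet,
    tf: str,
    max_grade: str = "B",
    activation_only: bool = True,
) -> list[str]:
    """Targets of ``tf`` with confidence at or above ``max_grade``
    (A < B < C < D < E) and, by default, activating mode only.

    Order of the input table is preserved (deterministic).
    """
    if max_grade not in GRADES:
        raise ValueError(f"max_grade must be one of {GRADES}, got {max_grade!r}")
    entries = regulons.entries
    if tf not in set(entries["tf"]):
        raise KeyError(f"unknown TF {tf!r}; available TFs: {sorted(set(entries['tf']))}")
    cutoff = GRADES.index(max_grade)
    mask = (entries["tf"] == tf) & entries["confidence"].map(GRADES.index).le(cutoff)
    if activation_only:
        mask &= entries["mode"] == "activation"
    return entries.loc[mask, "target"].tolist()


def split_by_halflife(targets, half_lives: pd.Series) -> tuple[list[str], list[str]]:
    """Median split of a regulon into short- and long-lived sub-regulons.

    Targets without half-life data are excluded; ties at the median are
    broken by lexicographic gene id, and when the annotated count is odd
    the middle gene goes to the short-lived half, so sizes differ by at
    most one.
    """
    half_lives = pd.Series(half_lives)
    annotated = [t for t in targets if t in half_lives.index and pd.notna(half_lives[t])]
    if len(annotated) < 2:
        raise ValueError(
            f"need >= 2 targets with half-life data, got {len(annotated)}"
        )
    ordered = sorted(annotated, key=lambda g: (float(half_lives[g]), g))
    n_short = (len(ordered) + 1) // 2
    return ordered[:n_short], ordered[n_short:]


def random_regulons(
    universe,
    exclude,
    size: int,
    n: int,
    seed: int = 0,
) -> list[list[str]]:
    """Null regulons: ``n`` uniform draws of ``size`` genes, without
    replacement within a draw, from ``universe`` minus ``exclude``.

    Used to build an empirical null for regulon-based statistics: the
    real TF's own targets are excluded so the null carries no signal.
    """
    eligible = sorted(set(universe) - set(exclude))
    if len(eligible) < size:
        raise ValueError(
            f"universe minus excluded targets has {len(eligible)} genes, need {size}"
        )
    rng = np.random.default_rng(seed)
    return [list(rng.choice(eligible, size=size, replace=False)) for _ in range(n)]


def refine_by_peaks(
    targets,
    tss: pd.DataFrame,
    peaks: pd.DataFrame,
    window: int = 2000,
) -> list[str]:
    """Keep targets whose TSS lies within ``window`` bp of a ChIP peak.

    ``tss`` has columns chrom, tss (one row per gene, gene id as index);
    ``peaks`` is BED-like with columns chrom, start, end in half-open
    0-based convention. A target's TSS must fall in
    ``[start - window, end + window)`` of at least one peak on the same
    chromosome. Targets without a TSS entry are dropped with a warning.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in peaks[["chrom", "start", "end"]].itertuples(index=False):
        if start >= end:
            raise ValueError(f"malformed peak {chrom}:{start}-{end} (start >= end)")
        trees.setdefault(chrom, IntervalTree()).addi(start - window, end + window)

    kept = []
    missing = []
    for gene in targets:
        if gene not in tss.index:
            missing.append(gene)
            continue
        row = tss.loc[gene]
        tree = trees.get(row["chrom"])
        if tree is not None and tree.overlaps_point(int(row["tss"])):
            kept.append(gene)
    if missing:
        warnings.warn(f"no TSS annotation for {len(missing)} target(s): {missing}", stacklevel=2)
    return kept


def load_halflife_table(path) -> pd.Series:
    """Read a gene -> half-life (min) TSV with columns gene_id, half_life_min."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    values = table.set_index("gene_id")["half_life_min"].astype(float)
    if (values <= 0).any():
        bad = list(values.index[values <= 0])
        raise ValueError(f"non-positive half-life for gene(s) {bad}")
    return values


def load_tss_table(path) -> pd.DataFrame:
    """Read a TSS TSV with columns gene_id, chrom, strand, tss (0-based)."""
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    table = table.set_index("gene_id")
    if (table["tss"] < 0).any():
        raise ValueError("negative TSS coordinate")
    return table[["chrom", "strand", "tss"]]


_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def load_tss_from_gtf(path) -> pd.DataFrame:
    """Derive one TSS per gene from a GTF: the 5'-most annotated
    transcript start (strand-aware), reported 0-based."""
    records: dict[str, tuple[str, str, int]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "transcript":
                continue
            chrom, start, end, strand, attrs = fields[0], int(fields[3]), int(fields[4]), fields[6], fields[8]
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                continue
            gene = m.group(1)
            tss = start - 1 if strand != "-" else end - 1  # GTF is 1-based inclusive
            if gene not in records:
                records[gene] = (chrom, strand, tss)
            else:
                c, s, t = records[gene]
                better = tss < t if strand != "-" else tss > t
                if better:
                    records[gene] = (chrom, strand, tss)
    table = pd.DataFrame.from_dict(records, orient="index", columns=["chrom", "strand", "tss"])
    table.index.name = "gene_id"
    return table


def load_peaks_bed(path) -> pd.DataFrame:
    """Read BED3 peaks (chrom, start, end; half-open 0-based)."""
    peaks = pd.read_csv(path, sep="\t", header=None, comment="#",
                        names=["chrom", "start", "end"], usecols=[0, 1, 2],
                        dtype={0: str})
    if (peaks["start"] >= peaks["end"]).any():
        bad = peaks[peaks["start"] >= peaks["end"]].iloc[0]
        raise ValueError(f"malformed peak {bad['chrom']}:{bad['start']}-{bad['end']}")
    return peaks
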