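"""Intron/exon read-count containers and counts-per-million normalisation.

The input boundary of the pipeline is a per-gene, per-sample table of
intron-level and exon-level read counts (read assignment to introns and
exons happens upstream). Both layers are normalised against the *shared*
library size — the intron plus exon counts of all genes in the sample:

    CPM_intron(g, j) = 1e6 * intron(g, j) / sum_g'(intron(g', j) + exon(g', j))
    CPM_exon(g, j)   = 1e6 * exon(g, j)   / sum_g'(intron(g', j) + exon(g', j))

so the two layers of one sample sum to exactly one million. No length
normalisation is applied: intronic reads can arise from priming inside
introns, so the effective intron length is unknown.

TSV dialect (version 1): one row per gene; columns ``gene_id``,
``has_intron`` (0/1), then ``<sample>_intron`` and ``<sample>_exon`` for
each sample. Optional sample metadata (``sample_id``, ``time``,
``replicate``) travels in a separate TSV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "CPMMatrix",
    "read_count_table",
    "write_count_table",
    "cpm",
    "total_cpm",
    "average_replicates",
]

LAYERS = ("intron", "exon", "total")


@dataclass
class CountMatrix:
    """Genes x samples read counts with an intron and an exon layer.

    ``has_intron`` records whether the gene has any annotated intron;
    intronless genes carry a structurally zero intron row and are
    excluded from intron-based activity estimates downstream.
    """

    intron: pd.DataFrame
    exon: pd.DataFrame
    has_intron: pd.Series
    sample_time: pd.Series | None = None
    sample_replicate: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.intron.index.equals(self.exon.index):
            raise ValueError("intron and exon layers must share the same gene index")
        if not self.intron.columns.equals(self.exon.columns):
            raise ValueError("intron and exon layers must share the same samples")
        if self.intron.index.has_duplicates:
            dupes = self.intron.index[self.intron.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        for name, layer in (("intron", self.intron), ("exon", self.exon)):
            if (layer.values < 0).any():
                g, s = np.argwhere(layer.values < 0)[0]
                raise ValueError(
                    f"negative {name} count for gene {layer.index[g]!r} in sample "
                    f"{layer.columns[s]!r}"
                )
        self.has_intron = self.has_intron.reindex(self.intron.index)
        if self.has_intron.isna().any():
            missing = self.has_intron.index[self.has_intron.isna()].tolist()
            raise ValueError(f"has_intron flag missing for genes {missing}")
        self.has_intron = self.has_intron.astype(bool)
        bad = (~self.has_intron) & (self.intron.sum(axis=1) > 0)
        if bad.any():
            raise ValueError(
                f"genes flagged intronless but carrying intron counts: {list(self.intron.index[bad])}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.intron.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intron.columns

    def library_size(self) -> pd.Series:
        """Per-sample intron + exon counts summed over all genes."""
        return self.intron.sum(axis=0) + self.exon.sum(axis=0)


@dataclass
class CPMMatrix:
    """Genes x samples counts-per-million values for one layer."""

    values: pd.DataFrame
    layer: str
    has_intron: pd.Series | None = None
    sample_time: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


def cpm(matrix: CountMatrix, layer: str) -> CPMMatrix:
    """Counts-per-million for one layer against the shared library size.

    The denominator is the sample's intron plus exon counts over *all*
    genes — deliberately shared between layers, so intron CPM of a gene
    responds to changes in any gene's exon counts and the two layers of
    a sample jointly sum to one million.
    """
    if layer not in ("intron", "exon"):
        raise ValueError(f"layer must be 'intron' or 'exon', got {layer!r}")
    lib = matrix.library_size()
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s) {list(zero.index)}")
    counts = matrix.intron if layer == "intron" else matrix.exon
    values = 1e6 * counts / lib
    return CPMMatrix(values=values, layer=layer, has_intron=matrix.has_intron,
                     sample_time=matrix.sample_time)


def total_cpm(matrix: CountMatrix) -> CPMMatrix:
    """Intron CPM plus exon CPM per gene (the 'total reads' layer)."""
    intron = cpm(matrix, "intron")
    exon = cpm(matrix, "exon")
    return CPMMatrix(values=intron.values + exon.values, layer="total",
                     has_intron=matrix.has_intron, sample_time=matrix.sample_time)


def average_replicates(cpm_matrix: CPMMatrix, groups: pd.Series) -> CPMMatrix:
    """Average CPM values across replicate samples.

    ``groups`` maps sample id to a group label (typically the time
    point); averaging happens on CPM, not raw counts, so deeper
    replicates do not dominate.
    """
    groups = groups.reindex(cpm_matrix.sample_ids)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValueError(f"no group label for sample(s) {missing}")
    averaged = cpm_matrix.values.T.groupby(groups, sort=True).mean().T
    time = None
    if cpm_matrix.sample_time is not None:
        time = cpm_matrix.sample_time.groupby(groups, sort=True).mean()
        time = time.reindex(averaged.columns)
    return CPMMatrix(values=averaged, layer=cpm_matrix.layer,
                     has_intron=cpm_matrix.has_intron, sample_time=time)


def read_count_table(path, samples_path=None) -> CountMatrix:
    """Read a counts TSV (dialect v1) into a :class:`CountMatrix`.

    Raises a parse error naming the offending gene/sample for negative
    counts, duplicate gene ids or ragged rows.
    """
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "has_intron"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if table["gene_id"].duplicated().any():
        dupes = table.loc[table["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dupes}")
    if table.isna().any().any():
        row = int(np.flatnonzero(table.isna().any(axis=1).to_numpy())[0])
        gene = table["gene_id"].iloc[row]
        raise ValueError(f"{path}: ragged/missing values in row for gene {gene!r}")
    table = table.set_index("gene_id")

    suffixes = {"_intron": {}, "_exon": {}}
    for col in table.columns:
        if col == "has_intron":
            continue
        for suf in suffixes:
            if col.endswith(suf):
                suffixes[suf][col[: -len(suf)]] = col
    samples = sorted(suffixes["_intron"])
    if samples != sorted(suffixes["_exon"]):
        raise ValueError(f"{path}: intron/exon columns do not pair up")
    if not samples:
        raise ValueError(f"{path}: no <sample>_intron/<sample>_exon column pairs found")

    intron = table[[suffixes["_intron"][s] for s in samples]].copy()
    intron.columns = samples
    exon = table[[suffixes["_exon"][s] for s in samples]].copy()
    exon.columns = samples

    sample_time = sample_replicate = None
    if samples_path is not None:
        meta = pd.read_csv(samples_path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
        meta = meta.reindex(samples)
        if "time" in meta.columns:
            sample_time = meta["time"].astype(float)
        if "replicate" in meta.columns:
            sample_replicate = meta["replicate"]

    return CountMatrix(
        intron=intron.astype(np.int64),
        exon=exon.astype(np.int64),
        has_intron=table["has_intron"].astype(bool),
        sample_time=sample_time,
        sample_replicate=sample_replicate,
    )


def write_count_table(matrix: CountMatrix, path, samples_path=None) -> None:
    """Write a :class:`CountMatrix` in the TSV dialect read by
    :func:`read_count_table`."""
    out = pd.DataFrame(index=matrix.gene_ids)
    out["has_intron"] = matrix.has_intron.astype(int)
    for s in matrix.sample_ids:
        out[f"{s}_intron"] = matrix.intron[s]
        out[f"{s}_exon"] = matrix.exon[s]
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
    if samples_path is not None:
        meta = pd.DataFrame(index=pd.Index(matrix.sample_ids, name="sample_id"))
        if matrix.sample_time is not None:
            meta["time"] = matrix.sample_time
        if matrix.sample_replicate is not None:
            meta["replicate"] = matrix.sample_replicate
        meta.to_csv(samples_path, sep="\t")


def read_cpm_table(path, layer: str = "total") -> CPMMatrix:
    """Read a pre-normalised expression table (gene_id x samples TSV).

    Escape hatch for datasets distributed as RPKM or other per-gene
    normalised values; they are treated as-is, tagged with ``layer``.
    """
    values = pd.read_csv(path, sep="\t", index_col="gene_id")
    return CPMMatrix(values=values.astype(float), layer=layer)


def write_cpm_table(cpm_matrix: CPMMatrix, path) -> None:
    out = cpm_matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")
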