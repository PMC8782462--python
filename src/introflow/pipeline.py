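"""End-to-end orchestration: counts -> CPM -> regulon filtering -> TF
activities -> rhythm/correlation/clustering, with a machine-readable
report.

The pipeline is a thin composition of the library modules; every stage
failure is re-raised with the stage name and the offending input so a
broken run points at its cause.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .activity import tfa_matrix
from .dynamics import classify_tf, cluster_modules, correlate_with_surrogate, cosinor_test, phase_difference
from .quantify import average_replicates, cpm, read_count_table, total_cpm, write_cpm_table
from .regulons import filter_regulon, load_regulons


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the input."""


@dataclass
class PipelineConfig:
    counts: str
    regulons: str
    samples: str | None = None
    surrogate: str | None = None
    max_grade: str = "B"
    period: float = 24.0
    alpha: float = 0.05
    layers: tuple[str, ...] = ("intron", "exon", "total")
    matched_gene_set: bool = False
    outdir: str = "introflow_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"config: unknown key(s) {sorted(unknown)}")
        if "layers" in raw:
            raw["layers"] = tuple(raw["layers"])
        return cls(**raw)


def _stage(name: str, detail: str = ""):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed on {detail or 'its input'}: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis and write TSV/JSON outputs.

    Returns the report dict (also written to ``<outdir>/report.json``):
    per TF and layer the cosinor p-value, amplitude and phase; the
    intron/exon concordance class and phase difference; optional
    surrogate correlations; and the two-module partition when at least
    four TFs are analysable.
    """
    for name, path in (("counts", config.counts), ("regulons", config.regulons)):
        if not Path(path).exists():
            raise PipelineError(f"stage 'inputs' failed: missing {name} file {path!r}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("quantify", config.counts):
        matrix = read_count_table(config.counts, samples_path=config.samples)
        layers = {}
        for layer in config.layers:
            layers[layer] = total_cpm(matrix) if layer == "total" else cpm(matrix, layer)
        if matrix.sample_time is not None:
            by_time = matrix.sample_time
            layers = {k: average_replicates(v, by_time) for k, v in layers.items()}
            times = layers[config.layers[0]].values.columns.astype(float).to_numpy()
        else:
            times = None

    with _stage("regulons", config.regulons):
        regulon_set = load_regulons(config.regulons)
        regulon_map = {
            tf: filter_regulon(regulon_set, tf, max_grade=config.max_grade)
            for tf in regulon_set.tfs()
        }
        regulon_map = {tf: tg for tf, tg in regulon_map.items() if tg}

    with _stage("tfa"):
        activities = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for layer, cpm_matrix in layers.items():
                activities[layer] = tfa_matrix(
                    cpm_matrix, regulon_map, matched_gene_set=config.matched_gene_set
                )
        for layer, act in activities.items():
            write_cpm_table_like(act.values, outdir / f"tfa_{layer}.tsv", "tf")

    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "max_grade": config.max_grade,
            "period": config.period,
            "alpha": config.alpha,
            "matched_gene_set": config.matched_gene_set,
        },
        "tfs": {},
    }

    if times is not None:
        with _stage("rhythm"):
            for tf in activities[config.layers[0]].values.index:
                entry = {}
                results = {}
                for layer in ("intron", "exon"):
                    if layer not in activities or tf not in activities[layer].values.index:
                        continue
                    series = activities[layer].values.loc[tf].to_numpy()
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = cosinor_test(series, times, period=config.period, tf=tf)
                    results[layer] = res
                    entry[layer] = {
                        "p_value": res.p_value,
                        "amplitude": res.amplitude,
                        "phase": res.phase,
                    }
                if "intron" in results and "exon" in results:
                    entry["class"] = classify_tf(results["intron"], results["exon"], config.alpha)
                    entry["phase_difference"] = phase_difference(
                        results["exon"].phase, results["intron"].phase, config.period
                    )
                report["tfs"][tf] = entry

    if config.surrogate is not None and times is not None:
        with _stage("correlate", config.surrogate):
            surrogate = pd.read_csv(config.surrogate, sep="\t", index_col="time")
            for tf in surrogate.columns:
                if "intron" not in activities or tf not in activities["intron"].values.index:
                    continue
                res = correlate_with_surrogate(
                    activities["intron"].values.loc[tf].to_numpy(), times,
                    surrogate[tf].to_numpy(), surrogate.index.to_numpy(dtype=float),
                    label=f"{tf}_intron_vs_surrogate",
                )
                report["tfs"].setdefault(tf, {})["surrogate_r_intron"] = res.r

    intron_act = activities.get("intron")
    if times is not None and intron_act is not None and intron_act.values.shape[0] >= 4:
        with _stage("cluster"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                partition = cluster_modules(intron_act.values, k=2)
            report["modules"] = {tf: int(m) for tf, m in partition.labels.items()}
            pd.Series(report["modules"], name="module").rename_axis("tf").to_csv(
                outdir / "modules.tsv", sep="\t"
            )

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def write_cpm_table_like(values: pd.DataFrame, path, index_name: str) -> None:
    out = values.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t")
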