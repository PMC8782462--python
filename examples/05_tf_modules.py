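"""Discovering temporally opposing TF modules by correlation clustering.

Plants eight rhythmic TFs in two anti-phase groups (peaks at 6 h and
18 h), estimates intron-based activities, and clusters the TFs by
Pearson correlation distance into two modules.
"""

from introflow import (
    FixtureConfig,
    TFSpec,
    average_replicates,
    cluster_modules,
    cpm,
    filter_regulon,
    generate_fixture,
    tfa_matrix,
)

specs = tuple(
    TFSpec(f"TF{i + 1}", rhythmic=True, phase=(6.0 if i < 4 else 18.0),
           halflife_min=300.0, module=(1 if i < 4 else 2))
    for i in range(8)
)
fx = generate_fixture(FixtureConfig(tf_specs=specs, targets_per_tf=4, seed=0))
intron = average_replicates(cpm(fx.counts, "intron"), fx.counts.sample_time)
act = tfa_matrix(intron, {tf: filter_regulon(fx.regulons, tf) for tf in fx.regulons.tfs()})

partition = cluster_modules(act.values, k=2)
for label in (1, 2):
    print(f"module {label}: {', '.join(sorted(partition.module(label)))}")
print("planted truth: TF1-TF4 peak at 6 h, TF5-TF8 at 18 h")
print("correlation-distance clustering recovers the two anti-phase groups — "
      "TFs that\nrise together in time share a module regardless of their "
      "absolute activity scale.")
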