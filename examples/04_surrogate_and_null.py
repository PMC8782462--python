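"""Validating an activity estimate against a surrogate, with a null model.

Correlates the intron-based activity with an independent surrogate of
TF activity (here the planted series; in real studies, e.g. genome-wide
DNA-binding signal) on a 0.5 h interpolation grid, then places that
correlation within the distribution of 1000 random regulons drawn from
non-target genes.
"""

import numpy as np

from introflow import (
    FixtureConfig,
    average_replicates,
    correlate_with_surrogate,
    cpm,
    filter_regulon,
    generate_fixture,
    null_percentile,
    random_regulons,
    tfa_mean,
)

fx = generate_fixture(FixtureConfig(seed=0))
intron = average_replicates(cpm(fx.counts, "intron"), fx.counts.sample_time)
times = intron.values.columns.to_numpy(dtype=float)
surrogate = fx.surrogate["TF1"].to_numpy()
sur_times = fx.surrogate.index.to_numpy(dtype=float)

targets = filter_regulon(fx.regulons, "TF1")
actual = correlate_with_surrogate(
    tfa_mean(intron, targets).to_numpy(), times, surrogate, sur_times
).r

universe = [g for g in intron.gene_ids
            if g.startswith("bg") and fx.counts.has_intron[g]]
nulls = [
    correlate_with_surrogate(
        tfa_mean(intron, reg).to_numpy(), times, surrogate, sur_times
    ).r
    for reg in random_regulons(universe, targets, size=len(targets), n=1000, seed=1)
]
percentile, p = null_percentile(actual, np.array(nulls))
print(f"corr(intron-based TFA, surrogate) = {actual:.3f}")
print(f"random-regulon null: percentile = {percentile:.1f}, empirical p = {p:.4f}")
print("the real regulon's correlation sits far above the null distribution, "
      "so the\nsignal comes from the regulon's composition, not from "
      "normalisation artefacts.")
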