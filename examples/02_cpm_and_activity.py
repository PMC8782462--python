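"""From a count table to intron- and exon-based TF activities.

Generates a synthetic experiment with one planted rhythmic TF, computes
shared-denominator CPM for both layers, averages replicates, and
compares the two activity estimates with the planted activity.
"""

import numpy as np

from introflow import (
    FixtureConfig,
    average_replicates,
    cpm,
    filter_regulon,
    generate_fixture,
    tfa_mean,
)

fx = generate_fixture(FixtureConfig(seed=0))
intron = average_replicates(cpm(fx.counts, "intron"), fx.counts.sample_time)
exon = average_replicates(cpm(fx.counts, "exon"), fx.counts.sample_time)

targets = filter_regulon(fx.regulons, "TF1")  # activating edges, grade A/B
act_intron = tfa_mean(intron, targets)  # intronless targets are excluded here
act_exon = tfa_mean(exon, targets)

truth = fx.surrogate["TF1"].to_numpy()
r_i = np.corrcoef(act_intron, truth)[0, 1]
r_e = np.corrcoef(act_exon, truth)[0, 1]
print(f"regulon size {len(targets)}; planted TF peaks at "
      f"{fx.truth.phases['TF1']:.0f} h")
print(f"corr(intron-based TFA, planted activity) = {r_i:.3f}")
print(f"corr(exon-based TFA,   planted activity) = {r_e:.3f}")
print("the intron-based estimate follows the planted activity more closely "
      "because\nits targets are long-lived: their mature mRNA pool lags and "
      "smooths the signal.")
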