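"""Circadian rhythmicity and phase of TF activities by cosinor regression.

Fits a fixed 24 h sinusoid to intron- and exon-based activities of a
planted rhythmic TF, classifies the TF by which layers are rhythmic,
and reports the exon-minus-intron peak phase difference.
"""

from introflow import (
    FixtureConfig,
    average_replicates,
    classify_tf,
    cosinor_test,
    cpm,
    filter_regulon,
    generate_fixture,
    phase_difference,
    tfa_mean,
)

fx = generate_fixture(FixtureConfig(seed=0))
intron = average_replicates(cpm(fx.counts, "intron"), fx.counts.sample_time)
exon = average_replicates(cpm(fx.counts, "exon"), fx.counts.sample_time)
times = intron.values.columns.to_numpy(dtype=float)

targets = filter_regulon(fx.regulons, "TF1")
res_i = cosinor_test(tfa_mean(intron, targets).to_numpy(), times, period=24.0, tf="TF1")
res_e = cosinor_test(tfa_mean(exon, targets).to_numpy(), times, period=24.0, tf="TF1")

print(f"intron layer: p = {res_i.p_value:.2e}, peak phase = {res_i.phase:.2f} h")
print(f"exon layer:   p = {res_e.p_value:.2e}, peak phase = {res_e.phase:.2f} h")
print(f"class: {classify_tf(res_i, res_e)} (both layers rhythmic)")
diff = phase_difference(res_e.phase, res_i.phase)
print(f"phase difference (exon - intron) = {diff:+.2f} h")
print("the planted peak is at 6 h; the intron phase recovers it, and the "
      "positive\ndifference shows the exon-based estimate lagging behind — "
      "the mRNA pool peaks\nhours after transcription does.")
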