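"""Why intronic reads track TF activity: a stochastic kinetics benchmark.

Simulates an oscillating TF driving target genes whose mRNA half-lives
span 20 min to 2000 min, in 50 cells with the tau-leap scheme, and
correlates each gene's unspliced (u) and spliced (s) levels with the TF.
"""

import numpy as np

from introflow import TFWaveformParams, ensemble_benchmark

half_lives = [20, 100, 500, 1000, 2000]  # min
wf = TFWaveformParams(noise_enabled=True)  # 0.06-0.5 uM oscillation, 5.5 h period
bench = ensemble_benchmark(np.repeat(half_lives, 3), wf, n_cells=50, seed=0)

print("half-life (min)   corr(u, TF)   corr(s, TF)")
for hl, cu, cs in zip(
    half_lives,
    bench.corr_u_mean.reshape(5, 3).mean(axis=1),
    bench.corr_s_mean.reshape(5, 3).mean(axis=1),
):
    print(f"{hl:>14}   {cu:>11.3f}   {cs:>11.3f}")
print(f"\nregulon-mean estimate: corr(u-based, TF) = {bench.regulon_corr_u:.3f}, "
      f"corr(s-based, TF) = {bench.regulon_corr_s:.3f}")
print("unspliced pre-mRNA stays tightly correlated with the TF at every "
      "half-life,\nwhile spliced mRNA decorrelates as the half-life grows — "
      "mature transcripts\nintegrate transcription instead of tracking it.")
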