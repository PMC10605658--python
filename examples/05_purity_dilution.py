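"""How tumor purity dilutes the MSI score.

Mixes a tumor proportion profile with its matched normal profile at
decreasing tumor fractions.  Because the score is a sum, the mixture score
is exactly linear in the tumor fraction, and the purity at which a sample
drops below the cutoff has a closed form f* = (c - S_N) / (S_T - S_N).
"""

import numpy as np

from msiscore import mix_purity

rng = np.random.default_rng(5)
p_normal = rng.uniform(0.08, 0.142, 81)          # high-background specimen
p_tumor = p_normal + rng.permutation(
    np.r_[np.full(20, 0.18), np.zeros(61)])      # low-degree tumor

s_t, s_n = p_tumor.sum(), p_normal.sum()
print(f"undiluted tumor score S_T : {s_t:.2f}")
print(f"normal tissue score  S_N  : {s_n:.2f}")
for f in [1.0, 0.8, 0.7, 0.5, 0.3, 0.2, 0.0]:
    s = mix_purity(p_tumor, p_normal, f).sum()
    print(f"  tumor fraction {f:.0%}: score {s:5.2f} "
          f"({'MSI-H' if s >= 10 else 'MSS'})")
f_star = (10.0 - s_n) / (s_t - s_n)
print(f"cutoff crossing at f* = {f_star:.1%} tumor content")
# A low-degree tumor needs roughly >= 25-30% tumor cells to stay above the
# cutoff, which is why low-purity specimens risk false-negative MSI calls.
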