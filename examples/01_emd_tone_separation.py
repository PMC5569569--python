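"""Separate two well-spaced tones with plain EMD.

A 200 Hz + 25 Hz mixture is a classic oracle for sifting: the first IMF
should capture the fast tone and the second the slow one, and the IMFs plus
residual must sum back to the input exactly.
"""

import numpy as np

from memdkit import emd, gen_tone_fixture

sig = gen_tone_fixture([200.0, 25.0], duration=2.0, fs=1000.0)
t = np.arange(sig.samples.size) / sig.sampling_rate
d = emd(sig)

print(f"IMFs extracted:        {d.n_imfs}")
print(f"IMF1 vs 200 Hz tone r: {np.corrcoef(d.imfs[0], np.sin(2 * np.pi * 200 * t))[0, 1]:.4f}")
print(f"IMF2 vs 25 Hz tone r:  {np.corrcoef(d.imfs[1], np.sin(2 * np.pi * 25 * t))[0, 1]:.4f}")
print(f"reconstruction error:  {np.max(np.abs(d.reconstruct() - sig.samples)):.2e}")
# correlations near 1 mean each tone landed in its own IMF; the
# reconstruction error is at floating-point level because sifting is
# a telescoping subtraction.
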