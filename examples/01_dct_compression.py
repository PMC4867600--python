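"""Truncated-DCT image compression: the idea behind the reduced basis.

Builds a 256x256 test image, keeps only the 50 lowest cosine frequencies
per axis, and reports the fraction of discarded coefficients and the
reconstruction error.  The same truncation, restricted to a lung mask, is
what reduces the EIT inverse problem to a few hundred unknowns.
"""

import numpy as np
from scipy.fft import dctn

from eitdct import dct2_truncated_roundtrip

rng = np.random.default_rng(0)
x = np.linspace(-1, 1, 256)
X, Y = np.meshgrid(x, x)
A = np.exp(-((X - 0.3) ** 2 + Y**2) * 8) + 0.5 * np.cos(3 * X + 2 * Y)

keep = 50
Ahat = dct2_truncated_roundtrip(A, keep=keep)
V = dctn(Ahat, norm="ortho")

discarded = 1 - keep**2 / 256**2
rel_err = np.linalg.norm(Ahat - A) / np.linalg.norm(A)
print(f"coefficients discarded : {discarded:.4f} (~96% compression)")
print(f"nonzero coefficients   : {int(np.sum(np.abs(V) > 1e-10))} of {256 * 256}")
print(f"relative l2 error      : {rel_err:.4f}")
print("A smooth image survives aggressive truncation almost unchanged —")
print("which is why a low-frequency cosine basis can carry a ventilation image.")
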