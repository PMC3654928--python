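"""Phase-only correlation on plain vectors: identity, shift, and decay.

POC discards spectral amplitude and correlates pure phase, so a signal
matched against itself (or any circular shift, at any positive scale)
peaks at exactly 1, while unrelated noise peaks near 0.
"""

import numpy as np

from pocclass import poc_1d, poc_2d, reshape_to_square

rng = np.random.default_rng(0)
x = rng.normal(size=225)

print(f"self match:            peak = {poc_1d(x, x).peak_value:.6f}")
res = poc_1d(x, np.roll(x, 40))
print(f"circular shift by 40:  peak = {res.peak_value:.6f} at index {res.peak_location}")
print(f"rescaled by 1000:      peak = {poc_1d(x, 1000 * x).peak_value:.6f}")
y = rng.normal(size=225)
print(f"independent noise:     peak = {poc_1d(x, y).peak_value:.6f}")

# 2-D variant: reshape the square-length vector to 15 x 15 and use 2-D DFTs
r2 = poc_2d(reshape_to_square(x), reshape_to_square(y))
print(f"independent noise, 2D: peak = {r2.peak_value:.6f}")
# The first three peaks are 1.0 (perfect phase agreement); the noise peaks
# are small -- that gap is the classification signal.
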