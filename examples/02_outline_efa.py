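"""From a comb silhouette to elliptic Fourier descriptors.

A synthetic comb-like outline is rasterized to a binary mask (the form
real photographs are reduced to), traced back to a boundary, smoothed,
resampled to equal arc length and decomposed into per-harmonic
coefficient quadruples (a_n, b_n, c_n, d_n).
"""

import numpy as np

from combqtl import (efa_decompose, efa_reconstruct, harmonic_power,
                     interpolate_outline, render_outline_mask, smooth_outline,
                     trace_outline)
from combqtl.morphometrics import EFACoefficients

# a 2:1 ellipse with mild upper-edge bumps, rendered at 512 px
comb = efa_reconstruct(EFACoefficients(
    [2, 0.1, 0.05], [0, 0.08, 0], [0, 0.1, 0.02], [1, 0, 0.04]), 1500)
mask = render_outline_mask(comb, 512)
traced = trace_outline(mask)
outline = interpolate_outline(smooth_outline(traced, 20), 1000)

coeffs = efa_decompose(outline, n_harmonics=8)
power, cumfrac, n_req = harmonic_power(coeffs, threshold=0.99)
print(f"mask: {mask.sum()} foreground px; traced boundary: {len(traced)} px")
print(f"harmonic power (first 5): {np.round(power[:5] / power.sum(), 4)}")
print(f"{n_req} harmonics reach 99% of power; "
      f"cumulative at H=8: {cumfrac[-1]:.6f}")
# The first harmonic is the best-fitting ellipse; higher harmonics add
# finer comb-edge detail with rapidly decaying power.
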