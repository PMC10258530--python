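"""Wavelet transform coherence of band-limited signals with planned overlap.

Two signals share a fraction rho of their variance in the hemodynamic
analysis band (0.015-0.15 Hz); the band-averaged Morlet wavelet coherence
should increase monotonically with rho.
"""

import numpy as np

from dyadsync.coherence import band_average, wtc
from dyadsync.simulate import band_limited_noise

fs, n = 10.0, 1200  # 120 s at 10 Hz

print("rho    band R2   Fisher z   effective band floor")
for rho in (0.0, 0.3, 0.6, 0.9):
    rng = np.random.default_rng(5)
    shared = band_limited_noise(n, fs, 0.015, 0.15, rng)
    x = np.sqrt(rho) * shared + np.sqrt(1 - rho) * band_limited_noise(
        n, fs, 0.015, 0.15, rng)
    y = np.sqrt(rho) * shared + np.sqrt(1 - rho) * band_limited_noise(
        n, fs, 0.015, 0.15, rng)
    ba = band_average(wtc(x, y, fs))
    print(f"{rho:.1f}    {ba['band_mean_r2']:.3f}     {ba['band_mean_z']:.3f}"
          f"      {ba['effective_band_floor_hz']:.4f} Hz")

print()
print("R2 is the squared wavelet coherence averaged over the band and")
print("outside the cone of influence; with 120 s blocks the lowest usable")
print("frequency sits above the nominal 0.015 Hz edge, and even fully")
print("independent signals (rho=0) show a nonzero smoothing-limited")
print("baseline, which is why pseudo-dyad nulls matter.")
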