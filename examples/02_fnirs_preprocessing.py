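"""fNIRS preprocessing on a simulated recording with known contaminants.

Generates a 23-channel two-wavelength recording containing hemodynamic
signal, cardiac/respiratory/Mayer oscillations, a global scalp component,
and spike artifacts, then runs the full preprocessing chain and reports
what each stage removed.
"""

import numpy as np

from dyadsync.preprocess import (
    beer_lambert,
    intensity_to_od,
    pca_spatial_filter,
    qc_channels,
    wavelet_motion_correct,
)
from dyadsync.simulate import NIRSSimConfig, default_layout, simulate_dyad_nirs

layout = default_layout()
cfg = NIRSSimConfig(scalp_amp=0.8, spike_rate_per_min=2.0, seed=7)
raw, _, truth = simulate_dyad_nirs(cfg, layout)

od = intensity_to_od(raw)
od_corr = wavelet_motion_correct(od)
hemo = beer_lambert(od_corr, layout)
hemo = qc_channels(hemo)
filtered = pca_spatial_filter(hemo, layout, smooth_sigma_cm=3.5)

n_ok = len(hemo.ok_indices())
print(f"channels passing heartbeat QC: {n_ok}/{hemo.n_channels}")

scalp = truth["scalp"]["A"]
pre = np.mean([abs(np.corrcoef(hemo.hbo[i], scalp)[0, 1])
               for i in hemo.ok_indices()])
post = np.mean([abs(np.corrcoef(filtered.hbo[i], scalp)[0, 1])
                for i in hemo.ok_indices()])
print(f"mean |corr| with injected scalp process: {pre:.3f} -> {post:.3f}")
print()
print("the wavelet step removes spike transients from the optical density,")
print("Beer-Lambert converts to oxy/deoxyhemoglobin in uM, the QC drops")
print("channels without a resolvable ~1.2 Hz pulse, and the PCA spatial")
print("filter strips the spatially-global scalp component while leaving")
print("focal cortical signal in place.")
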