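"""Pinned physical and algorithmic constants.

All defaults that the analysis depends on live here so that a processed
dataset can be tied to one version of these numbers.
"""

import numpy as np

#: Nominal wavelengths of the continuous-wave system (nm).
WAVELENGTHS = (760.0, 850.0)

#: Motion capture sampling rate (Hz).
MOTION_FS = 50.0

#: fNIRS sampling rate (Hz).
NIRS_FS = 10.0

#: Nominal source-detector separation (cm).
OPTODE_SEPARATION_CM = 3.5

#: Differential path-length factor, per wavelength (dimensionless).
#: A single adult-head value is used for both wavelengths.
DPF = {760.0: 6.0, 850.0: 6.0}

#: Molar extinction coefficients in 1/(mM*cm), rows = wavelength
#: (760, 850 nm), columns = chromophore (HbO2, HHb).  Values from the
#: standard compiled hemoglobin absorption spectra used throughout CW-NIRS.
EXTINCTION = np.array(
    [
        [0.5864, 1.5485],  # 760 nm
        [1.0580, 0.6916],  # 850 nm
    ]
)

#: Analysis frequency band for coherence (Hz): below respiration
#: (~0.2-0.3 Hz), Mayer waves (~0.1 Hz) are inside, cardiac (~1-2 Hz) far out.
BAND_LO_HZ = 0.015
BAND_HI_HZ = 0.15

#: Morlet mother-wavelet centre frequency (rad).
MORLET_OMEGA0 = 6.0

#: Voices per octave of the CWT scale grid.
VOICES_PER_OCTAVE = 12

#: Behavioral synchrony detection defaults.
CVV_THRESHOLD = 0.35
SYNC_WINDOW_S = 2.0
MAX_LAG_MS = 750.0
LAG_STEP_MS = 10.0
LAG0_BOUNDARY_MS = 30.0  # |lag| > this counts as "lagged" synchrony

#: Velocity smoothing window (ms), full width of the Gaussian kernel.
VELOCITY_SMOOTH_MS = 100.0

#: Stillness tolerance: velocity magnitudes below this (units/s) carry no
#: directional information and the cosine statistic is defined as 0.
STILLNESS_EPS = 1e-9

#: Clipping applied before arctanh so perfect copies stay finite.
FISHER_CLIP = 1.0 - 1e-12

#: Outlier exclusion multiple of the standard deviation.
OUTLIER_SD = 2.5

#: Closed ROI vocabulary.
ROI_LABELS = ("L.IFG", "R.IFG", "dmPFC")
ROI_NONE = "none"

CONDITIONS = ("BB", "FM", "IS")
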