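# dyadsync

Analysis pipeline for **dual-brain fNIRS hyperscanning** experiments on
interpersonal movement synchronization: two people move their hands in 3D
(back-to-back baseline, free movement, or intentional synchrony) while
prefrontal hemodynamics are recorded simultaneously from both heads. The
package quantifies how much the two bodies move in synchrony, how much the
two brains co-fluctuate, and whether the second predicts the first.

It is a library for researchers analysing (or simulating) such experiments
from Python; the `examples/` scripts show one capability each.

## What it computes

**Behavioral synchrony.** From 50 Hz 3D hand positions, instantaneous
velocities are smoothed with a 100 ms Gaussian window, and synchrony at time
*t* is the cosine of the angle between the dyad's velocity vectors,

```
C_ij(t) = <v_i(t), v_j(t)> / (|v_i(t)| |v_j(t)|)
```

CVV = 1 for identical movement direction, −1 for mirror movement, 0 for no
alignment. The signed CVV is averaged over a sliding 2 s window at every lag
on a ±750 ms grid (10 ms steps); windows whose |mean CVV| exceeds 0.35 are
synchrony moments. **Total sync** is the fraction of block time with
synchrony at lag 0 or at lags beyond 30 ms. Chance levels come from
**pseudo dyads** — condition-matched re-pairings of participants from
different real dyads.

**Neural coupling.** Raw two-wavelength (760/850 nm) intensities are
converted to optical density, motion-corrected in the wavelet domain,
converted to oxy/deoxyhemoglobin via the modified Beer–Lambert law (DPF
partial-volume correction), screened by heartbeat-based channel QC, and
cleansed of the global scalp component by PCA-based spatial filtering.
Between- and within-brain coupling is the Morlet (ω₀ = 6) **wavelet
transform coherence** averaged over 0.015–0.15 Hz outside the cone of
influence — below respiration (~0.25 Hz) and cardiac (~1–2 Hz) bands —
Fisher-z transformed and aggregated over channel pairs to ROI pairs
(L.IFG, R.IFG, dmPFC).

**Brain–behavior models.** Linear mixed models with condition, ROI pair and
coupling as fixed effects and a random intercept per dyad, fitted as a
ladder of interaction depths and compared by likelihood-ratio χ²; per-cell
simple slopes and real-vs-pseudo contrasts (Bonferroni) follow.

**Synthetic data.** Coupled Ornstein–Uhlenbeck velocity processes (coupling
κ, lag) for movement, and band-limited Gaussian processes with planned
shared variance ρ, physiological oscillations, scalp component and spike
artifacts for fNIRS — every stage has a parameter-recovery test bed with
known ground truth, and `simulate_experiment` writes full datasets in the
package's interchange formats (motion CSV, SNIRF, layout/design CSV).

## Worked example

```
$ python examples/01_movement_synchrony.py
injected lag: 200 ms, recovered lag: 200 ms
total sync     = 1.000
  at lag 0     = 0.708
  at |lag|>30  = 1.000
Fisher z of mean |CVV| = 0.371
```

A dyad simulated with κ = 0.8 coupling at a 200 ms delay: the lag scan
recovers the injected delay exactly on the 10 ms grid, and the follower's
delay shows up as high lagged sync with lower lag-0 sync.

```
$ python examples/03_wavelet_coherence.py
rho    band R2   Fisher z   effective band floor
0.0    0.270     0.576      0.0234 Hz
0.3    0.362     0.695      0.0234 Hz
0.6    0.555     0.961      0.0234 Hz
0.9    0.833     1.543      0.0234 Hz
```

Band-averaged coherence rises monotonically with the planned shared
variance; note the nonzero ρ = 0 baseline (smoothing-limited), which is why
pseudo-dyad nulls are essential, and the effective band floor above the
nominal 0.015 Hz edge for 120 s blocks.

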