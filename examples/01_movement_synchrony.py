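"""Dyadic movement synchrony from a simulated coupled pair.

Simulates two participants whose hand velocities are coupled (kappa = 0.8)
with a 200 ms leader-follower delay, then computes the lag-resolved sync
map and its summary measures.
"""

import numpy as np

from dyadsync.movement import (
    compute_velocity,
    dyad_sync_summary,
    gaussian_smooth,
    lagged_sync_map,
)
from dyadsync.simulate import MotionSimConfig, simulate_dyad_motion

cfg = MotionSimConfig(coupling=0.8, lag_ms=200.0, seed=42)
trace_a, trace_b = simulate_dyad_motion(cfg)

va = gaussian_smooth(compute_velocity(trace_a))
vb = gaussian_smooth(compute_velocity(trace_b))
smap = lagged_sync_map(va, vb, dyad_id="demo", condition="IS")

best_lag = smap.lags_ms[np.argmax(smap.C.mean(axis=0))]
summary = dyad_sync_summary(trace_a, trace_b, dyad_id="demo")

print(f"injected lag: {cfg.lag_ms:.0f} ms, recovered lag: {best_lag:.0f} ms")
print(f"total sync     = {summary.total_sync:.3f}")
print(f"  at lag 0     = {summary.lag0_sync:.3f}")
print(f"  at |lag|>30  = {summary.lagged_sync:.3f}")
print(f"Fisher z of mean |CVV| = {summary.fisher_z_mean_cvv:.3f}")
print()
print("total sync is the fraction of block time the windowed cosine of the")
print("two 3D velocity vectors exceeds 0.35 at lag 0 or at lags beyond")
print("30 ms; the recovered lag should sit within one 30 ms grid step of")
print("the injected 200 ms delay.")
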