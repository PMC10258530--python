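"""End-to-end analysis of a simulated hyperscanning experiment.

Writes a complete on-disk dataset (motion CSVs, SNIRF recordings, design
table), reads it back through the io layer, computes behavioral synchrony
and between-brain ROI coupling per condition, and fits the brain-behavior
mixed model.
"""

import tempfile
import warnings
from pathlib import Path

import pandas as pd

from dyadsync import io as dio
from dyadsync.coherence import records_to_frame, roi_pair_coupling
from dyadsync.movement import dyad_sync_summary
from dyadsync.preprocess import preprocess
from dyadsync.stats import fit_model_ladder, merge_sync_coupling, simple_slopes

workdir = Path(tempfile.mkdtemp())
from dyadsync.simulate import simulate_experiment

manifest = simulate_experiment(
    workdir, n_dyads=4, block_s=60.0,
    kappa={"BB": 0.0, "FM": 0.2, "IS": 0.9},
    rho={"BB": 0.0, "FM": 0.3, "IS": 0.7},
    seed=11,
)
layout = dio.read_layout(manifest["layout"])
print(f"dataset written to {workdir} ({len(manifest['nirs'])} SNIRF files)")

sync_rows, coupling = [], []
for design, motion_path in zip(manifest["designs"], manifest["motion"]):
    traces = dio.read_motion(motion_path, design)
    for cond in ("BB", "FM", "IS"):
        pair = [t for t in traces if t.condition == cond]
        s = dyad_sync_summary(pair[0], pair[1], dyad_id=design.dyad_id)
        sync_rows.append(dict(dyad_id=design.dyad_id, condition=cond,
                              group="real", total_sync=s.total_sync))

    hemos = []
    for pid in design.participant_ids:
        raw, _ = dio.read_nirs(workdir / f"nirs_{pid}.snirf")
        hemos.append(preprocess(raw, layout))
    coupling += roi_pair_coupling(
        hemos[0], layout, hemos[1], layout, scope="between",
        blocks=design.condition_blocks, unit_id=design.dyad_id,
    )

sync = pd.DataFrame(sync_rows)
print("\nmean total sync by condition:")
print(sync.groupby("condition").total_sync.mean().round(3))

merged = merge_sync_coupling(sync, records_to_frame(coupling))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = fit_model_ladder(merged)
    slopes = simple_slopes(report, merged)

print(f"\nmodel ladder selected depth {report.selected + 1} "
      f"(of {len(report.fits)}):")
print(report.comparisons.round(4).to_string(index=False))
print("\nper-cell coupling -> synchrony slopes (IS condition):")
print(slopes[slopes.condition == "IS"].round(3).to_string(index=False))
print()
print("the IS condition carries both the movement coupling (kappa=0.9) and")
print("the neural coupling (rho=0.7), so total sync is highest there; at")
print("only 4 demo dyads the per-cell slopes are noisy and the ladder")
print("rightly keeps the main-effects model -- parameter recovery at a")
print("powered size (30 dyads) is exercised in the test suite.")
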