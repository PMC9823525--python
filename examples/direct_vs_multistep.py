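"""Compare direct kinematic regression against the multi-step baseline.

Trains the direct regressor (through the differentiable skeletal-model
layer) and runs the scale-then-IK pipeline on identical test observations
corrupted with systematic 30-50 mm marker bias, then prints the side-by-side
metric table.  Expect the direct path to win on joint angles and body scales
while the multi-step path, which optimizes marker fit, stays competitive on
marker position error.  Takes a few minutes on one CPU.
"""

import skelkin as sk

cfg = sk.ExperimentConfig(n_train=20, n_test=4, seed=1)
report = sk.compare_pipelines(cfg)

rows = [
    ("MAE_angle (deg)", "mae_angle"),
    ("SD_angle (deg)", "sd_angle"),
    ("MPBLPE (mm)", "mpblpe"),
    ("MAE_body (mm)", "mae_body"),
    ("RMSE_body (-)", "rmse_body"),
    ("MV_angle (deg/s)", "mv_angle"),
]
print(f"{'metric':<18}{'direct':>10}{'multi-step':>12}")
for label, attr in rows:
    print(f"{label:<18}{getattr(report.direct, attr):>10.2f}{getattr(report.multistep, attr):>12.2f}")
print(f"\ndirect reduces MAE_angle by {report.mae_angle_reduction_pct:.1f}% "
      "relative to the multi-step baseline")
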