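"""End-to-end miniature run: simulate, train, predict, refine, evaluate.

A 2-patient phantom cohort is segmented with a reduced network (2 blocks,
8 filters, 2 epochs) so the whole pipeline finishes in seconds on a CPU.
Scores are poor at this training budget -- the point is the wiring: patient-
wise folds, Soft-Dice training, ensemble prediction, baseline refinement and
the full metrics report.
"""

import json

from octseg import RunConfig, run_pipeline
from octseg.network import NetworkConfig
from octseg.phantoms import PhantomSpec

config = RunConfig(
    out_dir="small_run", seed=1, K=2,
    simulate_patients=2, simulate_images_per_patient=2,
    patch_width=48, slice_width=64, sg_window=63, axial_pixel_um=2.2,
    network=NetworkConfig(n_blocks=2, filters_per_conv=8, epochs=2,
                          batch_size=4, augment=False),
    phantom=PhantomSpec(height_px=96, width_px=96, speckle_level=0.1,
                        n_follicles=1, follicle_depth_px=20,
                        follicle_halfwidth_px=8, surface_depth_px=20,
                        epidermis_thickness_px=15, surface_waviness_amp_px=2),
)
report = run_pipeline(config)

print(json.dumps(report.cohort, indent=1))
print("per-patient thickness error (um):")
print(report.per_patient[["patient_id", "et_gt_um", "et_pred_um",
                          "rmse_um", "mae_um", "rsr"]].to_string(index=False))
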