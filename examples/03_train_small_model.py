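"""Train a miniature joint anatomy + scar model on coarse phantoms.

Runs a few epochs of the full two-task pipeline — multiview fusion,
ConvLSTM sequence branch, attention-gated scar head, hybrid Dice loss,
decayed-learning-rate Adam — on 20-voxel phantoms so it finishes in well
under a minute. Printed: the per-epoch loss trajectory and held-out Dice
for both tasks.
"""

import atriaseg as ag

spec = ag.PhantomSpec(
    grid_edge=20, spacing_mm=2.0, la_semi_axes_mm=(12.0, 10.0, 9.0),
    n_pv_tubes=2, pv_length_mm=8.0,
)
cohort = ag.generate_cohort(spec, 8, seed=4)

model_cfg = ag.MVTTConfig(cube_edge=20, base_channels=4, n_res_blocks=1)
train_cfg = ag.TrainConfig(max_epochs=5, early_stop_patience=5, seed=0)
model, history = ag.train(model_cfg, cohort[:6], train_cfg, val_cohort=cohort[6:])

print(history.to_frame().to_string(index=False,
                                   float_format=lambda v: f"{v:.4f}"))
print(f"\nbest epoch: {history.best_epoch}")
print("train_loss is the hybrid Dice loss (anatomy term + scar term, each in "
      "[0, 1]); val_dice_* are overlap scores of the thresholded probability "
      "maps on the held-out phantoms. Anatomy converges first — the cavity is "
      "large and bright — while the small, discrete scar patches need the "
      "attention-modulated head and more epochs.")
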