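"""Shared scaled-down training study used by the acceptance and ordering
tests: 40-phantom cohorts at 48^3, the full model vs. the no-attention
variant, three seeds. Everything is computed once per test session."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import atriaseg as ag
from atriaseg.baselines import (
    fuzzy_cmeans_scar,
    kmeans_scar,
    sample_from_phantom,
    two_sd_threshold,
)
from atriaseg.metrics import confusion, metrics
from atriaseg.network import binarize
from atriaseg.training import prepare_sample

SEEDS = (0, 1, 2)
COHORT_SIZE = 40
HELD_OUT = 8
MAX_EPOCHS = 5
MODEL_KW = dict(base_channels=6, n_res_blocks=1, cube_edge=48)


@dataclass
class RunResult:
    anatomy_dice: float
    scar_dice: float
    baseline_scar_dice: dict[str, float]
    baseline_scar_specificity: dict[str, float]
    history: ag.TrainHistory


_COHORTS: dict[int, list] = {}


def _cohort_for(seed: int) -> list:
    # the two variants of a seed train on the identical cohort (paired design)
    if seed not in _COHORTS:
        _COHORTS[seed] = ag.generate_cohort(
            ag.PhantomSpec(), COHORT_SIZE, seed=11 + 100 * seed
        )
    return _COHORTS[seed]


def run_variant(seed: int, use_attention: bool, with_baselines: bool) -> RunResult:
    cohort = _cohort_for(seed)
    train_set = cohort[: COHORT_SIZE - HELD_OUT]
    held_out = cohort[COHORT_SIZE - HELD_OUT :]
    mcfg = ag.MVTTConfig(use_attention=use_attention, **MODEL_KW)
    tcfg = ag.TrainConfig(max_epochs=MAX_EPOCHS, early_stop_patience=MAX_EPOCHS,
                          seed=seed)
    model, history = ag.train(mcfg, train_set, tcfg, val_cohort=held_out)

    dice_a, dice_s = [], []
    base: dict[str, list] = {"2sd": [], "kmeans": [], "fcm": []}
    for s in held_out:
        img, gl, gas = prepare_sample(s, mcfg.cube_edge)
        out = model.forward(img)
        dice_a.append(metrics(confusion(binarize(out.anatomy_volume()), gl)).dice)
        dice_s.append(metrics(confusion(binarize(out.scar_volume()), gas)).dice)
        if with_baselines:
            ws = sample_from_phantom(s)
            masks = {
                "2sd": two_sd_threshold(ws),
                "kmeans": kmeans_scar(ws, seed=seed),
                "fcm": fuzzy_cmeans_scar(ws)[1],
            }
            for name, mask in masks.items():
                base[name].append(metrics(confusion(mask.labels, s.scar.labels)))
    return RunResult(
        anatomy_dice=float(np.mean(dice_a)),
        scar_dice=float(np.mean(dice_s)),
        baseline_scar_dice={
            k: float(np.mean([r.dice for r in v])) for k, v in base.items() if v
        },
        baseline_scar_specificity={
            k: float(np.mean([r.specificity for r in v])) for k, v in base.items() if v
        },
        history=history,
    )
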