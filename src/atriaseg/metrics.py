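"""Segmentation metrics and method-agreement statistics.

Voxelwise confusion counts; accuracy / sensitivity / specificity / Dice;
scar extent as a percentage of the atrial wall compartment at a fixed
2.25 mm wall thickness; Pearson correlation; and Bland–Altman bias with
95% limits of agreement (mean difference +/- 1.96 sample standard
deviations of the differences).

Metrics are computed per volume and averaged across cases, matching the
mean +/- sd presentation conventional for segmentation studies, rather than
pooled voxelwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats

from .phantom import wall_shell
from .volumes import LabelVolume


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsRecord:
    accuracy: float
    sensitivity: float
    specificity: float
    dice: float


@dataclass(frozen=True)
class AgreementStats:
    pearson_r: float
    bias: float
    loa_low: float
    loa_high: float


def _as_binary(x) -> np.ndarray:
    arr = x.labels if isinstance(x, LabelVolume) else np.asarray(x)
    uniq = np.unique(arr)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("masks must be binary (values in {0, 1})")
    return arr.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Voxelwise confusion counts between two aligned binary masks."""
    p, t = _as_binary(pred), _as_binary(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return float("nan")
    return num / den


def metrics(counts: ConfusionCounts) -> MetricsRecord:
    """AC=(tp+tn)/total, SE=tp/(tp+fn), SP=tn/(tn+fp), DI=2tp/(2tp+fp+fn)."""
    if counts.total <= 0:
        raise ValueError("confusion counts are empty")
    return MetricsRecord(
        accuracy=(counts.tp + counts.tn) / counts.total,
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        specificity=_ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        dice=_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, "dice"),
    )


def scar_percentage(
    scar: LabelVolume,
    anatomy: LabelVolume,
    spacing: tuple[float, float, float] | None = None,
    wall_mm: float = 2.25,
) -> float:
    """Scar burden: 100 * scar volume / wall-shell volume.

    The wall compartment is the shell of voxels within ``wall_mm`` of the
    anatomy surface (fixed atrial wall thickness assumption). All voxels
    share one spacing, so voxel counts stand in for volumes.
    """
    spacing = spacing or anatomy.spacing
    shell = wall_shell(anatomy, spacing, wall_mm)
    n_shell = int(shell.labels.sum())
    if n_shell == 0:
        raise ValueError("wall shell is empty")
    return 100.0 * float(scar.labels.sum()) / n_shell


def pearson(pairs) -> float:
    """Sample Pearson correlation between estimates and references."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("pearson requires >= 3 (estimate, reference) pairs")
    est, ref = arr[:, 0], arr[:, 1]
    if np.std(est) == 0 or np.std(ref) == 0:
        raise ValueError("pearson undefined for zero-variance inputs")
    r, _ = sp_stats.pearsonr(est, ref)
    return float(r)


def bland_altman(pairs) -> AgreementStats:
    """Bland–Altman agreement: bias = mean(est - ref); limits of agreement
    bias +/- 1.96 * sd(differences), with the sample (n-1) sd convention."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("bland_altman requires >= 2 (estimate, reference) pairs")
    diff = arr[:, 0] - arr[:, 1]
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    try:
        r = pearson(pairs)
    except ValueError:
        r = float("nan")
    return AgreementStats(
        pearson_r=r, bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd
    )
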