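"""Voxel-level agreement between an automated mask and a reference mask.

Metrics are computed inside a brain-domain mask: counting the vast air
background as true negatives would push specificity to 1 regardless of the
segmentation quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import BinaryMask, _check_lattice

__all__ = ["ConfusionCounts", "agreement"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: BinaryMask, truth: BinaryMask, domain: BinaryMask) -> ConfusionCounts:
    _check_lattice(pred, truth, "agreement")
    _check_lattice(pred, domain, "agreement")
    d = domain.data
    p = pred.data[d]
    t = truth.data[d]
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
        tn=int((~p & ~t).sum()),
    )


def agreement(
    pred: BinaryMask, truth: BinaryMask, domain: BinaryMask
) -> tuple[float | None, float | None, float | None]:
    """Sensitivity, specificity and Dice similarity coefficient in-domain.

    With an empty truth mask, sensitivity and DSC are undefined and reported
    as ``None`` rather than zero. Specificity is ``None`` only when every
    in-domain voxel is true-positive ground truth.
    """
    c = confusion(pred, truth, domain)
    truth_empty = (c.tp + c.fn) == 0
    sens = None if truth_empty else c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    dsc = (
        None
        if truth_empty
        else (2 * c.tp / (2 * c.tp + c.fp + c.fn) if (2 * c.tp + c.fp + c.fn) > 0 else None)
    )
    return sens, spec, dsc
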