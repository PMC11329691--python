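"""Injection specificity from voxel volumes, and the two experiment gates.

Specificity is the fraction of the injected tracer bolus that fell inside the
intended source structure.  Two estimators are used, on a voxelwise injection
density grid paired with a binary structure mask of the same shape:

binarized
    count of positive injection voxels inside the mask over all positive
    injection voxels — every expressing voxel counts equally.
weighted
    density-weighted version, sum(inj * mask) / sum(inj).

The binarized estimator feeds the 50 % inclusion gate (experiments where more
than half the bolus missed the target are discarded); the weighted estimator
feeds the stricter 75 % anatomical-confirmation tier.
"""

from __future__ import annotations

from typing import Iterable, Literal

import numpy as np

from .errors import DegenerateInputError, DimensionError, MissingFieldError
from .records import ExperimentRecord, SpecificityPair

#: Default gate thresholds: (inclusion, confirmation).
INCLUSION_THRESHOLD = 0.50
CONFIRMATION_THRESHOLD = 0.75

Tier = Literal["inclusion", "confirmation"]


def _check(inj: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    inj = np.asarray(inj, dtype=float)
    mask = np.asarray(mask)
    if inj.shape != mask.shape:
        raise DimensionError(
            f"injection shape {inj.shape} != mask shape {mask.shape}"
        )
    if np.any(inj < 0):
        raise DegenerateInputError("injection densities must be non-negative")
    if not np.isin(mask, (0, 1)).all():
        raise DegenerateInputError("structure mask must be binary")
    if not np.any(inj > 0):
        raise DegenerateInputError("injection volume has no positive voxel")
    return inj, mask.astype(bool)


def specificity_binarized(inj: np.ndarray, mask: np.ndarray) -> float:
    """Fraction of positive injection voxels that lie inside the mask."""
    inj, mask = _check(inj, mask)
    positive = inj > 0
    return float(np.count_nonzero(positive & mask) / np.count_nonzero(positive))


def specificity_weighted(inj: np.ndarray, mask: np.ndarray) -> float:
    """Density-weighted in-mask fraction: sum(inj·mask) / sum(inj)."""
    inj, mask = _check(inj, mask)
    return float(inj[mask].sum() / inj.sum())


def compute_specificity(inj: np.ndarray, mask: np.ndarray) -> SpecificityPair:
    """Both estimators for one experiment's injection volume and mask."""
    return SpecificityPair(
        binarized=specificity_binarized(inj, mask),
        weighted=specificity_weighted(inj, mask),
    )


def gate_experiments(
    records: Iterable[ExperimentRecord],
    tier: Tier = "inclusion",
    threshold: float | None = None,
) -> list[ExperimentRecord]:
    """Keep records passing the specificity gate for ``tier``, order preserved.

    The inclusion tier keeps records with *binarized* specificity ≥ 0.50; the
    confirmation tier keeps records with *weighted* specificity ≥ 0.75.  The
    ≥ boundary (rather than >) is deliberate so that an experiment exactly at
    the cut survives.  ``threshold`` overrides the tier default.
    """
    if tier == "inclusion":
        cut = INCLUSION_THRESHOLD if threshold is None else threshold
        attr = "binarized"
    elif tier == "confirmation":
        cut = CONFIRMATION_THRESHOLD if threshold is None else threshold
        attr = "weighted"
    else:  # pragma: no cover - guarded by Literal typing
        raise ValueError(f"unknown tier {tier!r}")
    kept = []
    for rec in records:
        if rec.specificity is None:
            raise MissingFieldError(
                f"experiment {rec.experiment_id!r} lacks a specificity value"
            )
        if getattr(rec.specificity, attr) >= cut:
            kept.append(rec)
    return kept
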