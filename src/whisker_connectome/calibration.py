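"""Threshold calibration against reference connections, and consensus binarization.

The four projection variables are binarized with variable-specific thresholds
calibrated on wild-type data: the threshold for a variable is raised until a
reference connection (a literature-anchored true positive) would be lost; the
largest threshold retaining 100 % of the reference set is kept.  Under the
≥-detection convention this sweep has a closed form — the minimum of the
variable over the reference edges — which is what :func:`calibrate` computes
(an optional grid sweep reproduces the incremental procedure for audit).

A connection is accepted only by consensus: all four thresholded matrices must
agree (equivalently, the sum of the four binary matrices equals 4).  The
criterion is recall-only by design: it encodes no assumption about absent
connections, only that known ones must survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CalibrationError, DimensionError
from .matrices import MergedMatrixSet, VariableMatrixSet, merge_hemispheres
from .ontology import ReferenceConnectionSet
from .records import VARIABLES


@dataclass(frozen=True)
class ThresholdSet:
    """Calibrated binarization thresholds, one per projection variable.

    Units: density is a fraction (a.u. in [0,1]); intensity and energy are in
    the tracer brightness units (a.u.); volume is in mm³.
    """

    density: float
    intensity: float
    energy: float
    volume: float

    def __getitem__(self, var: str) -> float:
        return getattr(self, var)

    def as_dict(self) -> dict[str, float]:
        return {v: getattr(self, v) for v in VARIABLES}

    def replace_variable(self, var: str, value: float) -> "ThresholdSet":
        d = self.as_dict()
        d[var] = value
        return ThresholdSet(**d)


#: Named threshold presets. "allen2024" carries published Allen-data-calibrated
#: values for users who skip calibration on their own data.
PRESETS: dict[str, ThresholdSet] = {
    "allen2024": ThresholdSet(density=9e-5, intensity=222.0, energy=28.91, volume=0.0395),
}


@dataclass
class BinaryConnectome:
    """Directed binary adjacency over an ordered node panel.

    The diagonal is stored but excluded from every count (self-connections are
    not considered).  ``measured`` marks rows backed by at least one gated
    experiment; an unmeasured row means "no data", not "no connection".
    """

    nodes: list[str]
    adjacency: np.ndarray  # int {0,1}, square
    measured: np.ndarray  # bool per node (row)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=int)
        n = len(self.nodes)
        if self.adjacency.shape != (n, n):
            raise DimensionError(
                f"adjacency shape {self.adjacency.shape} != ({n}, {n})"
            )
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.measured = np.asarray(self.measured, dtype=bool)

    @property
    def n(self) -> int:
        return len(self.nodes)

    def edge_count(self) -> int:
        """Number of off-diagonal edges (self-connections not considered)."""
        a = self.adjacency.copy()
        np.fill_diagonal(a, 0)
        return int(a.sum())

    def edges(self) -> list[tuple[str, str]]:
        """Off-diagonal (source, target) pairs, row-major order."""
        a = self.adjacency.copy()
        np.fill_diagonal(a, 0)
        rr, cc = np.nonzero(a)
        return [(self.nodes[r], self.nodes[c]) for r, c in zip(rr, cc)]


def _reference_values(
    wild: MergedMatrixSet, ref: ReferenceConnectionSet
) -> dict[str, np.ndarray]:
    """Per-variable vector of wild-type matrix values on the reference edges."""
    values: dict[str, list[float]] = {v: [] for v in VARIABLES}
    for src, tgt in ref:
        i, j = wild.index(src), wild.index(tgt)
        if not wild.measured[i]:
            raise CalibrationError(
                f"reference edge ({src}, {tgt}): source row unmeasured in wild-type data"
            )
        for v in VARIABLES:
            x = float(wild.variables[v][i, j])
            if x <= 0:
                raise CalibrationError(
                    f"reference edge ({src}, {tgt}) has zero {v}; calibration infeasible"
                )
            values[v].append(x)
    return {v: np.array(xs) for v, xs in values.items()}


def calibrate(
    wild: MergedMatrixSet,
    ref: ReferenceConnectionSet,
    method: str = "closed_form",
    sweep_steps: int = 10_000,
) -> ThresholdSet:
    """Largest per-variable thresholds retaining every reference edge.

    ``method="closed_form"`` takes the exact minimum over reference edges;
    ``method="sweep"`` reproduces the incremental-raise narrative on a grid of
    ``sweep_steps`` candidate thresholds per variable (audit mode; equal to
    the closed form up to grid resolution from below).
    """
    vals = _reference_values(wild, ref)
    if method == "closed_form":
        return ThresholdSet(**{v: float(vals[v].min()) for v in VARIABLES})
    if method == "sweep":
        out = {}
        for v in VARIABLES:
            grid = np.linspace(0.0, float(vals[v].max()), sweep_steps)
            keep = 0.0
            for theta in grid:  # raise until a reference edge is lost
                if np.all(vals[v] >= theta):
                    keep = float(theta)
                else:
                    break
            out[v] = keep
        return ThresholdSet(**out)
    raise ValueError(f"unknown calibration method {method!r}")


def binarize_consensus(m: MergedMatrixSet, theta: ThresholdSet) -> BinaryConnectome:
    """Four-variable consensus binarization of a merged matrix set.

    An edge is detected iff every variable meets its threshold (value ≥ θ);
    this equals summing the four thresholded binary matrices and keeping
    entries equal to 4.  Unmeasured source rows come out all-zero and keep
    their "no data" flag.
    """
    votes = np.zeros((m.n, m.n), dtype=int)
    for v in VARIABLES:
        votes += (m.variables[v] >= theta[v]).astype(int)
    adj = (votes == len(VARIABLES)).astype(int)
    adj[~m.measured, :] = 0
    return BinaryConnectome(nodes=list(m.sources), adjacency=adj, measured=m.measured.copy())


def apply_per_line(
    lines: list[VariableMatrixSet], theta: ThresholdSet
) -> dict[str, BinaryConnectome]:
    """Hemisphere-merge and binarize each line with the calibrated thresholds."""
    return {m.line_id: binarize_consensus(merge_hemispheres(m), theta) for m in lines}
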