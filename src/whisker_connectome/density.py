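"""Outgoing-density profiles and top-k concentration shares per source nucleus.

For each source, the continuous projection densities of its outgoing
connections are normalized to sum to 1 and sorted descending; the cumulative
share of the k densest targets then measures how concentrated (thalamus-like)
or distributed (cortex-like) the nucleus's output is.  Sources with no
measured outgoing density are reported with an explicit "no data" marker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import BinaryConnectome
from .matrices import MergedMatrixSet

DEFAULT_K_VALUES = (1, 2, 4, 6)


@dataclass
class DensityProfile:
    """Descending normalized outgoing-density shares for one source."""

    source: str
    group: str
    shares: np.ndarray  # descending, sums to 1
    targets: list[str]  # aligned with shares

    def topk(self, k: int) -> float:
        """Cumulative share of the k densest targets (clipped at the count)."""
        if k <= 0:
            raise ValueError(f"k must be positive, got {k}")
        return float(self.shares[: min(k, len(self.shares))].sum())


def profile_sources(
    m: MergedMatrixSet,
    groups: dict[str, str] | None = None,
    detected: BinaryConnectome | None = None,
) -> tuple[list[DensityProfile], list[str]]:
    """Density profiles for every measured source with positive outgoing total.

    The diagonal is excluded.  When ``detected`` is given, the profile is
    restricted to the edges retained in the binarized map, so sub-threshold
    background does not dilute the shares; otherwise the raw row is profiled.
    Returns ``(profiles, no_data)`` where ``no_data`` lists sources that are
    unmeasured or have no positive outgoing density.
    """
    groups = groups or {}
    dens = np.array(m.variables["density"], dtype=float, copy=True)
    np.fill_diagonal(dens, 0.0)
    if detected is not None:
        mask = np.array(detected.adjacency, dtype=bool)
        np.fill_diagonal(mask, False)
        dens = np.where(mask, dens, 0.0)
    profiles: list[DensityProfile] = []
    no_data: list[str] = []
    for i, src in enumerate(m.sources):
        row = dens[i]
        total = row.sum()
        if not m.measured[i] or total <= 0:
            no_data.append(src)
            continue
        pos = np.nonzero(row > 0)[0]
        order = pos[np.argsort(-row[pos], kind="stable")]
        shares = row[order] / total
        profiles.append(
            DensityProfile(
                source=src,
                group=groups.get(src, ""),
                shares=shares,
                targets=[m.sources[j] for j in order],
            )
        )
    return profiles, no_data


def topk_summary(
    profiles: list[DensityProfile], k_values: tuple[int, ...] = DEFAULT_K_VALUES
) -> pd.DataFrame:
    """Tidy table: one row per (source, k) with the cumulative top-k share."""
    for k in k_values:
        if k <= 0:
            raise ValueError(f"k values must be positive, got {k}")
    rows = [
        {"source": p.source, "group": p.group, "k": k, "cumulative_share": p.topk(k)}
        for p in profiles
        for k in k_values
    ]
    return pd.DataFrame(rows, columns=["source", "group", "k", "cumulative_share"])
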