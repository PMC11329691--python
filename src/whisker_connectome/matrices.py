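"""Source×target projection matrices per transgenic line.

Experiments that pass the inclusion gate are grouped per line and projected
onto matrices with injected structures as rows and target structures as
columns.  Targets span both hemispheres, ordered relative to the injection
side: an S-structure parcellation yields S×2S matrices whose left block is
ipsilateral and right block contralateral.  Contralateral projections are
sparse, so the two hemispheric blocks are merged with an elementwise maximum
(false-negative-averse) into square S×S matrices before thresholding.

Rows for structures never injected in a line are flagged *unmeasured* —
downstream maps report "no data" for them rather than "no connection".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, EmptySetError, OntologyError
from .ontology import Ontology
from .records import VARIABLES, ExperimentRecord


@dataclass
class VariableMatrixSet:
    """Per-line S×2S matrices, one per projection variable."""

    line_id: str
    sources: list[str]
    variables: dict[str, np.ndarray]
    measured: np.ndarray  # bool (S,)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.sources)

    def _validate_wide(self) -> None:
        for var, m in self.variables.items():
            if m.shape != (self.n, 2 * self.n):
                raise DimensionError(
                    f"{var}: expected shape {(self.n, 2 * self.n)}, got {m.shape}"
                )


@dataclass
class MergedMatrixSet:
    """Hemisphere-merged square S×S matrices, one per variable."""

    line_id: str
    sources: list[str]
    variables: dict[str, np.ndarray]
    measured: np.ndarray
    provenance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.sources)

    def index(self, acronym: str) -> int:
        try:
            return self.sources.index(acronym)
        except ValueError:
            raise OntologyError(f"acronym {acronym!r} not in matrix panel") from None

    def value(self, var: str, source: str, target: str) -> float:
        return float(self.variables[var][self.index(source), self.index(target)])


def build_line_matrices(
    records: list[ExperimentRecord],
    line: str,
    ontology: Ontology,
    combine: str = "max",
) -> VariableMatrixSet:
    """Aggregate one line's gated experiments into S×2S variable matrices.

    Multiple experiments injected at the same source are combined elementwise
    by ``combine`` ("max", the default false-negative-averse rule, or "mean").
    Columns 0..S-1 are ipsilateral to the injection, S..2S-1 contralateral.
    """
    if combine not in ("max", "mean"):
        raise ValueError(f"combine must be 'max' or 'mean', got {combine!r}")
    line_records = [r for r in records if r.line_id == line]
    if not line_records:
        raise EmptySetError(f"no experiments for line {line!r}")
    S = len(ontology)
    acronyms = ontology.acronyms
    col = {a: i for i, a in enumerate(acronyms)}

    per_source: dict[int, list[dict[str, np.ndarray]]] = {}
    provenance: dict[str, list[str]] = {}
    for rec in line_records:
        src = ontology.resolve(rec.source_structure)
        r = ontology.index(src)
        rows = {v: np.zeros(2 * S) for v in VARIABLES}
        for p in rec.projections:
            c = col[ontology.resolve(p.structure)]
            if p.hemisphere != rec.injection_hemisphere:
                c += S
            for v in VARIABLES:
                rows[v][c] = getattr(p, v)
        per_source.setdefault(r, []).append(rows)
        provenance.setdefault(src, []).append(rec.experiment_id)

    variables = {v: np.zeros((S, 2 * S)) for v in VARIABLES}
    measured = np.zeros(S, dtype=bool)
    for r, stack in per_source.items():
        measured[r] = True
        for v in VARIABLES:
            block = np.stack([rows[v] for rows in stack])
            variables[v][r] = block.max(axis=0) if combine == "max" else block.mean(axis=0)
    return VariableMatrixSet(
        line_id=line,
        sources=acronyms,
        variables=variables,
        measured=measured,
        provenance=provenance,
    )


def merge_hemispheres(m: VariableMatrixSet) -> MergedMatrixSet:
    """Collapse the ipsi/contra blocks with an elementwise maximum."""
    m._validate_wide()
    S = m.n
    merged = {
        v: np.maximum(mat[:, :S], mat[:, S:]) for v, mat in m.variables.items()
    }
    return MergedMatrixSet(
        line_id=m.line_id,
        sources=list(m.sources),
        variables=merged,
        measured=m.measured.copy(),
        provenance={k: list(v) for k, v in m.provenance.items()},
    )


def extract_subnetwork(
    m: MergedMatrixSet,
    panel: list[str] | tuple[str, ...],
    ontology: Ontology | None = None,
) -> MergedMatrixSet:
    """Restrict a merged matrix set to a nucleus panel, in panel order."""
    resolve = ontology.resolve if ontology is not None else (lambda a: a)
    names = [resolve(a) for a in panel]
    idx = np.array([m.index(a) for a in names])
    return MergedMatrixSet(
        line_id=m.line_id,
        sources=names,
        variables={v: mat[np.ix_(idx, idx)].copy() for v, mat in m.variables.items()},
        measured=m.measured[idx].copy(),
        provenance={a: list(m.provenance.get(a, [])) for a in names if a in m.provenance},
    )


def extract_subnetwork_wide(
    m: VariableMatrixSet,
    panel: list[str] | tuple[str, ...],
    ontology: Ontology | None = None,
) -> VariableMatrixSet:
    """Panel restriction of an unmerged S×2S set (both column blocks)."""
    resolve = ontology.resolve if ontology is not None else (lambda a: a)
    names = [resolve(a) for a in panel]
    pos = {a: i for i, a in enumerate(m.sources)}
    for a in names:
        if a not in pos:
            raise OntologyError(f"acronym {a!r} not in matrix panel")
    idx = np.array([pos[a] for a in names])
    S = m.n
    cols = np.concatenate([idx, idx + S])
    return VariableMatrixSet(
        line_id=m.line_id,
        sources=names,
        variables={v: mat[np.ix_(idx, cols)].copy() for v, mat in m.variables.items()},
        measured=m.measured[idx].copy(),
        provenance={a: list(m.provenance.get(a, [])) for a in names if a in m.provenance},
    )
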