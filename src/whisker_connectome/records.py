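"""Experiment records: one anterograde-tracing experiment per record.

Each record mirrors the per-experiment JSON exported by mesoscale projection
atlases: an injected (source) structure, the transgenic line of the animal,
and, for every target structure in each hemisphere, four projection summaries:

volume
    mm³ of labeled signal in the target structure.
intensity
    summed brightness of expressing pixels (a.u.).
density
    fraction of the structure's pixels expressing the tracer, in [0, 1].
energy
    summed brightness divided by the structure's pixel count (a.u.).

Records optionally carry precomputed injection-specificity estimates (the
binarized and the density-weighted fraction of the tracer bolus inside the
intended source structure); otherwise specificity is computed from the paired
injection volume and structure mask.
"""

from __future__ import annotations

from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import OntologyError, SchemaError
from .ontology import Ontology

VARIABLES = ("density", "intensity", "energy", "volume")

Hemisphere = Literal["left", "right"]


class ProjectionMeasurement(BaseModel):
    """Four projection variables for one (target structure, hemisphere)."""

    model_config = ConfigDict(extra="forbid")

    structure: str
    hemisphere: Hemisphere
    volume: float = Field(ge=0)
    intensity: float = Field(ge=0)
    density: float = Field(ge=0, le=1)
    energy: float = Field(ge=0)


class SpecificityPair(BaseModel):
    """Binarized and density-weighted injection-specificity fractions."""

    model_config = ConfigDict(extra="forbid")

    binarized: float = Field(ge=0, le=1)
    weighted: float = Field(ge=0, le=1)


class ExperimentRecord(BaseModel):
    """One tracing experiment: source, line, and per-structure measurements."""

    model_config = ConfigDict(extra="forbid")

    experiment_id: str
    line_id: str
    source_structure: str
    injection_hemisphere: Hemisphere = "right"
    specificity: Optional[SpecificityPair] = None
    projections: list[ProjectionMeasurement] = Field(default_factory=list)

    def measurements(self) -> dict[tuple[str, Hemisphere], dict[str, float]]:
        """Map (structure acronym, hemisphere) → the four variables."""
        return {
            (p.structure, p.hemisphere): {v: getattr(p, v) for v in VARIABLES}
            for p in self.projections
        }


def validate_record(payload: dict, ontology: Ontology | None = None) -> ExperimentRecord:
    """Parse and validate one record dict; resolve acronyms if an ontology is given.

    Raises
    ------
    SchemaError
        Naming the experiment_id (when present) and the offending field.
    OntologyError
        When the source or a target acronym is not resolvable.
    """
    exp_id = payload.get("experiment_id", "<missing experiment_id>")
    try:
        record = ExperimentRecord.model_validate(payload)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise SchemaError(
            f"experiment {exp_id!r}: invalid field {loc!r}: {first['msg']}"
        ) from exc
    if ontology is not None:
        try:
            record.source_structure = ontology.resolve(record.source_structure)
        except OntologyError as exc:
            raise OntologyError(f"experiment {exp_id!r}: {exc}") from exc
        unknown = sorted(
            {p.structure for p in record.projections if p.structure not in ontology}
        )
        if unknown:
            raise OntologyError(
                f"experiment {exp_id!r}: unknown structure acronyms {unknown}"
            )
        for p in record.projections:
            p.structure = ontology.resolve(p.structure)
    return record
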