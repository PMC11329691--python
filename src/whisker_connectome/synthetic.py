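"""Synthetic Allen-style tracing data with a planted ground-truth connectome.

The generator emulates the *statistical* shape of mesoscale tracer data —
per-experiment JSON records with four projection variables per target
structure and hemisphere, paired injection-density volumes and structure
masks, a transgenic-line category table and a reference-connection list —
without any biological realism of projection topographies.  Every pipeline
stage is thereby testable offline.

The default regime is *separable*: on true edges every variable is drawn at
or above a per-variable signal floor, on non-edges at or below a strictly
smaller background ceiling.  Reference edges receive exactly the floor value
in wild-type experiments, so threshold calibration has an analytically known
answer (the floor) and end-to-end recovery of the planted adjacency is exact.
:func:`degrade` re-draws a chosen fraction of true edges into the background
range to study recall loss in the non-separable regime.
"""

from __future__ import annotations

import math
from copy import deepcopy
from dataclasses import dataclass, field as dc_field

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigError
from .ontology import (
    LineCategoryTable,
    NucleusPanel,
    Ontology,
    ReferenceConnectionSet,
    build_ontology,
    load_panel,
)
from .records import VARIABLES, ExperimentRecord, ProjectionMeasurement, SpecificityPair


class GeneratorConfig(BaseModel):
    """Study conditions for the synthetic bundle.

    Defaults keep tests fast (30 structures per hemisphere) while matching
    the real pipeline's proportions: a 34-edge reference set, wild-type plus
    five transgenic lines, and an injection-specificity mixture placing mass
    below the 50 % inclusion gate, between the gates, and above the 75 %
    confirmation tier.
    """

    model_config = ConfigDict(extra="forbid")

    n_structures: int = Field(default=30, ge=18)
    edge_probability: float = Field(default=0.15, ge=0, lt=1)
    n_reference: int = Field(default=34, ge=0)
    lines_per_category: dict[str, int] = Field(
        default_factory=lambda: {"excitatory": 2, "inhibitory": 2, "uncategorized": 1}
    )
    line_source_coverage: float = Field(default=0.7, gt=0, le=1)
    signal_floors: dict[str, float] = Field(
        default_factory=lambda: {"density": 0.02, "intensity": 50.0, "energy": 5.0, "volume": 0.01}
    )
    background_ceilings: dict[str, float] = Field(
        default_factory=lambda: {"density": 0.005, "intensity": 10.0, "energy": 1.0, "volume": 0.002}
    )
    signal_scales: dict[str, float] = Field(
        default_factory=lambda: {"density": 0.9, "intensity": 2000.0, "energy": 100.0, "volume": 0.5}
    )
    specificity_masses: tuple[float, float, float] = (0.30, 0.35, 0.35)
    contra_probability: float = Field(default=0.2, ge=0, le=1)
    grid_shape: tuple[int, int, int] = (16, 16, 16)
    n_injection_voxels: int = Field(default=200, ge=50)
    overlapping: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        for v in VARIABLES:
            if v not in self.signal_floors or v not in self.background_ceilings:
                raise ConfigError(f"floors/ceilings must cover variable {v!r}")
            if not self.overlapping and self.signal_floors[v] <= self.background_ceilings[v]:
                raise ConfigError(
                    f"{v}: signal floor {self.signal_floors[v]} must exceed background "
                    f"ceiling {self.background_ceilings[v]} (set overlapping=True to force)"
                )
            if self.signal_scales[v] < self.signal_floors[v]:
                raise ConfigError(f"{v}: signal scale below floor")
        if abs(sum(self.specificity_masses) - 1.0) > 1e-9:
            raise ConfigError("specificity masses must sum to 1")
        if self.n_reference > 18 * 17:
            raise ConfigError("reference set cannot exceed the core panel's ordered pairs")
        return self


@dataclass
class GroundTruth:
    """Planted adjacency and the supports needed to score the pipeline."""

    nodes: list[str]
    adjacency: np.ndarray  # (n, n) binary, zero diagonal
    strengths: np.ndarray  # (n, n) in (0, 1] on edges
    reference: ReferenceConnectionSet
    per_line_sources: dict[str, list[str]]
    confirmed_support: set[tuple[str, str]] = dc_field(default_factory=set)

    def edge_pairs(self) -> list[tuple[str, str]]:
        rr, cc = np.nonzero(self.adjacency)
        return [(self.nodes[r], self.nodes[c]) for r, c in zip(rr, cc)]


@dataclass
class SyntheticBundle:
    """Everything one pipeline run consumes, plus the ground truth."""

    config: GeneratorConfig
    ontology: Ontology
    panel: NucleusPanel
    experiments: list[ExperimentRecord]
    volumes: dict[str, tuple[np.ndarray, np.ndarray]]  # exp_id -> (injection, mask)
    truth: GroundTruth
    line_table: LineCategoryTable
    reference: ReferenceConnectionSet
    degraded_edges: list[tuple[str, str]] = dc_field(default_factory=list)


def _subpanel(panel: NucleusPanel, ontology: Ontology) -> NucleusPanel:
    """Restrict the shipped panel to the structures present in the ontology."""
    present = [a for a in panel.extended57 if a in ontology]
    extra = [a for a in ontology.acronyms if a not in set(present)]
    extended = tuple(present + extra)[: max(57, 18)]
    extended = tuple(a for a in extended if a in ontology)
    return NucleusPanel(
        core18=panel.core18,
        extended57=extended,
        neuromodulatory=frozenset(a for a in panel.neuromodulatory if a in extended),
    )


def _draw_specificity(rng: np.random.Generator, masses: tuple[float, float, float]) -> float:
    band = rng.choice(3, p=list(masses))
    lo, hi = ((0.05, 0.499), (0.50, 0.749), (0.75, 0.98))[band]
    return float(rng.uniform(lo, hi))


def _signal(
    rng: np.random.Generator, cfg: GeneratorConfig, strength: float
) -> dict[str, float]:
    """Variable values on a true edge: floor + strength-scaled uniform lift."""
    out = {}
    for v in VARIABLES:
        f, s = cfg.signal_floors[v], cfg.signal_scales[v]
        u = 1.0 - rng.random()  # in (0, 1]
        out[v] = f + strength * (s - f) * u
    return out


def _background(rng: np.random.Generator, cfg: GeneratorConfig) -> dict[str, float]:
    return {v: float(rng.uniform(0.0, cfg.background_ceilings[v])) for v in VARIABLES}


def _make_volume(
    rng: np.random.Generator, cfg: GeneratorConfig, target_spec: float
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Injection grid and mask realizing ``target_spec`` (binarized) exactly.

    The mask is a half-space; the injection support is ``n_injection_voxels``
    voxels with the in-mask count set to round(target · K), so the realized
    binarized specificity deviates from the target by at most 1/(2K).
    """
    shape = cfg.grid_shape
    mask = np.zeros(shape)
    half = shape[0] // 2
    mask[:half, :, :] = 1.0
    inside = np.flatnonzero(mask.ravel() == 1)
    outside = np.flatnonzero(mask.ravel() == 0)
    K = cfg.n_injection_voxels
    k_in = int(round(target_spec * K))
    k_in = min(max(k_in, 0), K)
    chosen = np.concatenate(
        [
            rng.choice(inside, size=k_in, replace=False),
            rng.choice(outside, size=K - k_in, replace=False),
        ]
    )
    inj = np.zeros(shape).ravel()
    inj[chosen] = 0.5 + 0.5 * rng.random(K)  # densities in (0.5, 1]
    inj = inj.reshape(shape)
    binarized = k_in / K
    weighted = float(inj[mask.astype(bool)].sum() / inj.sum())
    return inj, mask, binarized, weighted


def generate(config: GeneratorConfig | None = None) -> SyntheticBundle:
    """Generate a fully seeded synthetic bundle from a planted connectome."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    ontology = build_ontology(cfg.n_structures)
    panel = _subpanel(load_panel(), ontology)
    nodes = ontology.acronyms
    n = len(nodes)

    # ---- planted adjacency with forced reference edges -------------------
    adjacency = (rng.random((n, n)) < cfg.edge_probability).astype(int)
    np.fill_diagonal(adjacency, 0)
    core_idx = [ontology.index(a) for a in panel.core18]
    core_pairs = [(i, j) for i in core_idx for j in core_idx if i != j]
    ref_choice = rng.choice(len(core_pairs), size=cfg.n_reference, replace=False)
    ref_pairs_idx = [core_pairs[k] for k in ref_choice]
    for i, j in ref_pairs_idx:
        adjacency[i, j] = 1
    strengths = np.where(adjacency == 1, 1.0 - rng.random((n, n)), 0.0)
    reference = ReferenceConnectionSet([(nodes[i], nodes[j]) for i, j in ref_pairs_idx])
    ref_set = set(reference.pairs)

    # ---- lines and their injected sources --------------------------------
    line_table_map = {"wild": "wild"}
    per_line_sources: dict[str, list[str]] = {"wild": list(nodes)}
    for cat, count in cfg.lines_per_category.items():
        for k in range(count):
            line_id = f"{cat[:3]}-{k}"
            line_table_map[line_id] = cat
            n_cov = max(1, int(round(cfg.line_source_coverage * n)))
            cov = rng.choice(n, size=n_cov, replace=False)
            per_line_sources[line_id] = [nodes[i] for i in sorted(cov)]
    line_table = LineCategoryTable(line_table_map)

    # ---- experiments ------------------------------------------------------
    experiments: list[ExperimentRecord] = []
    volumes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    confirmed_sources: set[str] = set()
    exp_counter = 0

    def add_experiment(line_id: str, source: str, spec_target: float) -> None:
        nonlocal exp_counter
        exp_id = f"exp-{exp_counter:04d}"
        exp_counter += 1
        inj, mask, binarized, weighted = _make_volume(rng, cfg, spec_target)
        hemi = "right" if rng.random() < 0.5 else "left"
        other = "left" if hemi == "right" else "right"
        si = ontology.index(source)
        projections = []
        for tj, target in enumerate(nodes):
            is_edge = bool(adjacency[si, tj]) and tj != si
            is_ref_wild = is_edge and line_id == "wild" and (source, target) in ref_set
            if is_ref_wild:
                ipsi = dict(cfg.signal_floors)  # exactly the planted floor
            elif is_edge:
                ipsi = _signal(rng, cfg, strengths[si, tj])
            else:
                ipsi = _background(rng, cfg)
            if is_edge and not is_ref_wild and rng.random() < cfg.contra_probability:
                contra = _signal(rng, cfg, strengths[si, tj])
            else:
                contra = _background(rng, cfg)
            projections.append(
                ProjectionMeasurement(structure=target, hemisphere=hemi, **ipsi)
            )
            projections.append(
                ProjectionMeasurement(structure=target, hemisphere=other, **contra)
            )
        experiments.append(
            ExperimentRecord(
                experiment_id=exp_id,
                line_id=line_id,
                source_structure=source,
                injection_hemisphere=hemi,
                specificity=SpecificityPair(binarized=binarized, weighted=weighted),
                projections=projections,
            )
        )
        volumes[exp_id] = (inj, mask)
        if binarized >= 0.5 and weighted >= 0.75:
            confirmed_sources.add(source)

    for source in nodes:  # wild-type: one guaranteed-gated + one mixture draw
        add_experiment("wild", source, float(rng.uniform(0.50, 0.98)))
        add_experiment("wild", source, _draw_specificity(rng, cfg.specificity_masses))
    for line_id, sources in per_line_sources.items():
        if line_id == "wild":
            continue
        for source in sources:
            add_experiment(line_id, source, _draw_specificity(rng, cfg.specificity_masses))

    confirmed_support = {
        (s, t)
        for (s, t) in GroundTruth(
            nodes=nodes,
            adjacency=adjacency,
            strengths=strengths,
            reference=reference,
            per_line_sources=per_line_sources,
        ).edge_pairs()
        if s in confirmed_sources
    }
    truth = GroundTruth(
        nodes=nodes,
        adjacency=adjacency,
        strengths=strengths,
        reference=reference,
        per_line_sources=per_line_sources,
        confirmed_support=confirmed_support,
    )
    return SyntheticBundle(
        config=cfg,
        ontology=ontology,
        panel=panel,
        experiments=experiments,
        volumes=volumes,
        truth=truth,
        line_table=line_table,
        reference=reference,
    )


def degrade(bundle: SyntheticBundle, overlap: float, seed: int = 0) -> SyntheticBundle:
    """Re-draw a fraction of true edges below the signal floors.

    ``overlap`` of the planted edges (possibly including reference edges) have
    their measured values replaced by background draws in every experiment.
    At overlap 0 this is the identity; at overlap 1 every true edge falls
    below the calibrated thresholds and pipeline recall (scored at thresholds
    equal to the planted floors) drops to 0.
    """
    if not 0 <= overlap <= 1:
        raise ValueError(f"overlap must be in [0, 1], got {overlap}")
    out = deepcopy(bundle)
    if overlap == 0:
        return out
    rng = np.random.default_rng(seed)
    edges = out.truth.edge_pairs()
    n_hit = math.ceil(overlap * len(edges))
    hit_idx = rng.choice(len(edges), size=n_hit, replace=False)
    hit = {edges[k] for k in hit_idx}
    cfg = out.config
    for rec in out.experiments:
        src = rec.source_structure
        for p in rec.projections:
            if (src, p.structure) in hit:
                for v in VARIABLES:
                    setattr(p, v, float(rng.uniform(0.0, cfg.background_ceilings[v])))
    out.degraded_edges = sorted(hit)
    return out
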