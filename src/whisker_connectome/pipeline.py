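"""End-to-end orchestration: gate → build → calibrate → binarize → classify → report.

The pipeline mirrors the data-processing order of the source experiments:
specificity gating of experiments, per-line variable matrices, hemisphere
merge, threshold calibration on wild-type data against the reference set,
four-variable consensus binarization per line, per-category combination,
edge classification on the 18-nucleus core panel, then graph-theoretic and
density characterization on the extended panel.  Every stage is a pure
function of its inputs plus the seed, so a re-run with the same config
produces byte-identical outputs (verified via content hashes in the
manifest).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import io as wio
from .calibration import (
    PRESETS,
    BinaryConnectome,
    ThresholdSet,
    binarize_consensus,
    calibrate,
)
from .classification import (
    ClassifiedConnectome,
    classify_edges,
    combine_categories,
    count_report,
)
from .density import profile_sources, topk_summary
from .errors import ConfigError, WhiskerConnectomeError
from .graphs import (
    TESTABLE_METRICS,
    GraphReport,
    PermutationResult,
    SmallWorldVerdict,
    ablation_permutation_test,
    nodal_metrics,
    small_world_verdict,
)
from .matrices import MergedMatrixSet, build_line_matrices, extract_subnetwork, merge_hemispheres
from .ontology import (
    NucleusPanel,
    Ontology,
    ReferenceConnectionSet,
)
from .records import VARIABLES
from .specificity import compute_specificity, gate_experiments
from .synthetic import GroundTruth, SyntheticBundle


class PipelineConfig(BaseModel):
    """Run-time knobs: gates, thresholds mode, permutation sizes, seed."""

    model_config = ConfigDict(extra="forbid")

    thresholds: str | dict[str, float] = "calibrate"  # or a preset name
    inclusion_gate: float = 0.50
    confirmation_gate: float = 0.75
    combine: str = "max"
    n_perm: int = 10_000
    n_null: int = 100
    seed: int = 0


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    config: PipelineConfig
    n_experiments: int
    n_gated: int
    thresholds: ThresholdSet
    thresholds_source: str
    per_line: dict[str, BinaryConnectome]
    category_maps: dict[str, BinaryConnectome]
    all_map: BinaryConnectome  # extended panel
    core_map: BinaryConnectome  # core-18 panel
    classified: ClassifiedConnectome  # on the core panel
    summary: dict
    graph_report: GraphReport
    small_world: SmallWorldVerdict
    permutations: dict[str, PermutationResult]
    density_topk: "object"  # tidy DataFrame
    density_no_data: list[str]
    stage_counts: dict = field(default_factory=dict)


def _subgraph(bc: BinaryConnectome, panel: list[str] | tuple[str, ...]) -> BinaryConnectome:
    idx = []
    pos = {a: i for i, a in enumerate(bc.nodes)}
    for a in panel:
        if a not in pos:
            raise ConfigError(f"panel acronym {a!r} not in connectome nodes")
        idx.append(pos[a])
    idx = np.array(idx)
    return BinaryConnectome(
        nodes=list(panel),
        adjacency=bc.adjacency[np.ix_(idx, idx)],
        measured=bc.measured[idx],
    )


def run_bundle(
    bundle: SyntheticBundle,
    config: PipelineConfig | None = None,
    literature: set[tuple[str, str]] | None = None,
) -> PipelineResult:
    """Run the full pipeline on an in-memory data bundle."""
    cfg = config or PipelineConfig()
    records = list(bundle.experiments)
    ontology = bundle.ontology
    panel = bundle.panel

    # Stage 1: specificity (compute from volumes where records lack it), gates.
    for rec in records:
        if rec.specificity is None:
            if rec.experiment_id not in bundle.volumes:
                raise WhiskerConnectomeError(
                    f"stage specificity: experiment {rec.experiment_id!r} has neither "
                    "a specificity value nor a volume/mask pair"
                )
            inj, mask = bundle.volumes[rec.experiment_id]
            rec.specificity = compute_specificity(inj, mask)
    gated = gate_experiments(records, "inclusion", cfg.inclusion_gate)

    # Stage 2: per-line matrices, hemisphere merge, panel extraction.
    lines = sorted({r.line_id for r in gated})
    merged: dict[str, MergedMatrixSet] = {}
    for line in lines:
        wide = build_line_matrices(gated, line, ontology, combine=cfg.combine)
        merged[line] = extract_subnetwork(
            merge_hemispheres(wide), panel.extended57, ontology
        )

    # Stage 3: thresholds.
    if isinstance(cfg.thresholds, dict):
        theta = ThresholdSet(**{v: cfg.thresholds[v] for v in VARIABLES})
        theta_source = "explicit"
    elif cfg.thresholds == "calibrate":
        if "wild" not in merged:
            raise WhiskerConnectomeError("stage calibrate: no gated wild-type experiments")
        theta = calibrate(merged["wild"], bundle.reference)
        theta_source = "calibrated"
    elif cfg.thresholds in PRESETS:
        theta = PRESETS[cfg.thresholds]
        theta_source = f"preset:{cfg.thresholds}"
    else:
        raise ConfigError(f"unknown thresholds mode {cfg.thresholds!r}")

    # Stage 4: consensus binarization per line, per-category combination.
    per_line = {line: binarize_consensus(m, theta) for line, m in merged.items()}
    category_maps = combine_categories(per_line, bundle.line_table)
    all_map = category_maps["all"]

    # Stage 5: anatomical-confirmation support from the 75 % tier.
    confirmed = gate_experiments(gated, "confirmation", cfg.confirmation_gate)
    confirmed_sources = {r.source_structure for r in confirmed}
    confirmed_support = {
        (s, t) for s, t in all_map.edges() if s in confirmed_sources
    }

    # Stage 6: classification and counts on the core panel.
    lit = literature if literature is not None else set(bundle.reference.pairs)
    core_map = _subgraph(all_map, panel.core18)
    core_categories = {
        cat: _subgraph(bc, panel.core18) for cat, bc in category_maps.items()
    }
    core_nodes = set(panel.core18)
    core_support = {
        (s, t) for s, t in confirmed_support if s in core_nodes and t in core_nodes
    }
    classified = classify_edges(core_map, lit, core_support, core_categories)
    summary = count_report(classified)

    # Stage 7: graph analysis on the extended panel.
    groups = {a: ontology.group(a) for a in all_map.nodes}
    graph_report = nodal_metrics(all_map, groups=groups)
    sw = small_world_verdict(all_map, n_null=cfg.n_null, seed=cfg.seed)
    remove = sorted(set(panel.neuromodulatory) & set(all_map.nodes))
    permutations = {
        metric: ablation_permutation_test(
            all_map, remove, metric, n_perm=cfg.n_perm, seed=cfg.seed
        )
        for metric in TESTABLE_METRICS
    }

    # Stage 8: outgoing-density concentration profiles.
    density_matrix = _combined_density(merged)
    profiles, no_data = profile_sources(density_matrix, groups=groups, detected=all_map)
    topk = topk_summary(profiles)

    stage_counts = {
        "experiments_total": len(records),
        "experiments_gated": len(gated),
        "experiments_confirmation_tier": len(confirmed),
        "lines": len(lines),
        "edges_per_category": {
            cat: bc.edge_count() for cat, bc in category_maps.items()
        },
        "statuses": classified.status_counts(),
    }
    return PipelineResult(
        config=cfg,
        n_experiments=len(records),
        n_gated=len(gated),
        thresholds=theta,
        thresholds_source=theta_source,
        per_line=per_line,
        category_maps=category_maps,
        all_map=all_map,
        core_map=core_map,
        classified=classified,
        summary=summary,
        graph_report=graph_report,
        small_world=sw,
        permutations=permutations,
        density_topk=topk,
        density_no_data=no_data,
        stage_counts=stage_counts,
    )


def _combined_density(merged: dict[str, MergedMatrixSet]) -> MergedMatrixSet:
    """Elementwise max of per-line merged matrices (measured = any line)."""
    first = next(iter(merged.values()))
    variables = {v: np.zeros_like(first.variables[v]) for v in VARIABLES}
    measured = np.zeros(first.n, dtype=bool)
    for m in merged.values():
        measured |= m.measured
        for v in VARIABLES:
            variables[v] = np.maximum(variables[v], m.variables[v])
    return MergedMatrixSet(
        line_id="all",
        sources=list(first.sources),
        variables=variables,
        measured=measured,
    )


def recovery_scores(all_map: BinaryConnectome, truth: GroundTruth) -> dict[str, float]:
    """Precision / recall of the detected map against the planted adjacency.

    Scored on off-diagonal ordered pairs over the map's node panel.
    """
    pos = {a: i for i, a in enumerate(truth.nodes)}
    idx = np.array([pos[a] for a in all_map.nodes])
    planted = truth.adjacency[np.ix_(idx, idx)].astype(bool)
    detected = all_map.adjacency.astype(bool)
    off = ~np.eye(len(all_map.nodes), dtype=bool)
    tp = int((planted & detected & off).sum())
    fp = int((~planted & detected & off).sum())
    fn = int((planted & ~detected & off).sum())
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {"tp": tp, "fp": fp, "fn": fn, "precision": precision, "recall": recall}


# ---------------------------------------------------------------------------
# Disk round-trip: write a bundle, run from disk, emit outputs + manifest
# ---------------------------------------------------------------------------


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> None:
    """Serialize a bundle into the on-disk dialects the pipeline reads."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    wio.write_experiments(bundle.experiments, d / "experiments")
    vol_dir = d / "volumes"
    vol_dir.mkdir(exist_ok=True)
    for exp_id, (inj, mask) in bundle.volumes.items():
        wio.write_volume(inj, vol_dir / f"{exp_id}.injection.json")
        wio.write_volume(mask, vol_dir / f"{exp_id}.mask.json")
    lines = ["acronym\tgroup"]
    lines += [f"{a}\t{bundle.ontology.group(a)}" for a in bundle.ontology.acronyms]
    (d / "ontology.tsv").write_text("\n".join(lines) + "\n")
    (d / "panel.json").write_text(
        json.dumps(
            {
                "core18": list(bundle.panel.core18),
                "extended57": list(bundle.panel.extended57),
                "neuromodulatory": sorted(bundle.panel.neuromodulatory),
            },
            indent=1,
        )
        + "\n"
    )
    wio.write_line_categories(bundle.line_table, d / "line_categories.tsv")
    ref_lines = ["source\ttarget"] + [f"{s}\t{t}" for s, t in bundle.reference]
    (d / "reference.tsv").write_text("\n".join(ref_lines) + "\n")
    truth_payload = {
        "nodes": bundle.truth.nodes,
        "adjacency": bundle.truth.adjacency.tolist(),
        "confirmed_support": sorted(bundle.truth.confirmed_support),
    }
    (d / "ground_truth.json").write_text(json.dumps(truth_payload, indent=1) + "\n")


def read_bundle(directory: str | Path) -> SyntheticBundle:
    """Load a bundle previously written by :func:`write_bundle`."""
    from .synthetic import GeneratorConfig  # local to avoid import noise

    d = Path(directory)
    entries = []
    for line in (d / "ontology.tsv").read_text().splitlines()[1:]:
        if line:
            a, g = line.split("\t")
            entries.append((a, g))
    ontology = Ontology(entries)
    payload = json.loads((d / "panel.json").read_text())
    panel = NucleusPanel(
        core18=tuple(payload["core18"]),
        extended57=tuple(payload["extended57"]),
        neuromodulatory=frozenset(payload["neuromodulatory"]),
    )
    records = wio.read_experiments(d / "experiments", ontology)
    volumes = {}
    vol_dir = d / "volumes"
    if vol_dir.is_dir():
        for f in sorted(vol_dir.glob("*.injection.json")):
            exp_id = f.name.removesuffix(".injection.json")
            volumes[exp_id] = (
                wio.read_volume(f),
                wio.read_volume(vol_dir / f"{exp_id}.mask.json"),
            )
    line_table = wio.read_line_categories(d / "line_categories.tsv")
    ref_pairs = []
    for line in (d / "reference.tsv").read_text().splitlines()[1:]:
        if line:
            s, t = line.split("\t")
            ref_pairs.append((s, t))
    reference = ReferenceConnectionSet(ref_pairs)
    tp = json.loads((d / "ground_truth.json").read_text())
    truth = GroundTruth(
        nodes=tp["nodes"],
        adjacency=np.asarray(tp["adjacency"], dtype=int),
        strengths=np.zeros((len(tp["nodes"]), len(tp["nodes"]))),
        reference=reference,
        per_line_sources={},
        confirmed_support={tuple(e) for e in tp["confirmed_support"]},
    )
    return SyntheticBundle(
        config=GeneratorConfig(),
        ontology=ontology,
        panel=panel,
        experiments=records,
        volumes=volumes,
        truth=truth,
        line_table=line_table,
        reference=reference,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(
    data_dir: str | Path,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Disk-based run: read a dataset directory, write outputs and a manifest."""
    cfg = config or PipelineConfig()
    bundle = read_bundle(data_dir)
    result = run_bundle(bundle, cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    wio.write_thresholds(result.thresholds, out / "thresholds.json")
    for cat, bc in sorted(result.category_maps.items()):
        wio.write_binary_adjacency(bc, out / f"adjacency_{cat}.tsv")
    wio.write_connectome(result.classified, out / "classified")
    (out / "summary.json").write_text(
        json.dumps(result.summary, indent=1, sort_keys=True) + "\n"
    )
    graph_payload = {
        "global_mean": result.graph_report.global_mean,
        "global_sd": result.graph_report.global_sd,
        "hubs": sorted(result.graph_report.hub_set),
        "group_shares": result.graph_report.group_shares,
        "n_edges": result.graph_report.n_edges,
        "small_world": {
            "clustering_graph": result.small_world.clustering_graph,
            "clustering_er": result.small_world.clustering_er,
            "path_graph": result.small_world.path_graph,
            "path_er": result.small_world.path_er,
            "is_small_world": result.small_world.is_small_world,
        },
        "permutations": {
            m: {
                "observed_statistic": r.observed_statistic,
                "p_value": r.p_value,
                "n_permutations": r.n_permutations,
            }
            for m, r in result.permutations.items()
        },
    }
    (out / "graph_report.json").write_text(
        json.dumps(graph_payload, indent=1, sort_keys=True) + "\n"
    )
    result.graph_report.nodal.to_csv(out / "nodal_metrics.tsv", sep="\t")
    result.density_topk.to_csv(out / "density_topk.tsv", sep="\t", index=False)

    outputs = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config": json.loads(cfg.model_dump_json()),
        "stage_counts": result.stage_counts,
        "thresholds_source": result.thresholds_source,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
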