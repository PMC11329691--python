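"""Readers and writers for experiment records, volumes, matrices and connectomes.

Formats are deliberately plain text: experiment records are one JSON document
per experiment; adjacency matrices are TSV with acronym headers; voxel
volumes and masks are dense 3-D rasters stored as JSON with a header-declared
shape; thresholds and summaries are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .calibration import BinaryConnectome, ThresholdSet
from .classification import ClassifiedConnectome, EdgeInfo
from .errors import SchemaError
from .matrices import MergedMatrixSet
from .ontology import LineCategoryTable, Ontology
from .records import ExperimentRecord, validate_record

# ---------------------------------------------------------------------------
# Experiment records
# ---------------------------------------------------------------------------


def read_experiments(
    path: str | Path, ontology: Ontology | None = None
) -> list[ExperimentRecord]:
    """Read validated experiment records from a JSON file or a directory.

    A directory is scanned for ``*.json`` (one record per file, sorted by
    name); a file may hold a single record object or a list of records.
    Validation failures raise :class:`SchemaError` naming the experiment and
    field; unresolvable acronyms raise :class:`OntologyError`.
    """
    path = Path(path)
    payloads: list[dict] = []
    if path.is_dir():
        for f in sorted(path.glob("*.json")):
            payloads.append(_load_json(f))
    else:
        doc = _load_json(path)
        payloads = doc if isinstance(doc, list) else [doc]
    return [validate_record(p, ontology) for p in payloads]


def write_experiments(records: list[ExperimentRecord], directory: str | Path) -> list[Path]:
    """Write one JSON file per record into ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for rec in records:
        p = directory / f"{rec.experiment_id}.json"
        p.write_text(json.dumps(rec.model_dump(), indent=1, sort_keys=True) + "\n")
        paths.append(p)
    return paths


def _load_json(path: Path):
    try:
        return json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON: {exc}") from exc


# ---------------------------------------------------------------------------
# Dense 3-D rasters (injection volumes and structure masks)
# ---------------------------------------------------------------------------


def write_volume(grid: np.ndarray, path: str | Path) -> None:
    """Store a dense 3-D raster as JSON: declared shape plus flat values."""
    grid = np.asarray(grid)
    payload = {"shape": list(grid.shape), "data": [float(x) for x in grid.ravel()]}
    Path(path).write_text(json.dumps(payload))


def read_volume(path: str | Path) -> np.ndarray:
    payload = _load_json(Path(path))
    try:
        shape = tuple(payload["shape"])
        data = np.asarray(payload["data"], dtype=float)
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: raster must declare 'shape' and 'data'") from exc
    if data.size != int(np.prod(shape)):
        raise SchemaError(
            f"{path}: {data.size} values do not fill declared shape {shape}"
        )
    return data.reshape(shape)


# ---------------------------------------------------------------------------
# Matrices, thresholds, categories
# ---------------------------------------------------------------------------


def write_merged_matrices(m: MergedMatrixSet, directory: str | Path) -> None:
    """TSV per variable with acronym headers, plus a sidecar flags/provenance JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for var, mat in m.variables.items():
        _write_matrix_tsv(mat, m.sources, directory / f"{m.line_id}.{var}.tsv")
    sidecar = {
        "line_id": m.line_id,
        "unmeasured": [a for a, f in zip(m.sources, m.measured) if not f],
        "provenance": m.provenance,
    }
    (directory / f"{m.line_id}.flags.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n"
    )


def _write_matrix_tsv(mat: np.ndarray, nodes: list[str], path: Path) -> None:
    lines = ["\t".join(["source\\target"] + list(nodes))]
    for name, row in zip(nodes, np.asarray(mat)):
        lines.append("\t".join([name] + [repr(float(x)) for x in row]))
    path.write_text("\n".join(lines) + "\n")


def _read_matrix_tsv(path: Path) -> tuple[np.ndarray, list[str]]:
    rows = [l.split("\t") for l in Path(path).read_text().splitlines() if l]
    nodes = rows[0][1:]
    mat = np.array([[float(x) for x in r[1:]] for r in rows[1:]])
    return mat, nodes


def write_thresholds(theta: ThresholdSet, path: str | Path) -> None:
    units = {"density": "a.u.", "intensity": "a.u.", "energy": "a.u.", "volume": "mm^3"}
    payload = {v: {"value": x, "unit": units[v]} for v, x in theta.as_dict().items()}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_thresholds(path: str | Path) -> ThresholdSet:
    payload = _load_json(Path(path))
    return ThresholdSet(**{v: payload[v]["value"] for v in payload})


def write_line_categories(table: LineCategoryTable, path: str | Path) -> None:
    lines = ["line_id\tcategory"]
    lines += [f"{l}\t{c}" for l, c in sorted(table.as_dict().items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_line_categories(path: str | Path) -> LineCategoryTable:
    mapping = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("line_id\t"):
            continue
        l, c = line.split("\t")
        mapping[l] = c
    return LineCategoryTable(mapping)


# ---------------------------------------------------------------------------
# Classified connectomes
# ---------------------------------------------------------------------------


def write_connectome(c: ClassifiedConnectome, base: str | Path) -> tuple[Path, Path]:
    """Write ``<base>.edges.tsv`` (edge list) and ``<base>.adjacency.tsv``.

    The edge list holds source, target, status and the supporting categories;
    the adjacency table is the square binary matrix.  :func:`read_connectome`
    on the same base reproduces the map exactly.
    """
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    edges_path = base.with_suffix(".edges.tsv")
    adj_path = base.with_suffix(".adjacency.tsv")
    lines = ["source\ttarget\tstatus\tcategories"]
    for (s, t), info in sorted(c.edges.items()):
        lines.append(f"{s}\t{t}\t{info.status}\t{','.join(sorted(info.categories))}")
    edges_path.write_text("\n".join(lines) + "\n")
    _write_matrix_tsv(c.adjacency().astype(float), c.nodes, adj_path)
    return edges_path, adj_path


def read_connectome(base: str | Path) -> ClassifiedConnectome:
    base = Path(base)
    adj, nodes = _read_matrix_tsv(base.with_suffix(".adjacency.tsv"))
    edges: dict[tuple[str, str], EdgeInfo] = {}
    for line in base.with_suffix(".edges.tsv").read_text().splitlines()[1:]:
        if not line:
            continue
        s, t, status, cats = line.split("\t")
        edges[(s, t)] = EdgeInfo(status=status, categories=frozenset(cats.split(",")))
    c = ClassifiedConnectome(nodes=nodes, edges=edges)
    if not np.array_equal(c.adjacency(), adj.astype(int)):
        raise SchemaError(f"{base}: edge list and adjacency table disagree")
    return c


def write_binary_adjacency(bc: BinaryConnectome, path: str | Path) -> None:
    _write_matrix_tsv(bc.adjacency.astype(float), bc.nodes, Path(path))
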