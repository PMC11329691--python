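"""Structure ontology, nucleus panels, line categories and reference connections.

The ontology is a flat, ordered list of brain structures, mirrored across the
two hemispheres: every structure exists once per hemisphere, identified by its
canonical acronym plus a hemisphere label.  Acronym synonyms that circulate in
the literature (``SSp-bfd`` for ``bfd``, ``M1`` for ``MOp``, ``nRT`` for
``RT``) are resolved through an alias table, so inputs may use either form.

A :class:`NucleusPanel` names the nuclei of interest: the 18-nucleus core of
the whisker sensorimotor system, the 57-nucleus extended network, and the
subset of neuromodulator-releasing nuclei removed in the ablation comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ConfigError, OntologyError

HEMISPHERES = ("left", "right")

#: Literature synonyms resolved to canonical acronyms.
DEFAULT_ALIASES: dict[str, str] = {
    "SSp-bfd": "bfd",
    "M1": "MOp",
    "Mop": "MOp",
    "nRT": "RT",
    "PoM": "PO",
}

#: Anatomical groups cycled over filler structures in synthetic ontologies.
_FILLER_GROUPS = (
    "midbrain",
    "thalamus",
    "cortex",
    "medulla",
    "hindbrain",
    "striatum",
    "cerebellum",
    "amygdala",
    "hypothalamus",
    "pallidum",
)


@dataclass(frozen=True)
class Structure:
    """One brain structure in one hemisphere."""

    id: int
    acronym: str
    hemisphere: str
    group: str

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise OntologyError(f"unknown hemisphere {self.hemisphere!r}")


class Ontology:
    """Ordered set of structures, mirrored over both hemispheres.

    Parameters
    ----------
    entries
        Ordered ``(acronym, group)`` pairs for one hemisphere; the other
        hemisphere is implied (every structure appears in both).
    aliases
        Synonym → canonical-acronym map, merged over :data:`DEFAULT_ALIASES`.
    """

    def __init__(
        self,
        entries: Iterable[tuple[str, str]],
        aliases: Mapping[str, str] | None = None,
    ) -> None:
        entries = list(entries)
        acronyms = [a for a, _ in entries]
        if len(set(acronyms)) != len(acronyms):
            dupes = sorted({a for a in acronyms if acronyms.count(a) > 1})
            raise OntologyError(f"duplicate acronyms in ontology: {dupes}")
        self._acronyms: list[str] = acronyms
        self._groups: dict[str, str] = dict(entries)
        self._index: dict[str, int] = {a: i for i, a in enumerate(acronyms)}
        self._aliases: dict[str, str] = dict(DEFAULT_ALIASES)
        if aliases:
            self._aliases.update(aliases)

    def __len__(self) -> int:
        return len(self._acronyms)

    def __contains__(self, acronym: str) -> bool:
        try:
            self.resolve(acronym)
        except OntologyError:
            return False
        return True

    @property
    def acronyms(self) -> list[str]:
        """Canonical acronyms, in ontology order (one hemisphere)."""
        return list(self._acronyms)

    def resolve(self, acronym: str) -> str:
        """Map an acronym or a known synonym to its canonical form."""
        canonical = self._aliases.get(acronym, acronym)
        if canonical not in self._index:
            raise OntologyError(f"unknown structure acronym {acronym!r}")
        return canonical

    def index(self, acronym: str) -> int:
        return self._index[self.resolve(acronym)]

    def group(self, acronym: str) -> str:
        return self._groups[self.resolve(acronym)]

    def structures(self) -> list[Structure]:
        """All structures over both hemispheres (left block, then right)."""
        out = []
        for hemi in HEMISPHERES:
            for i, a in enumerate(self._acronyms):
                out.append(Structure(id=i, acronym=a, hemisphere=hemi, group=self._groups[a]))
        return out


@dataclass(frozen=True)
class NucleusPanel:
    """Named nucleus panels: 18-core, 57-extended, neuromodulatory subset."""

    core18: tuple[str, ...]
    extended57: tuple[str, ...]
    neuromodulatory: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.core18) != 18:
            raise ConfigError(f"core panel must have 18 entries, got {len(self.core18)}")
        if len(set(self.core18)) != 18:
            raise ConfigError("core panel acronyms must be unique")
        if len(set(self.extended57)) != len(self.extended57):
            raise ConfigError("extended panel acronyms must be unique")
        missing = set(self.core18) - set(self.extended57)
        if missing:
            raise ConfigError(f"core panel not a subset of extended panel: {sorted(missing)}")
        stray = set(self.neuromodulatory) - set(self.extended57)
        if stray:
            raise ConfigError(f"neuromodulatory set not within extended panel: {sorted(stray)}")


class LineCategoryTable:
    """Total map from transgenic line id to its cell-type category.

    Categories follow the standard characterization of transgenic tracer
    lines: ``excitatory`` (glutamatergic markers), ``inhibitory`` (GABA /
    glycine markers), ``uncategorized`` (mixed or neuromodulatory markers),
    and ``wild`` for wild-type animals.
    """

    CATEGORIES = ("wild", "excitatory", "inhibitory", "uncategorized")

    def __init__(self, mapping: Mapping[str, str]) -> None:
        for line, cat in mapping.items():
            if cat not in self.CATEGORIES:
                raise ConfigError(f"line {line!r}: unknown category {cat!r}")
        self._map = dict(mapping)

    def __contains__(self, line_id: str) -> bool:
        return line_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    def category(self, line_id: str) -> str:
        try:
            return self._map[line_id]
        except KeyError:
            raise ConfigError(f"line {line_id!r} missing from category table") from None

    def lines(self, category: str | None = None) -> list[str]:
        if category is None:
            return sorted(self._map)
        return sorted(l for l, c in self._map.items() if c == category)

    def as_dict(self) -> dict[str, str]:
        return dict(self._map)


class ReferenceConnectionSet:
    """Directed (source, target) acronym pairs used as calibration anchors."""

    def __init__(self, pairs: Iterable[tuple[str, str]]) -> None:
        pairs = [tuple(p) for p in pairs]
        for s, t in pairs:
            if s == t:
                raise ConfigError(f"reference set may not contain self-pair ({s}, {t})")
        if len(set(pairs)) != len(pairs):
            raise ConfigError("reference set contains duplicate pairs")
        self._pairs: tuple[tuple[str, str], ...] = tuple(pairs)

    def __iter__(self):
        return iter(self._pairs)

    def __len__(self) -> int:
        return len(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return tuple(pair) in set(self._pairs)

    @property
    def pairs(self) -> tuple[tuple[str, str], ...]:
        return self._pairs


# ---------------------------------------------------------------------------
# Shipped defaults
# ---------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("whisker_connectome").joinpath("data", name)))


def load_panel(config: str | Path | None = None) -> NucleusPanel:
    """Load a nucleus panel from a JSON config (default: the shipped panel).

    The config must list ``core18`` (exactly 18 acronyms), ``extended57``
    (superset of the core) and ``neuromodulatory`` (subset of the extended
    panel).  Invariant violations raise :class:`ConfigError`.
    """
    path = _data_path("panel_57.json") if config is None else Path(config)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read panel config {path}: {exc}") from exc
    for key in ("core18", "extended57", "neuromodulatory"):
        if key not in payload:
            raise ConfigError(f"panel config missing key {key!r}")
    return NucleusPanel(
        core18=tuple(payload["core18"]),
        extended57=tuple(payload["extended57"]),
        neuromodulatory=frozenset(payload["neuromodulatory"]),
    )


def load_reference_set(path: str | Path | None = None) -> ReferenceConnectionSet:
    """Load the reference-connection list from a two-column TSV (default shipped)."""
    p = _data_path("reference_34.tsv") if path is None else Path(path)
    pairs = []
    for lineno, line in enumerate(p.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "source" and fields[1] == "target":
            continue  # header
        if len(fields) < 2:
            raise ConfigError(f"{p}:{lineno}: expected 2 tab-separated columns")
        pairs.append((fields[0], fields[1]))
    return ReferenceConnectionSet(pairs)


def default_panel_entries() -> list[tuple[str, str]]:
    """(acronym, group) pairs for the shipped 57-nucleus extended panel."""
    payload = json.loads(_data_path("panel_57.json").read_text())
    return [(a, g) for a, g in payload["groups"].items()]


def build_ontology(n_structures: int, panel: NucleusPanel | None = None) -> Ontology:
    """Build an ontology of ``n_structures`` per hemisphere.

    Panel nuclei come first (with their anatomical groups); remaining slots
    are filled with placeholder structures ``BS<k>`` whose groups cycle over
    the standard anatomical divisions.  Used by the synthetic generator and
    anywhere a full 723-structure parcellation is not required.
    """
    panel = panel or load_panel()
    named = default_panel_entries()
    ordered = [e for e in named if e[0] in panel.core18]
    ordered += [e for e in named if e[0] not in panel.core18]
    if n_structures < len(panel.core18):
        raise ConfigError(
            f"need at least {len(panel.core18)} structures to host the core panel"
        )
    entries = ordered[:n_structures]
    k = 0
    while len(entries) < n_structures:
        entries.append((f"BS{k}", _FILLER_GROUPS[k % len(_FILLER_GROUPS)]))
        k += 1
    return Ontology(entries)
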