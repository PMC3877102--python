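"""Projection of screen scores onto a pathway model.

Species are read from an SBML Level 2 file (CellDesigner-flavoured files
are plain SBML with vendor annotations, which are ignored).  Each species'
predicted binding affinity is rendered on a white-to-red scale over
0–10 pKd — white at 0, fully red at 10, scores above the range clamped to
10 — and species with no structure or no generated binding mode stay gray.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import floor, isfinite
from pathlib import Path
from typing import Mapping

from lxml import etree

logger = logging.getLogger(__name__)

SCALE_MIN: float = 0.0
SCALE_MAX: float = 10.0
GRAY_RGB: tuple[int, int, int] = (190, 190, 190)

#: Species names treated as small molecules / currency metabolites, not proteins.
_NON_PROTEIN_NAMES = {"atp", "adp", "gtp", "gdp", "amp", "camp", "pi", "h2o", "ca2+"}


@dataclass
class Species:
    id: str
    name: str
    is_protein_like: bool


def read_network_species(path: str | Path) -> list[Species]:
    """Species (id, display name) of an SBML Level 2 model, in document order.

    Protein-likeness is a logged heuristic on the display name; the caller
    may override it via the identity-to-structure mapping table.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if etree.QName(root).localname != "sbml":
        raise ValueError(f"{path}: root element is <{root.tag}>, not <sbml>")
    nodes = root.findall(".//{*}listOfSpecies/{*}species")
    species: list[Species] = []
    for node in nodes:
        sid = node.get("id")
        if sid is None:
            raise ValueError(f"{path}: species element without an id attribute")
        name = node.get("name", sid)
        protein_like = name.lower() not in _NON_PROTEIN_NAMES
        if not protein_like:
            logger.info("species %s (%s) flagged as non-protein", sid, name)
        species.append(Species(id=sid, name=name, is_protein_like=protein_like))
    if not species:
        logger.warning("%s: model declares no species", path)
    return species


def score_to_color(score: float) -> tuple[int, int, int]:
    """Map a docking score to the white-to-red scale.

    Linear interpolation from white (255,255,255) at 0 to red (255,0,0) at
    10; values outside [0, 10] are clamped (a score that exceeds the range
    is set as 10).  Channels round half-up.
    """
    if not isfinite(score):
        raise ValueError(f"score must be finite, got {score!r}")
    s = min(max(score, SCALE_MIN), SCALE_MAX)
    gb = int(floor(255 * (1 - s / SCALE_MAX) + 0.5))
    return (255, gb, gb)


@dataclass
class SpeciesAnnotation:
    species_id: str
    name: str
    score: float | None
    rgb: tuple[int, int, int]
    status: str  # "ok" | "gray"


@dataclass
class NetworkAnnotation:
    """One entry per model species, plus scores that matched no species."""

    entries: dict[str, SpeciesAnnotation]
    orphan_scores: dict[str, float] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        return [
            {
                "species_id": a.species_id,
                "name": a.name,
                "score": a.score,
                "rgb": "#%02x%02x%02x" % a.rgb,
                "status": a.status,
            }
            for a in self.entries.values()
        ]


def annotate_network(
    species: list[Species], scores: Mapping[str, float]
) -> NetworkAnnotation:
    """Join screen scores onto model species; unmatched species render gray.

    The join is by species id, falling back to case-insensitive display
    name (logged).  Scores matching no species are collected as orphans,
    never dropped silently.
    """
    ids = [sp.id for sp in species]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate species ids in model: {dupes}")
    by_name = {}
    for sp in species:
        by_name.setdefault(sp.name.lower(), sp.id)

    resolved: dict[str, float] = {}
    orphans: dict[str, float] = {}
    id_set = set(ids)
    for key, score in scores.items():
        if key in id_set:
            resolved[key] = score
        elif key.lower() in by_name:
            logger.info("score key %r matched species by display name", key)
            resolved[by_name[key.lower()]] = score
        else:
            orphans[key] = score

    entries: dict[str, SpeciesAnnotation] = {}
    for sp in species:
        if sp.id in resolved:
            score = resolved[sp.id]
            entries[sp.id] = SpeciesAnnotation(
                sp.id, sp.name, score, score_to_color(score), "ok"
            )
        else:
            entries[sp.id] = SpeciesAnnotation(sp.id, sp.name, None, GRAY_RGB, "gray")
    return NetworkAnnotation(entries=entries, orphan_scores=orphans)
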