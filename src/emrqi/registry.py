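"""Three-level weighted quality-indicator hierarchy.

The index system is a depth-3 tree: four first-level quality dimensions
(Operability, Completeness, Correctness, Timeliness), eleven second-level
sub-dimensions, and thirty-three computable third-level (leaf) indicators.
Weights are stored as *absolute* (global-scale) fractions, printed to three
decimals in the packaged default; relative weights among siblings are derived
as ``absolute / parent_absolute`` rather than stored, so there is a single
source of truth.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "IndicatorNode",
    "IndexSystem",
    "IndexValidationError",
    "WeightReport",
    "load_index_system",
    "default_index_system",
    "validate_weights",
]

#: Residual tolerated between a parent's absolute weight and the sum of its
#: children's, to absorb 3-decimal rounding of published weights.
DEFAULT_WEIGHT_TOLERANCE = 0.002


class IndexValidationError(ValueError):
    """Structural or weight-conservation failure; lists offending nodes."""

    def __init__(self, message: str, offenders: list[str] | None = None):
        super().__init__(message)
        self.offenders = offenders or []


@dataclass(frozen=True)
class IndicatorNode:
    id: str
    name: str
    level: int
    absolute_weight: float
    parent_id: str | None = None
    calculator_id: str | None = None

    def __post_init__(self):
        if self.level not in (1, 2, 3):
            raise IndexValidationError(f"node {self.id}: level must be 1, 2 or 3")
        if not (0.0 < self.absolute_weight <= 1.0):
            raise IndexValidationError(
                f"node {self.id}: absolute weight {self.absolute_weight} outside (0, 1]"
            )
        if self.level == 3 and not self.calculator_id:
            raise IndexValidationError(f"leaf node {self.id} lacks a calculator")
        if self.level in (1, 2) and self.calculator_id:
            raise IndexValidationError(f"non-leaf node {self.id} declares a calculator")
        if self.level == 1 and self.parent_id is not None:
            raise IndexValidationError(f"level-1 node {self.id} must not have a parent")
        if self.level > 1 and self.parent_id is None:
            raise IndexValidationError(f"node {self.id} (level {self.level}) lacks a parent")


@dataclass
class IndexSystem:
    """Validated weighted tree of quality indicators."""

    nodes: dict[str, IndicatorNode]
    name: str = "index-system"
    version: str = "0"
    provenance: str = ""
    _children: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._children = {}
        for node in self.nodes.values():
            if node.parent_id is not None:
                self._children.setdefault(node.parent_id, []).append(node.id)
        self._validate_structure()

    # -- structure -----------------------------------------------------

    def _validate_structure(self) -> None:
        offenders = []
        for node in self.nodes.values():
            if node.parent_id is None:
                continue
            parent = self.nodes.get(node.parent_id)
            if parent is None:
                offenders.append(f"{node.id}: orphan (parent {node.parent_id} missing)")
            elif parent.level != node.level - 1:
                offenders.append(
                    f"{node.id}: parent {parent.id} is level {parent.level}, "
                    f"expected {node.level - 1}"
                )
        if offenders:
            raise IndexValidationError("invalid tree structure", offenders)

    def level(self, level: int) -> list[IndicatorNode]:
        return sorted(
            (n for n in self.nodes.values() if n.level == level), key=lambda n: n.id
        )

    @property
    def leaves(self) -> list[IndicatorNode]:
        return self.level(3)

    def children(self, node_id: str) -> list[IndicatorNode]:
        return [self.nodes[c] for c in self._children.get(node_id, [])]

    def relative_weight(self, node_id: str) -> float:
        node = self.nodes[node_id]
        if node.parent_id is None:
            return node.absolute_weight
        return node.absolute_weight / self.nodes[node.parent_id].absolute_weight

    # -- serialization -------------------------------------------------

    def to_config(self) -> dict:
        entries = []
        for node in sorted(self.nodes.values(), key=lambda n: (n.level, n.id)):
            e = {"id": node.id, "name": node.name, "level": node.level,
                 "weight": node.absolute_weight}
            if node.parent_id:
                e["parent"] = node.parent_id
            if node.calculator_id:
                e["calculator"] = node.calculator_id
            entries.append(e)
        return {"name": self.name, "version": self.version,
                "provenance": self.provenance, "nodes": entries}

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_config(), sort_keys=False))

    def content_hash(self) -> str:
        """Stable hash of ids + full-precision weights, for provenance blocks."""
        payload = json.dumps(
            [(n.id, n.parent_id, n.absolute_weight) for n in
             sorted(self.nodes.values(), key=lambda x: x.id)]
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class WeightReport:
    """Per-parent weight-conservation residuals."""

    residuals: dict[str, float]     # parent id -> |sum(children) - parent|
    root_residual: float            # |sum(level-1) - 1|
    tolerance: float

    @property
    def passed(self) -> bool:
        worst = max(self.residuals.values(), default=0.0)
        return worst <= self.tolerance and self.root_residual <= self.tolerance

    @property
    def failing_parents(self) -> list[str]:
        bad = [p for p, r in self.residuals.items() if r > self.tolerance]
        if self.root_residual > self.tolerance:
            bad.append("<root>")
        return bad


def validate_weights(system: IndexSystem,
                     tolerance: float = DEFAULT_WEIGHT_TOLERANCE) -> WeightReport:
    """Check that every parent's weight equals the sum of its children's.

    Report-only: never raises. Printed weights are rounded, so small residuals
    are expected; the default tolerance absorbs 3-decimal rounding drift.
    """
    residuals = {}
    for node in system.nodes.values():
        kids = system.children(node.id)
        if kids:
            residuals[node.id] = abs(
                sum(k.absolute_weight for k in kids) - node.absolute_weight
            )
    root_residual = abs(sum(n.absolute_weight for n in system.level(1)) - 1.0)
    return WeightReport(residuals=residuals, root_residual=root_residual,
                        tolerance=tolerance)


def _load_config(source) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    text = Path(source).read_text()
    return yaml.safe_load(text)


def load_index_system(source, tolerance: float = DEFAULT_WEIGHT_TOLERANCE,
                      check_weights: bool = True) -> IndexSystem:
    """Load and validate an index system from a YAML/JSON path or a mapping.

    Each node entry declares ``id``, ``name``, ``level``, absolute ``weight``,
    a ``parent`` for levels 2-3, and a ``calculator`` key for level 3.

    Raises :class:`IndexValidationError` on duplicate ids, orphans, level
    gaps, or weight-conservation residuals beyond ``tolerance``.
    """
    cfg = _load_config(source)
    nodes: dict[str, IndicatorNode] = {}
    dupes = []
    for entry in cfg.get("nodes", []):
        node = IndicatorNode(
            id=str(entry["id"]),
            name=str(entry["name"]),
            level=int(entry["level"]),
            absolute_weight=float(entry["weight"]),
            parent_id=entry.get("parent"),
            calculator_id=entry.get("calculator"),
        )
        if node.id in nodes:
            dupes.append(node.id)
        nodes[node.id] = node
    if dupes:
        raise IndexValidationError("duplicate node ids", dupes)
    system = IndexSystem(
        nodes=nodes,
        name=cfg.get("name", "index-system"),
        version=str(cfg.get("version", "0")),
        provenance=cfg.get("provenance", ""),
    )
    if check_weights:
        report = validate_weights(system, tolerance)
        if not report.passed:
            raise IndexValidationError(
                "weight conservation violated", report.failing_parents
            )
    return system


def default_index_system() -> IndexSystem:
    """The packaged default: 4 dimensions, 11 sub-dimensions, 33 leaves."""
    ref = importlib.resources.files("emrqi.data") / "index_system.yaml"
    return load_index_system(yaml.safe_load(ref.read_text()))


def render_tree(system: IndexSystem) -> str:
    """Human-readable indented tree with weights (used by the CLI)."""
    lines = [f"{system.name} v{system.version}  [hash {system.content_hash()}]"]

    def walk(nodes: Iterable[IndicatorNode], indent: int):
        for node in sorted(nodes, key=lambda n: n.id):
            lines.append(f"{'  ' * indent}{node.id}  {node.name}  "
                         f"({node.absolute_weight:.3f})")
            walk(system.children(node.id), indent + 1)

    walk(system.level(1), 0)
    return "\n".join(lines)
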