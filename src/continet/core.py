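"""Domain types and project validation.

The data model mirrors how serial-section EM annotation tools record a
reconstruction: every annotated structure is a single point object (a
neurite profile centroid, a presynaptic density, or a gap junction) with
pixel coordinates X/Y and a section number Z, and continuity between
objects is asserted by pairwise links in a relationship table.  Maximal
chains of linked objects ("contins") represent either one neuron's
skeleton or one multi-section synapse.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "ObjType",
    "Confidence",
    "Severity",
    "AnnotationObject",
    "Relationship",
    "Contin",
    "Synapse",
    "AdjacencyMatrix",
    "Issue",
    "validate_project",
    "DEFAULT_Z_GAP_TOLERANCE",
]


class ObjType(str, enum.Enum):
    """Kind of annotated structure a point object marks."""

    NEURITE = "NEURITE"
    CHEMICAL = "CHEMICAL"
    GAP = "GAP"


class Confidence(str, enum.Enum):
    HIGH = "HIGH"
    UNCERTAIN = "UNCERTAIN"


class Severity(str, enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"


#: Largest legal section gap inside one neurite chain before a warning is
#: raised.  Small gaps arise from missing sections in real series and do
#: not preclude reconstruction.
DEFAULT_Z_GAP_TOLERANCE = 3


def _clean_name(name: Optional[str]) -> Optional[str]:
    if name is None:
        return None
    name = name.strip()
    return name or None


@dataclass
class AnnotationObject:
    """One annotated point: a neurite profile or a synapse marker.

    Parameters
    ----------
    object_id
        Positive integer, unique within a project.
    x, y
        Pixel coordinates in the source image (0-based).
    z
        Section number (1-based as printed on micrographs; non-negative).
    obj_type
        NEURITE, CHEMICAL or GAP; determines which payload fields apply.
    cell_name
        Name of the cell this neurite profile belongs to (NEURITE only).
    pre_cell, post_cells
        Presynaptic cell and ordered postsynaptic partners (CHEMICAL
        only; more than one post partner makes the synapse a polyad).
    partner_cells
        The two connected cells (GAP only).
    is_cell_body
        Marks the soma position on a neurite skeleton.
    contin_id
        Assigned by assembly; ``None`` until then.
    """

    object_id: int
    x: float
    y: float
    z: int
    obj_type: ObjType
    cell_name: Optional[str] = None
    pre_cell: Optional[str] = None
    post_cells: tuple[str, ...] = ()
    partner_cells: tuple[str, ...] = ()
    annotator_id: str = ""
    confidence: Confidence = Confidence.HIGH
    is_cell_body: bool = False
    contin_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.obj_type = ObjType(self.obj_type)
        self.confidence = Confidence(self.confidence)
        self.cell_name = _clean_name(self.cell_name)
        self.pre_cell = _clean_name(self.pre_cell)
        self.post_cells = tuple(
            n for n in (_clean_name(c) for c in self.post_cells) if n
        )
        self.partner_cells = tuple(
            n for n in (_clean_name(c) for c in self.partner_cells) if n
        )

    def payload_key(self) -> tuple:
        """Hashable synaptic payload, used for consensus voting."""
        if self.obj_type is ObjType.CHEMICAL:
            return (self.pre_cell, tuple(sorted(self.post_cells)))
        if self.obj_type is ObjType.GAP:
            return (tuple(sorted(self.partner_cells)),)
        return ()

    def copy(self, **changes) -> "AnnotationObject":
        return replace(self, **changes)


@dataclass(frozen=True)
class Relationship:
    """Undirected continuity link between two objects.

    Stored canonically with ``object_id_a < object_id_b``.
    """

    object_id_a: int
    object_id_b: int
    annotator_id: str = ""

    def __post_init__(self) -> None:
        a, b = self.object_id_a, self.object_id_b
        if a == b:
            raise ValueError(f"relationship links object {a} to itself")
        if a > b:
            object.__setattr__(self, "object_id_a", b)
            object.__setattr__(self, "object_id_b", a)

    @property
    def pair(self) -> tuple[int, int]:
        return (self.object_id_a, self.object_id_b)


@dataclass
class Contin:
    """A maximal connected chain of objects.

    For neurite objects a contin is one neuron's skeleton trace; for
    synapse objects it is one synapse spanning one or more sections.
    """

    contin_id: int
    kind: ObjType
    object_ids: frozenset[int]
    resolved_name: Optional[str] = None

    def __len__(self) -> int:
        return len(self.object_ids)


@dataclass
class Synapse:
    """A consolidated chemical or gap-junction connection.

    ``size_sections`` is the number of distinct sections the presynaptic
    density or gap junction traverses — the morphometric proxy for
    connection strength.
    """

    synapse_id: int
    syn_type: ObjType
    pre_cell: Optional[str]
    post_cells: tuple[str, ...]
    partner_cells: tuple[str, ...]
    size_sections: int
    centroid: tuple[float, float, float]
    z_span: tuple[int, int]
    inconsistent: bool = False
    payload_variants: tuple = ()
    member_ids: tuple[int, ...] = ()

    def partners(self) -> tuple[str, ...]:
        """All partner names regardless of synapse type."""
        if self.syn_type is ObjType.CHEMICAL:
            return tuple(sorted(self.post_cells))
        return tuple(sorted(self.partner_cells))


@dataclass
class AdjacencyMatrix:
    """cells x cells weight matrix in units of serial sections.

    Chemical matrices are directed (rows presynaptic, columns
    postsynaptic); gap-junction matrices are symmetric.
    """

    cells: list[str]
    weights: "object"  # numpy ndarray, shape (n, n)
    matrix_type: ObjType

    def __post_init__(self) -> None:
        import numpy as np

        self.weights = np.asarray(self.weights)
        n = len(self.cells)
        if self.weights.shape != (n, n):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{n} cells"
            )

    def index(self, cell: str) -> int:
        try:
            return self.cells.index(cell)
        except ValueError:
            raise KeyError(f"cell {cell!r} not in matrix") from None

    def __getitem__(self, key: tuple[str, str]):
        pre, post = key
        return self.weights[self.index(pre), self.index(post)]

    def total(self):
        return self.weights.sum()

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.weights, index=self.cells, columns=self.cells
        )


@dataclass(frozen=True)
class Issue:
    """One validation finding."""

    code: str
    severity: Severity
    message: str
    object_ids: tuple[int, ...] = ()

    def __str__(self) -> str:
        ids = ",".join(map(str, self.object_ids))
        return f"[{self.severity.value}] {self.code}: {self.message} ({ids})"


def _payload_issues(obj: AnnotationObject) -> Iterable[Issue]:
    t = obj.obj_type
    if t is ObjType.CHEMICAL:
        if not obj.pre_cell or not obj.post_cells:
            yield Issue(
                "BAD_PAYLOAD",
                Severity.ERROR,
                f"chemical object {obj.object_id} lacks pre/post cells",
                (obj.object_id,),
            )
        if len(set(obj.post_cells)) != len(obj.post_cells):
            yield Issue(
                "BAD_PAYLOAD",
                Severity.ERROR,
                f"object {obj.object_id} has duplicate post cells",
                (obj.object_id,),
            )
        if obj.partner_cells or obj.cell_name:
            yield Issue(
                "BAD_PAYLOAD",
                Severity.ERROR,
                f"chemical object {obj.object_id} carries non-chemical fields",
                (obj.object_id,),
            )
    elif t is ObjType.GAP:
        if len(obj.partner_cells) != 2:
            yield Issue(
                "BAD_PAYLOAD",
                Severity.ERROR,
                f"gap object {obj.object_id} needs exactly 2 partners",
                (obj.object_id,),
            )
        elif obj.partner_cells[0] == obj.partner_cells[1]:
            yield Issue(
                "BAD_PAYLOAD",
                Severity.ERROR,
                f"gap object {obj.object_id} partners are identical",
                (obj.object_id,),
            )
        if obj.pre_cell or obj.post_cells or obj.cell_name:
            yield Issue(
                "BAD_PAYLOAD",
                Severity.ERROR,
                f"gap object {obj.object_id} carries non-gap fields",
                (obj.object_id,),
            )
    else:  # NEURITE
        if obj.pre_cell or obj.post_cells or obj.partner_cells:
            yield Issue(
                "BAD_PAYLOAD",
                Severity.ERROR,
                f"neurite object {obj.object_id} carries synaptic fields",
                (obj.object_id,),
            )
    if obj.z < 0:
        yield Issue(
            "BAD_COORDINATE",
            Severity.ERROR,
            f"object {obj.object_id} has negative section number {obj.z}",
            (obj.object_id,),
        )


def validate_project(
    objects: Sequence[AnnotationObject],
    relationships: Sequence[Relationship],
    z_gap_tolerance: int = DEFAULT_Z_GAP_TOLERANCE,
) -> list[Issue]:
    """Check every project invariant; return all findings.

    An empty report means the project is clean.  Problems are reported,
    never raised.  The report is a multiset independent of input row
    order: it is sorted by (code, object ids).
    """
    issues: list[Issue] = []
    by_id: dict[int, AnnotationObject] = {}

    seen_dup: set[int] = set()
    for obj in objects:
        if obj.object_id in by_id and obj.object_id not in seen_dup:
            seen_dup.add(obj.object_id)
            issues.append(
                Issue(
                    "DUPLICATE_OBJECT_ID",
                    Severity.ERROR,
                    f"object id {obj.object_id} occurs more than once",
                    (obj.object_id,),
                )
            )
        by_id.setdefault(obj.object_id, obj)
        issues.extend(_payload_issues(obj))

    seen_rel: set[tuple[int, int]] = set()
    valid_rels: list[Relationship] = []
    for rel in relationships:
        if rel.pair in seen_rel:
            issues.append(
                Issue(
                    "DUPLICATE_RELATIONSHIP",
                    Severity.ERROR,
                    f"duplicate link {rel.object_id_a}-{rel.object_id_b}",
                    rel.pair,
                )
            )
            continue
        seen_rel.add(rel.pair)
        a = by_id.get(rel.object_id_a)
        b = by_id.get(rel.object_id_b)
        if a is None or b is None:
            missing = tuple(
                i for i in rel.pair if i not in by_id
            )
            issues.append(
                Issue(
                    "DANGLING_REF",
                    Severity.ERROR,
                    f"link {rel.object_id_a}-{rel.object_id_b} references "
                    f"nonexistent object(s) {missing}",
                    rel.pair,
                )
            )
            continue
        if a.obj_type is not b.obj_type:
            issues.append(
                Issue(
                    "TYPE_MISMATCH",
                    Severity.ERROR,
                    f"link {rel.object_id_a}-{rel.object_id_b} joins "
                    f"{a.obj_type.value} to {b.obj_type.value}",
                    rel.pair,
                )
            )
            continue
        valid_rels.append(rel)
        if (
            a.obj_type is ObjType.NEURITE
            and abs(a.z - b.z) > z_gap_tolerance
        ):
            issues.append(
                Issue(
                    "Z_GAP",
                    Severity.WARNING,
                    f"link {rel.object_id_a}-{rel.object_id_b} spans "
                    f"{abs(a.z - b.z)} sections (tolerance "
                    f"{z_gap_tolerance})",
                    rel.pair,
                )
            )

    # connected-component checks: neurite cycles, conflicting cell names
    issues.extend(_component_issues(by_id, valid_rels))

    issues.sort(key=lambda i: (i.code, i.object_ids, i.message))
    return issues


def _component_issues(
    by_id: dict[int, AnnotationObject], rels: Sequence[Relationship]
) -> Iterable[Issue]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(by_id)
    g.add_edges_from(r.pair for r in rels)
    for comp in nx.connected_components(g):
        comp = set(comp)
        members = [by_id[i] for i in comp]
        kind = members[0].obj_type
        sub_edges = sum(1 for r in rels if r.object_id_a in comp)
        if kind is ObjType.NEURITE:
            if sub_edges > len(comp) - 1:
                yield Issue(
                    "NEURITE_CYCLE",
                    Severity.WARNING,
                    f"neurite contin {min(comp)} contains a cycle "
                    f"({sub_edges} links over {len(comp)} objects)",
                    (min(comp),),
                )
            names = sorted(
                {m.cell_name for m in members if m.cell_name}
            )
            if len(names) > 1:
                counts = {
                    n: sum(1 for m in members if m.cell_name == n)
                    for n in names
                }
                yield Issue(
                    "NAME_CONFLICT",
                    Severity.WARNING,
                    f"contin {min(comp)} mixes cell names {counts}",
                    (min(comp),),
                )


def has_errors(issues: Iterable[Issue]) -> bool:
    return any(i.severity is Severity.ERROR for i in issues)
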