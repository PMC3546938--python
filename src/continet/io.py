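"""Flat-file project tables and interchange exports.

A project lives in a directory of UTF-8 TSV tables: an object table (one
row per annotated point), a relationship table (one row per continuity
link) and an optional section table (per-section thickness and presence).
Each table opens with a one-line schema tag so readers can reject files
from a different schema version.  Writers are deterministic: rows sorted
by id, bit-identical output for identical input.

Interchange exports: SWC for skeleton morphology, 3-column TSV edge
lists and CSV adjacency matrices (rows presynaptic, columns
postsynaptic).
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .assembly import NeuriteSkeleton
from .core import (
    AdjacencyMatrix,
    AnnotationObject,
    Confidence,
    ObjType,
    Relationship,
)

__all__ = [
    "FormatError",
    "SectionMeta",
    "ProjectBundle",
    "read_object_table",
    "write_object_table",
    "read_relationship_table",
    "write_relationship_table",
    "read_project",
    "write_project",
    "export_swc",
    "export_edge_list",
    "export_matrix_csv",
    "read_matrix_csv",
]

OBJECT_SCHEMA = "#continet objects v1"
RELATIONSHIP_SCHEMA = "#continet relationships v1"
SECTION_SCHEMA = "#continet sections v1"

OBJECT_COLUMNS = [
    "object_id",
    "x",
    "y",
    "z",
    "obj_type",
    "cell_name",
    "pre_cell",
    "post_cells",
    "partner_cells",
    "annotator_id",
    "confidence",
    "is_cell_body",
    "contin_id",
]
RELATIONSHIP_COLUMNS = ["object_id_a", "object_id_b", "annotator_id"]
SECTION_COLUMNS = ["z", "thickness_nm", "present"]

#: delimiter inside multi-valued fields (cell names never contain commas
#: or tabs)
LIST_SEP = ","


class FormatError(ValueError):
    """Raised when an input file does not match the documented schema."""


@dataclass(frozen=True)
class SectionMeta:
    thickness_nm: float = 80.0
    present: bool = True


@dataclass
class ProjectBundle:
    """All tables of one annotation project."""

    objects: list[AnnotationObject] = field(default_factory=list)
    relationships: list[Relationship] = field(default_factory=list)
    series_meta: dict[int, SectionMeta] = field(default_factory=dict)


def _num(value: float) -> str:
    """Shortest faithful text for a coordinate (ints stay ints)."""
    f = float(value)
    return str(int(f)) if f.is_integer() else repr(f)


def _check_header(path: Path, schema: str, columns: list[str], fh) -> None:
    tag = fh.readline().rstrip("\n")
    if tag != schema:
        raise FormatError(
            f"{path}: expected schema tag {schema!r}, found {tag!r}"
        )
    header = fh.readline().rstrip("\n").split("\t")
    if header != columns:
        raise FormatError(
            f"{path}: header {header} does not match schema columns"
        )


def read_object_table(path) -> list[AnnotationObject]:
    """Parse an object table; raises FormatError naming the bad row."""
    path = Path(path)
    objects: list[AnnotationObject] = []
    with open(path, encoding="utf-8", newline="") as fh:
        _check_header(path, OBJECT_SCHEMA, OBJECT_COLUMNS, fh)
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=3):
            if not row:
                continue
            if len(row) != len(OBJECT_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected "
                    f"{len(OBJECT_COLUMNS)} fields, found {len(row)}"
                )
            rec = dict(zip(OBJECT_COLUMNS, row))
            try:
                obj_type = ObjType(rec["obj_type"])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: unknown obj_type "
                    f"{rec['obj_type']!r}"
                ) from None
            try:
                obj = AnnotationObject(
                    object_id=int(rec["object_id"]),
                    x=float(rec["x"]),
                    y=float(rec["y"]),
                    z=int(rec["z"]),
                    obj_type=obj_type,
                    cell_name=rec["cell_name"] or None,
                    pre_cell=rec["pre_cell"] or None,
                    post_cells=tuple(
                        p for p in rec["post_cells"].split(LIST_SEP) if p
                    ),
                    partner_cells=tuple(
                        p
                        for p in rec["partner_cells"].split(LIST_SEP)
                        if p
                    ),
                    annotator_id=rec["annotator_id"],
                    confidence=Confidence(rec["confidence"]),
                    is_cell_body=rec["is_cell_body"] == "1",
                    contin_id=(
                        int(rec["contin_id"]) if rec["contin_id"] else None
                    ),
                )
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            if obj_type is ObjType.CHEMICAL and (
                not obj.pre_cell or not obj.post_cells
            ):
                raise FormatError(
                    f"{path}:{lineno}: chemical object "
                    f"{obj.object_id} lacks pre/post cells"
                )
            if obj_type is ObjType.GAP and len(obj.partner_cells) != 2:
                raise FormatError(
                    f"{path}:{lineno}: gap object {obj.object_id} "
                    "needs exactly two partner cells"
                )
            objects.append(obj)
    return objects


def write_object_table(
    objects: Sequence[AnnotationObject], path
) -> None:
    """Write objects sorted by id; output is byte-deterministic."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(OBJECT_SCHEMA + "\n")
        fh.write("\t".join(OBJECT_COLUMNS) + "\n")
        for o in sorted(objects, key=lambda o: o.object_id):
            row = [
                str(o.object_id),
                _num(o.x),
                _num(o.y),
                str(o.z),
                o.obj_type.value,
                o.cell_name or "",
                o.pre_cell or "",
                LIST_SEP.join(o.post_cells),
                LIST_SEP.join(o.partner_cells),
                o.annotator_id,
                o.confidence.value,
                "1" if o.is_cell_body else "0",
                "" if o.contin_id is None else str(o.contin_id),
            ]
            fh.write("\t".join(row) + "\n")


def read_relationship_table(path) -> list[Relationship]:
    path = Path(path)
    rels: list[Relationship] = []
    with open(path, encoding="utf-8", newline="") as fh:
        _check_header(path, RELATIONSHIP_SCHEMA, RELATIONSHIP_COLUMNS, fh)
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            row = line.split("\t")
            if len(row) != len(RELATIONSHIP_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected 3 fields, found {len(row)}"
                )
            try:
                rels.append(
                    Relationship(int(row[0]), int(row[1]), row[2])
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return rels


def write_relationship_table(
    relationships: Sequence[Relationship], path
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(RELATIONSHIP_SCHEMA + "\n")
        fh.write("\t".join(RELATIONSHIP_COLUMNS) + "\n")
        for r in sorted(
            relationships, key=lambda r: (r.object_id_a, r.object_id_b)
        ):
            fh.write(
                f"{r.object_id_a}\t{r.object_id_b}\t{r.annotator_id}\n"
            )


def _read_sections(path: Path) -> dict[int, SectionMeta]:
    meta: dict[int, SectionMeta] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        _check_header(path, SECTION_SCHEMA, SECTION_COLUMNS, fh)
        for lineno, line in enumerate(fh, start=3):
            line = line.rstrip("\n")
            if not line:
                continue
            z, thick, present = line.split("\t")
            meta[int(z)] = SectionMeta(float(thick), present == "1")
    return meta


def _write_sections(meta: dict[int, SectionMeta], path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(SECTION_SCHEMA + "\n")
        fh.write("\t".join(SECTION_COLUMNS) + "\n")
        for z in sorted(meta):
            m = meta[z]
            fh.write(f"{z}\t{_num(m.thickness_nm)}\t{int(m.present)}\n")


def read_project(directory) -> ProjectBundle:
    """Read objects.tsv / relationships.tsv / sections.tsv from a dir."""
    directory = Path(directory)
    obj_path = directory / "objects.tsv"
    rel_path = directory / "relationships.tsv"
    if not obj_path.exists() or not rel_path.exists():
        raise FormatError(
            f"{directory}: project needs objects.tsv and relationships.tsv"
        )
    bundle = ProjectBundle(
        objects=read_object_table(obj_path),
        relationships=read_relationship_table(rel_path),
    )
    sec_path = directory / "sections.tsv"
    if sec_path.exists():
        bundle.series_meta = _read_sections(sec_path)
    return bundle


def write_project(bundle: ProjectBundle, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_object_table(bundle.objects, directory / "objects.tsv")
    write_relationship_table(
        bundle.relationships, directory / "relationships.tsv"
    )
    if bundle.series_meta:
        _write_sections(bundle.series_meta, directory / "sections.tsv")


def export_swc(
    skeleton: NeuriteSkeleton,
    path,
    nm_per_pixel: float = 1.0,
    section_thickness_nm: float = 80.0,
) -> None:
    """Write a skeleton as SWC morphology.

    Sample ids start at 1 at the root (parent -1) and every parent
    precedes its children.  x/y are pixels scaled to nm; z is section
    number times section thickness.  Radius is half the section
    thickness since the reconstruction is non-volumetric.  Cyclic
    skeletons are refused.
    """
    if not skeleton.is_tree:
        raise ValueError(
            f"skeleton {skeleton.contin_id} contains a cycle; break "
            "cycles (build_skeleton does) before SWC export"
        )
    children = skeleton.children()
    radius = 0.5 * section_thickness_nm
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# SWC export\n")
        fh.write(
            f"# scale: {_num(nm_per_pixel)} nm/pixel, section "
            f"{_num(section_thickness_nm)} nm\n"
        )
        sample_of: dict[int, int] = {}
        order: list[tuple[int, int]] = [(skeleton.root, -1)]
        stack = [skeleton.root]
        while stack:
            cur = stack.pop()
            for child in reversed(children[cur]):
                order.append((child, cur))
                stack.append(child)
        for sample_id, (obj_id, parent_obj) in enumerate(order, start=1):
            sample_of[obj_id] = sample_id
            o = skeleton.nodes[obj_id]
            parent = -1 if parent_obj == -1 else sample_of[parent_obj]
            fh.write(
                f"{sample_id} 0 {_num(o.x * nm_per_pixel)} "
                f"{_num(o.y * nm_per_pixel)} "
                f"{_num(o.z * section_thickness_nm)} "
                f"{_num(radius)} {parent}\n"
            )


def export_edge_list(matrix: AdjacencyMatrix, path) -> None:
    """Write nonzero entries as pre/post/weight TSV.

    Gap-junction matrices emit each unordered pair once (upper
    triangle including the diagonal).
    """
    path = Path(path)
    symmetric = matrix.matrix_type is ObjType.GAP
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("pre\tpost\tweight\n")
        n = len(matrix.cells)
        for i in range(n):
            start = i if symmetric else 0
            for j in range(start, n):
                w = matrix.weights[i, j]
                if w:
                    fh.write(
                        f"{matrix.cells[i]}\t{matrix.cells[j]}\t{_num(w)}\n"
                    )


def export_matrix_csv(matrix: AdjacencyMatrix, path) -> None:
    """CSV adjacency matrix: presynaptic rows, postsynaptic columns."""
    matrix.to_dataframe().to_csv(path, lineterminator="\n")


def read_matrix_csv(path, matrix_type: ObjType) -> AdjacencyMatrix:
    import pandas as pd

    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column cells differ")
    return AdjacencyMatrix(
        list(df.index), df.to_numpy(), matrix_type
    )
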