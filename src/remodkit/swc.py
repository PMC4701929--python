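"""Reading and writing neuronal reconstructions in the SWC format.

SWC is the plain-text interchange format used by NeuroMorpho and most
reconstruction software: one sample point per line, seven whitespace
separated columns::

    id  type  x  y  z  radius  parent

with ``type`` 1 = soma, 2 = axon, 3 = basal dendrite, 4 = apical
dendrite (codes >= 5 are custom), coordinates and radius in micrometers,
and ``parent`` the id of the preceding sample (-1 for the root).

The reader is liberal in what it accepts — comments, blank lines,
arbitrary whitespace, non-contiguous or unsorted ids, children listed
before their parents — and strict in what it validates: unique ids,
exactly one root, every parent resolvable, positive radii.  The writer
always emits a canonical file: ids re-indexed contiguously from 1 in an
order where every parent precedes its children, floats printed with six
decimals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Union

from .errors import SWCParseError, SWCStructureError

__all__ = [
    "SWCRecord",
    "ParseReport",
    "parse_swc",
    "read_swc",
    "write_swc",
    "save_swc",
]


@dataclass(frozen=True)
class SWCRecord:
    """One sample point of a reconstruction."""

    sample_id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int


@dataclass
class ParseReport:
    """Diagnostics collected while parsing an SWC source."""

    n_records: int = 0
    n_trees: int = 0
    warnings: list[str] = field(default_factory=list)


def _int_field(token: str, line_no: int, name: str) -> int:
    try:
        return int(token)
    except ValueError:
        pass
    try:
        value = float(token)
    except ValueError:
        raise SWCParseError(
            f"line {line_no}: non-numeric {name} field {token!r}"
        ) from None
    if value.is_integer():
        return int(value)
    raise SWCParseError(f"line {line_no}: non-integer {name} field {token!r}")


def _float_field(token: str, line_no: int, name: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise SWCParseError(
            f"line {line_no}: non-numeric {name} field {token!r}"
        ) from None


def parse_swc(
    source: Union[str, Iterable[str], IO[str]],
) -> tuple[list[SWCRecord], ParseReport]:
    """Parse SWC text into records, validating the tree structure.

    Parameters
    ----------
    source
        SWC *content*: a string, an open text file, or any iterable of
        lines.  Use :func:`read_swc` to parse from a filesystem path.

    Returns
    -------
    (records, report)
        Records in file order, and a :class:`ParseReport` whose
        ``warnings`` list tolerated irregularities (e.g. forward
        references, a child appearing before its parent).

    Raises
    ------
    SWCParseError
        Malformed line: wrong column count, non-numeric field,
        non-positive radius.
    SWCStructureError
        No root, more than one root, duplicate ids, dangling or
        self-referential parent links.
    """
    if isinstance(source, str):
        lines: Iterable[str] = source.splitlines()
    else:
        lines = source

    records: list[SWCRecord] = []
    seen: dict[int, int] = {}  # sample_id -> line number
    report = ParseReport()

    for line_no, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        tokens = line.split()
        if len(tokens) != 7:
            raise SWCParseError(
                f"line {line_no}: expected 7 columns, found {len(tokens)}"
            )
        sample_id = _int_field(tokens[0], line_no, "id")
        type_code = _int_field(tokens[1], line_no, "type")
        x = _float_field(tokens[2], line_no, "x")
        y = _float_field(tokens[3], line_no, "y")
        z = _float_field(tokens[4], line_no, "z")
        radius = _float_field(tokens[5], line_no, "radius")
        parent_id = _int_field(tokens[6], line_no, "parent")
        if radius <= 0:
            raise SWCParseError(
                f"line {line_no}: radius must be > 0, got {radius}"
            )
        if parent_id == sample_id:
            raise SWCStructureError(
                f"line {line_no}: sample {sample_id} is its own parent"
            )
        if sample_id in seen:
            raise SWCStructureError(
                f"line {line_no}: duplicate sample id {sample_id} "
                f"(first defined on line {seen[sample_id]})"
            )
        seen[sample_id] = line_no
        records.append(
            SWCRecord(sample_id, type_code, x, y, z, radius, parent_id)
        )

    roots = [r for r in records if r.parent_id == -1]
    if not roots:
        raise SWCStructureError("no root record (parent -1) found")
    if len(roots) > 1:
        ids = ", ".join(str(r.sample_id) for r in roots)
        raise SWCStructureError(
            f"multiple roots found (samples {ids}); one tree per file required"
        )

    ids = set(seen)
    n_forward = 0
    defined: set[int] = set()
    for rec in records:
        if rec.parent_id != -1:
            if rec.parent_id not in ids:
                raise SWCStructureError(
                    f"sample {rec.sample_id} references missing parent "
                    f"{rec.parent_id}"
                )
            if rec.parent_id not in defined:
                n_forward += 1
        defined.add(rec.sample_id)
    if n_forward:
        report.warnings.append(
            f"{n_forward} record(s) appear before their parent (forward "
            "references resolved)"
        )

    report.n_records = len(records)
    report.n_trees = 1
    return records, report


def read_swc(path: Union[str, os.PathLike]) -> tuple[list[SWCRecord], ParseReport]:
    """Parse an SWC file from disk.  See :func:`parse_swc`."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_swc(fh)


def write_swc(morphology) -> str:
    """Serialize a morphology to canonical SWC text.

    Ids are re-indexed contiguously from 1 with every parent preceding
    its children; coordinates and radii are printed with six decimals.
    The output round-trips through :func:`parse_swc` preserving topology
    and geometry exactly.  Refuses to serialize an invalid tree.
    """
    morphology.validate()
    order = morphology._preorder_ids()
    new_id = {old: i for i, old in enumerate(order, start=1)}
    lines = []
    for old in order:
        node = morphology.nodes[old]
        parent = -1 if node.parent == -1 else new_id[node.parent]
        x, y, z = node.pos
        lines.append(
            f"{new_id[old]} {node.type_code} "
            f"{x:.6f} {y:.6f} {z:.6f} {node.radius:.6f} {parent}"
        )
    return "\n".join(lines) + "\n"


def save_swc(morphology, path: Union[str, os.PathLike]) -> None:
    """Write a morphology to ``path`` in canonical SWC form."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(write_swc(morphology))
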