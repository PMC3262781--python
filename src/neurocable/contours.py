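"""Equivalent-cylinder import of serial-section EM contour stacks.

Electron-microscopy reconstructions describe a piece of dendrite as a
stack of closed 2-D contours, one per serial section, each with a known
section thickness.  For cable modelling the stack is reduced to an
equivalent cylinder that preserves the quantities that matter
electrically: total length (the summed section thickness) and lateral
membrane area (the summed perimeter × thickness of the sections), so

    LENGTH = Σ hᵢ,   DIA = (Σ perimeterᵢ·hᵢ) / (π·LENGTH).

The input is a plain-text stack file: a ``section <index> <thickness>``
line followed by one ``x y`` coordinate pair per contour vertex, all in
metres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from shapely.geometry import Polygon

from .model import ModelContainer
from .paths import as_path


class ContourError(Exception):
    pass


@dataclass(frozen=True)
class Contour:
    """One closed EM contour from a serial section."""

    section: int
    thickness: float  # section thickness, m
    points: tuple[tuple[float, float], ...]  # closed polygon vertices, m

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ContourError("a contour needs at least 3 points")
        if self.thickness <= 0:
            raise ContourError("section thickness must be positive")


@dataclass(frozen=True)
class ContourStack:
    """Ordered contours of one unbranched dendritic piece."""

    contours: tuple[Contour, ...]

    def __post_init__(self) -> None:
        idx = [c.section for c in self.contours]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ContourError("section indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.contours)


def polygon_area(contour: Contour) -> float:
    """Absolute (orientation-independent) enclosed area, m²."""
    return Polygon(contour.points).area


def polygon_perimeter(contour: Contour) -> float:
    """Euclidean closed-loop perimeter, m."""
    return Polygon(contour.points).length


def equivalent_cylinder(stack: ContourStack) -> tuple[float, float]:
    """Reduce a stack to (DIA, LENGTH) conserving lateral membrane area."""
    if not stack.contours:
        raise ContourError("empty contour stack")
    length = sum(c.thickness for c in stack.contours)
    if length <= 0:
        raise ContourError("zero total thickness")
    lateral_area = sum(
        polygon_perimeter(c) * c.thickness for c in stack.contours)
    dia = lateral_area / (math.pi * length)
    return dia, length


def read_stack_file(filename: str) -> list[ContourStack]:
    """Parse a stack text file; blank lines separate stacks."""
    stacks: list[ContourStack] = []
    contours: list[Contour] = []
    section: tuple[int, float] | None = None
    points: list[tuple[float, float]] = []

    def flush_contour() -> None:
        nonlocal section, points
        if section is not None:
            contours.append(Contour(section[0], section[1], tuple(points)))
        section, points = None, []

    def flush_stack() -> None:
        nonlocal contours
        flush_contour()
        if contours:
            stacks.append(ContourStack(tuple(contours)))
        contours = []

    with open(filename) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                flush_stack()
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] == "section":
                if len(parts) != 3:
                    raise ContourError(
                        f"line {lineno}: section needs index and thickness")
                flush_contour()
                section = (int(parts[1]), float(parts[2]))
            else:
                if section is None:
                    raise ContourError(
                        f"line {lineno}: coordinates before any section line")
                if len(parts) != 2:
                    raise ContourError(f"line {lineno}: expected 'x y'")
                points.append((float(parts[0]), float(parts[1])))
    flush_stack()
    return stacks


def to_segments(stacks, container: ModelContainer, path, defaults: dict):
    """Create one segment per stack under ``path``, chained in order.

    ``defaults`` supplies the passive specific parameters (RM, RA, CM,
    ELEAK, Vm_init); DIA and LENGTH come from the equivalent cylinders.
    Returns the created segments.
    """
    required = ("RM", "RA", "CM", "ELEAK", "Vm_init")
    missing = [k for k in required if k not in defaults]
    if missing:
        raise ContourError(f"missing passive defaults: {missing}")
    base = as_path(path)
    created = []
    prev_path = base
    for k, stack in enumerate(stacks):
        dia, length = equivalent_cylinder(stack)
        seg_path = prev_path.child(f"c{k}") if created else base
        seg = container.create_segment(seg_path)
        seg.set_parameters(dict(defaults))
        seg.set_parameter("DIA", dia)
        seg.set_parameter("LENGTH", length)
        created.append(seg)
        prev_path = seg_path
    return created
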