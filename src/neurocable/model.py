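"""Model container: the biological model tree and its mathematical translation.

The container stores a neuron model as a tree of named nodes — cells,
segments (pieces of dendritic morphology), ion channels and synapses —
addressed by slash paths.  It holds the *biological* description:
membrane parameters are *specific* quantities per unit area or length
(RM in Ω·m², CM in F/m², RA in Ω·m), as reported in the literature.
:func:`specific_to_actual` translates them into the *actual* lumped
values of one compartment (Rm in Ω, Cm in F, Ra in Ω), scaled to the
compartment surface area, which is what the cable solver consumes.

All quantities are SI throughout (V, s, m, Ω, F, S, A).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field

from .paths import ModelPath, PathError, as_path

log = logging.getLogger(__name__)

#: Parameter vocabulary per node kind.  Unknown names are stored with a
#: logged warning (forward compatibility for annotated library files).
SEGMENT_PARAMS = frozenset(
    {"Vm_init", "RM", "RA", "CM", "ELEAK", "DIA", "LENGTH", "INJECT",
     # actual-valued parameters written by the SLI loader
     "Cm", "Em", "InitVm", "Inject", "Ra", "Rm",
     # derived annotations
     "SOMATOPETAL_BRANCHPOINTS"}
)
CHANNEL_PARAMS = frozenset({"GBAR", "EREV"})
SYNAPSE_PARAMS = frozenset({"GMAX", "TAU1", "TAU2", "EREV", "EVENT_FILENAME"})

#: Derived annotations that only exist after an analysis pass has run.
DERIVED_PARAMS = frozenset({"SOMATOPETAL_BRANCHPOINTS"})

#: Parameters with an implicit default when never set.
DEFAULT_PARAMS = {"INJECT": 0.0}


class ModelError(Exception):
    """Structural error in the model tree (bad path, duplicate, ...)."""


class ParameterError(ModelError):
    """A required or requested parameter is missing or invalid."""


@dataclass
class CompartmentParams:
    """Actual (lumped) electrical parameters of one compartment."""

    Cm: float  # membrane capacitance, F
    Rm: float  # membrane resistance, Ω
    Ra: float  # axial resistance, Ω
    Em: float  # leak reversal potential, V
    InitVm: float  # initial membrane potential, V
    Inject: float = 0.0  # injected current, A

    def __post_init__(self) -> None:
        if not (self.Cm > 0 and self.Rm > 0 and self.Ra > 0):
            raise ParameterError("Cm, Rm and Ra must be positive")


class Node:
    """Base class for all addressable model nodes."""

    kind = "node"
    vocabulary: frozenset[str] = frozenset()

    def __init__(self, path: ModelPath):
        self.path = path
        self.parameters: dict[str, float | str] = {}
        self.children: list[Node] = []

    def _accepts(self, name: str) -> bool:
        return name in self.vocabulary or name in DERIVED_PARAMS

    def set_parameter(self, name: str, value: float | str) -> None:
        if not self._accepts(name):
            log.warning("unknown parameter %r on %s %s (stored anyway)",
                        name, self.kind, self.path)
        self.parameters[name] = value

    def set_parameters(self, mapping: dict[str, float | str]) -> None:
        for name, value in mapping.items():
            self.set_parameter(name, value)

    def get_parameter(self, name: str):
        if name in self.parameters:
            return self.parameters[name]
        if name in DEFAULT_PARAMS and name in self.vocabulary:
            return DEFAULT_PARAMS[name]
        raise ParameterError(f"unknown parameter {name!r} on {self.path}")

    def has_parameter(self, name: str) -> bool:
        return name in self.parameters or (
            name in DEFAULT_PARAMS and name in self.vocabulary)

    def __repr__(self) -> str:
        return f"<{type(self).__name__} {self.path}>"


class CellNode(Node):
    kind = "cell"

    def __init__(self, path: ModelPath):
        super().__init__(path)
        self.root_segments: list[SegmentNode] = []

    @property
    def soma(self) -> "SegmentNode":
        """The first root segment created or loaded under this cell."""
        if not self.root_segments:
            raise ModelError(f"cell {self.path} has no segments")
        return self.root_segments[0]


class SegmentNode(Node):
    kind = "segment"
    vocabulary = SEGMENT_PARAMS

    def __init__(self, path: ModelPath):
        super().__init__(path)
        self.parent_segment: SegmentNode | None = None
        self.segment_children: list[SegmentNode] = []
        #: True when parameterized directly with actual values (SLI import);
        #: compilation then bypasses specific_to_actual.
        self.actual_parameterized = False


class ChannelNode(Node):
    kind = "channel"
    vocabulary = CHANNEL_PARAMS

    def _accepts(self, name: str) -> bool:
        if name.startswith("GATE_") and (
                name.endswith("_POWER") or name.endswith("_KINETICS")):
            return True
        return super()._accepts(name)

    @property
    def gates(self) -> dict[str, tuple[int, str]]:
        """Gate specs derived from GATE_<g>_POWER / GATE_<g>_KINETICS
        parameters: mapping gate name -> (power, kinetics id)."""
        powers: dict[str, int] = {}
        kinetics: dict[str, str] = {}
        for name, value in self.parameters.items():
            if name.startswith("GATE_") and name.endswith("_POWER"):
                powers[name[5:-6]] = int(value)
            elif name.startswith("GATE_") and name.endswith("_KINETICS"):
                kinetics[name[5:-9]] = str(value)
        out = {}
        for g in sorted(powers):
            if powers[g] < 0:
                raise ParameterError(f"negative gate power on {self.path}")
            if g not in kinetics:
                raise ParameterError(
                    f"gate {g!r} on {self.path} has a power but no kinetics id")
            out[g] = (powers[g], kinetics[g])
        return out


class SynapseNode(Node):
    kind = "synapse"
    vocabulary = SYNAPSE_PARAMS


def specific_to_actual(seg: SegmentNode) -> CompartmentParams:
    """Translate a segment's specific parameters into actual compartment values.

    Cylinder (LENGTH > 0): area = π·DIA·LENGTH, Cm = CM·area,
    Rm = RM/area, Ra = 4·RA·LENGTH/(π·DIA²).  Sphere (LENGTH = 0):
    area = π·DIA², Ra = RA/(π·DIA/2).  Em, InitVm and Inject pass
    through unchanged.
    """
    if seg.actual_parameterized:
        try:
            return CompartmentParams(
                Cm=float(seg.get_parameter("Cm")),
                Rm=float(seg.get_parameter("Rm")),
                Ra=float(seg.get_parameter("Ra")),
                Em=float(seg.get_parameter("Em")),
                InitVm=float(seg.get_parameter("InitVm")),
                Inject=float(seg.parameters.get("Inject", 0.0)),
            )
        except ParameterError as e:
            raise ParameterError(f"{seg.path}: {e}") from None
    required = ("DIA", "LENGTH", "RM", "RA", "CM", "ELEAK", "Vm_init")
    missing = [n for n in required if not seg.has_parameter(n)]
    if missing:
        raise ParameterError(
            f"segment {seg.path} missing required parameters: {missing}")
    dia = float(seg.get_parameter("DIA"))
    length = float(seg.get_parameter("LENGTH"))
    if dia <= 0:
        raise ParameterError(f"segment {seg.path}: DIA must be positive")
    if length < 0:
        raise ParameterError(f"segment {seg.path}: LENGTH must be >= 0")
    rm_s = float(seg.get_parameter("RM"))
    ra_s = float(seg.get_parameter("RA"))
    cm_s = float(seg.get_parameter("CM"))
    if length > 0:
        area = math.pi * dia * length
        ra = 4.0 * ra_s * length / (math.pi * dia * dia)
    else:
        area = math.pi * dia * dia
        ra = ra_s / (math.pi * dia / 2.0)
    return CompartmentParams(
        Cm=cm_s * area,
        Rm=rm_s / area,
        Ra=ra,
        Em=float(seg.get_parameter("ELEAK")),
        InitVm=float(seg.get_parameter("Vm_init")),
        Inject=float(seg.get_parameter("INJECT")),
    )


class ModelContainer:
    """Hierarchical store of neuron models, addressed by slash paths."""

    def __init__(self, library_paths: list[str] | None = None):
        self._nodes: dict[str, Node] = {}
        #: ordered library search path; first match wins
        self.library_paths: list[str] = list(library_paths or [])

    # -- construction ------------------------------------------------------

    def _register(self, node: Node) -> None:
        key = str(node.path)
        if key in self._nodes:
            raise ModelError(f"duplicate path: {key}")
        self._nodes[key] = node

    def create_cell(self, path) -> CellNode:
        path = as_path(path)
        cell = CellNode(path)
        self._register(cell)
        return cell

    def create_segment(self, path) -> SegmentNode:
        path = as_path(path)
        if len(path) < 2:
            raise ModelError(f"segment path {path} has no ancestor")
        ancestor = self.resolve(path.parent)
        if not isinstance(ancestor, (CellNode, SegmentNode)):
            raise ModelError(
                f"segment parent {path.parent} is a {ancestor.kind}, "
                "expected cell or segment")
        seg = SegmentNode(path)
        self._register(seg)
        ancestor.children.append(seg)
        if isinstance(ancestor, SegmentNode):
            seg.parent_segment = ancestor
            ancestor.segment_children.append(seg)
        else:
            ancestor.root_segments.append(seg)
        return seg

    def create_channel(self, path) -> ChannelNode:
        return self._create_leaf(path, ChannelNode)

    def create_synapse(self, path) -> SynapseNode:
        return self._create_leaf(path, SynapseNode)

    def _create_leaf(self, path, cls):
        path = as_path(path)
        if len(path) >= 2:
            try:
                parent: Node | None = self.resolve(path.parent)
            except ModelError:
                parent = None
        else:
            parent = None
        node = cls(path)
        self._register(node)
        if parent is not None:
            parent.children.append(node)
        return node

    # -- resolution and query ----------------------------------------------

    def resolve(self, path) -> Node:
        key = str(as_path(path))
        try:
            return self._nodes[key]
        except KeyError:
            raise ModelError(f"unresolvable path: {key}") from None

    def exists(self, path) -> bool:
        return str(as_path(path)) in self._nodes

    def __contains__(self, path) -> bool:
        return self.exists(path)

    def cells(self) -> list[CellNode]:
        return [n for n in self._nodes.values() if isinstance(n, CellNode)]

    def segments_of(self, root) -> list[SegmentNode]:
        """All segments in the subtree at ``root`` (cell or segment),
        depth-first pre-order."""
        node = self.resolve(root)
        out: list[SegmentNode] = []

        def walk(seg: SegmentNode) -> None:
            out.append(seg)
            for child in seg.segment_children:
                walk(child)

        if isinstance(node, CellNode):
            for r in node.root_segments:
                walk(r)
        elif isinstance(node, SegmentNode):
            walk(node)
        else:
            raise ModelError(f"{node.path} is a {node.kind}, "
                             "expected cell or segment")
        return out

    def segment_tips(self, cellpath) -> list[ModelPath]:
        """Paths of the most distal segment of each dendrite: segments with
        no segment children, in depth-first pre-order."""
        return [s.path for s in self.segments_of(cellpath)
                if not s.segment_children]

    # -- parameters --------------------------------------------------------

    def set_parameter(self, path, name: str, value) -> None:
        self.resolve(path).set_parameter(name, value)

    def set_parameters(self, path, mapping: dict) -> None:
        self.resolve(path).set_parameters(mapping)

    def show_parameter(self, path, name: str):
        return self.resolve(path).get_parameter(name)

    # -- morphology analysis -----------------------------------------------

    def morphology_summarize(self, rootpath) -> None:
        """Annotate every segment in the subtree with
        SOMATOPETAL_BRANCHPOINTS: the number of strictly intermediate
        nodes on its path toward the soma with >= 2 segment children
        (both endpoints excluded)."""
        for seg in self.segments_of(rootpath):
            count = 0
            node = seg.parent_segment
            while node is not None and node.parent_segment is not None:
                if len(node.segment_children) >= 2:
                    count += 1
                node = node.parent_segment
            seg.parameters["SOMATOPETAL_BRANCHPOINTS"] = count

    # -- library import ----------------------------------------------------

    def find_library_file(self, relname: str) -> str:
        import os

        if os.path.isabs(relname) and os.path.exists(relname):
            return relname
        for base in self.library_paths:
            cand = os.path.join(base, relname)
            if os.path.exists(cand):
                return cand
        if os.path.exists(relname):
            return relname
        raise ModelError(f"library file not found on search path: {relname}")

    def import_child(self, path, libref: str) -> Node:
        """Attach a deep copy of a library prototype under ``path``.

        ``libref`` has the form ``file.ndf::/name``.
        """
        from . import ndf  # local import: ndf depends on this module

        if "::" not in libref:
            raise ModelError(f"malformed library reference: {libref!r}")
        fname, proto = libref.split("::", 1)
        filepath = self.find_library_file(fname)
        doc = ndf.parse_file(filepath)
        block = doc.find(proto)
        if block is None:
            raise ModelError(f"prototype {proto!r} not found in {fname}")
        parent = self.resolve(path)
        return ndf.instantiate_block(self, copy.deepcopy(block),
                                     as_path(path).child(proto.lstrip("/")),
                                     parent)

    def read_ndf(self, filename: str) -> list[Node]:
        """Merge the definitions of an NDF file into this container."""
        from . import ndf

        filepath = self.find_library_file(filename)
        doc = ndf.parse_file(filepath)
        return ndf.merge_document(self, doc)

    # GENESIS-style spelling used by scripted front-ends
    Read = read_ndf

    def export_ndf(self, rootpath, filename: str) -> None:
        """Write the subtree at ``rootpath`` as an NDF library file that
        ``read_ndf`` restores to an equivalent tree."""
        from . import ndf

        doc = ndf.document_from_tree(self, rootpath)
        with open(filename, "w") as fh:
            fh.write(ndf.render(doc))

    def export_ndf_text(self, rootpath) -> str:
        from . import ndf

        return ndf.render(ndf.document_from_tree(self, rootpath))
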