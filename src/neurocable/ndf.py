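"""Reader/writer for the declarative model file dialect (NDF).

The format is line-oriented and diffable.  A file starts with ``#!ndf``;
blocks open with ``CELL``, ``SEGMENT``, ``CHANNEL`` or ``SYNAPSE``
followed by a name, contain ``PARAMETER <name> <value>`` lines and
``CHILD <file>::<prototype>`` import references, nest freely, and close
with ``END``.  ``#`` lines are comments; indentation is ignored.
Numbers are rendered with 17 significant digits so values round-trip
exactly; rendering is canonical (document order, parameters sorted), so
equal documents render byte-identically.

This is a documented local dialect, not compatible with any external
NDF grammar.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .model import (CellNode, ChannelNode, ModelContainer, ModelError, Node,
                    SegmentNode, SynapseNode)
from .paths import as_path

HEADER = "#!ndf"

BLOCK_KEYWORDS = ("CELL", "SEGMENT", "CHANNEL", "SYNAPSE")

_KIND_TO_KEYWORD = {
    CellNode: "CELL",
    SegmentNode: "SEGMENT",
    ChannelNode: "CHANNEL",
    SynapseNode: "SYNAPSE",
}


class NdfParseError(ValueError):
    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class NdfBlock:
    keyword: str
    name: str
    parameters: dict[str, float | str] = field(default_factory=dict)
    child_refs: list[str] = field(default_factory=list)
    blocks: list["NdfBlock"] = field(default_factory=list)


@dataclass
class NdfDocument:
    blocks: list[NdfBlock] = field(default_factory=list)

    def find(self, name: str) -> NdfBlock | None:
        for b in self.blocks:
            if b.name == name:
                return b
        return None


# -- value formatting -------------------------------------------------------

def _format_value(value) -> str:
    if isinstance(value, bool):
        raise TypeError("boolean parameter values are not supported")
    if isinstance(value, (int, float)):
        return "%.17g" % float(value)
    text = str(value)
    needs_quotes = (not text) or any(c.isspace() for c in text)
    if not needs_quotes:
        try:
            float(text)
            needs_quotes = True  # string that looks numeric: keep it a string
        except ValueError:
            pass
    return f'"{text}"' if needs_quotes else text


def _parse_value(token: str):
    if token.startswith('"') and token.endswith('"') and len(token) >= 2:
        return token[1:-1]
    try:
        return float(token)
    except ValueError:
        return token


# -- parsing ----------------------------------------------------------------

def parse(text: str) -> NdfDocument:
    lines = text.splitlines()
    if not lines or lines[0].strip() != HEADER:
        raise NdfParseError(f"missing {HEADER} header", 1)
    doc = NdfDocument()
    stack: list[NdfBlock] = []

    def siblings() -> list[NdfBlock]:
        return stack[-1].blocks if stack else doc.blocks

    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 2)
        keyword = parts[0]
        if keyword in BLOCK_KEYWORDS:
            if len(parts) < 2:
                raise NdfParseError(f"{keyword} requires a name", lineno)
            name = parts[1]
            if any(b.name == name for b in siblings()):
                raise NdfParseError(f"duplicate path: {name}", lineno)
            block = NdfBlock(keyword, name)
            siblings().append(block)
            stack.append(block)
        elif keyword == "PARAMETER":
            if not stack:
                raise NdfParseError("PARAMETER outside a block", lineno)
            if len(parts) < 3:
                raise NdfParseError("PARAMETER requires a name and a value",
                                    lineno)
            stack[-1].parameters[parts[1]] = _parse_value(parts[2].strip())
        elif keyword == "CHILD":
            if not stack:
                raise NdfParseError("CHILD outside a block", lineno)
            if len(parts) < 2 or "::" not in parts[1]:
                raise NdfParseError("CHILD requires <file>::<prototype>",
                                    lineno)
            stack[-1].child_refs.append(parts[1])
        elif keyword == "END":
            if not stack:
                raise NdfParseError("unbalanced END", lineno)
            stack.pop()
        else:
            raise NdfParseError(f"unknown keyword: {keyword}", lineno)
    if stack:
        raise NdfParseError(f"unclosed block {stack[-1].keyword} "
                            f"{stack[-1].name}", len(lines))
    return doc


def parse_file(filename: str) -> NdfDocument:
    with open(filename) as fh:
        return parse(fh.read())


# -- rendering --------------------------------------------------------------

def render(doc: NdfDocument) -> str:
    out = [HEADER]

    def emit(block: NdfBlock, depth: int) -> None:
        pad = "  " * depth
        out.append(f"{pad}{block.keyword} {block.name}")
        inner = "  " * (depth + 1)
        for name in sorted(block.parameters):
            out.append(f"{inner}PARAMETER {name} "
                       f"{_format_value(block.parameters[name])}")
        for ref in block.child_refs:
            out.append(f"{inner}CHILD {ref}")
        for sub in block.blocks:
            emit(sub, depth + 1)
        out.append(f"{pad}END")

    for block in doc.blocks:
        emit(block, 0)
    return "\n".join(out) + "\n"


# -- container glue ---------------------------------------------------------

def instantiate_block(container: ModelContainer, block: NdfBlock, path,
                      parent: Node | None) -> Node:
    """Create the node described by ``block`` at ``path`` and recurse."""
    path = as_path(path)
    if block.keyword == "CELL":
        node: Node = container.create_cell(path)
    elif block.keyword == "SEGMENT":
        node = container.create_segment(path)
    elif block.keyword == "CHANNEL":
        node = container.create_channel(path)
    elif block.keyword == "SYNAPSE":
        node = container.create_synapse(path)
    else:  # pragma: no cover - parser rejects unknown keywords
        raise ModelError(f"unknown block keyword {block.keyword}")
    node.set_parameters(dict(block.parameters))
    for ref in block.child_refs:
        container.import_child(path, ref)
    for sub in block.blocks:
        instantiate_block(container, sub, path.child(sub.name.lstrip("/")),
                          node)
    return node


def merge_document(container: ModelContainer, doc: NdfDocument) -> list[Node]:
    """Merge every top-level definition of ``doc`` into the container."""
    created = []
    for block in doc.blocks:
        created.append(
            instantiate_block(container, block, as_path(block.name), None))
    return created


def block_from_node(node: Node, top_level: bool) -> NdfBlock:
    keyword = _KIND_TO_KEYWORD[type(node)]
    name = str(node.path) if top_level else node.path.name
    block = NdfBlock(keyword, name, parameters=dict(node.parameters))
    for child in node.children:
        block.blocks.append(block_from_node(child, top_level=False))
    return block


def document_from_tree(container: ModelContainer, rootpath) -> NdfDocument:
    root = container.resolve(rootpath)
    return NdfDocument([block_from_node(root, top_level=True)])
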