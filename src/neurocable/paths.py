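"""Slash-separated model paths with optional integer indices (``/a/b[3]/c``).

Every node in a model tree is addressed by an absolute path.  A path
component is a bare name token, optionally suffixed with a bracketed
non-negative integer index, e.g. ``b1s06[182]``.  Paths round-trip
through :meth:`ModelPath.parse` / ``str()`` unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

SEP = "/"

_TOKEN_RE = re.compile(r"^(?P<name>[^/\[\]\s]+)(?:\[(?P<index>\d+)\])?$")


class PathError(ValueError):
    """Raised for malformed or non-absolute model paths."""


@dataclass(frozen=True)
class PathComponent:
    name: str
    index: int | None = None

    def __str__(self) -> str:
        if self.index is None:
            return self.name
        return f"{self.name}[{self.index}]"

    @classmethod
    def parse(cls, token: str) -> "PathComponent":
        m = _TOKEN_RE.match(token)
        if m is None:
            raise PathError(f"malformed path component: {token!r}")
        idx = m.group("index")
        return cls(m.group("name"), int(idx) if idx is not None else None)


@dataclass(frozen=True)
class ModelPath:
    """An absolute address of a node in the model tree."""

    components: tuple[PathComponent, ...]

    def __post_init__(self) -> None:
        for c in self.components:
            if not c.name:
                raise PathError("empty path component")
            if c.index is not None and c.index < 0:
                raise PathError("negative path index")

    @classmethod
    def parse(cls, text: str) -> "ModelPath":
        if not text.startswith(SEP):
            raise PathError(f"path must be absolute (start with {SEP!r}): {text!r}")
        body = text[1:]
        if not body:
            return cls(())
        tokens = body.split(SEP)
        if any(not t for t in tokens):
            raise PathError(f"empty component in path: {text!r}")
        return cls(tuple(PathComponent.parse(t) for t in tokens))

    def __str__(self) -> str:
        return SEP + SEP.join(str(c) for c in self.components)

    def __len__(self) -> int:
        return len(self.components)

    @property
    def parent(self) -> "ModelPath":
        if not self.components:
            raise PathError("root path has no parent")
        return ModelPath(self.components[:-1])

    @property
    def name(self) -> str:
        if not self.components:
            return ""
        return str(self.components[-1])

    def child(self, token: str) -> "ModelPath":
        return ModelPath(self.components + (PathComponent.parse(token),))

    def is_ancestor_of(self, other: "ModelPath") -> bool:
        n = len(self.components)
        return n < len(other.components) and other.components[:n] == self.components

    def relative_to(self, ancestor: "ModelPath") -> tuple[str, ...]:
        if not (ancestor == self or ancestor.is_ancestor_of(self)):
            raise PathError(f"{self} is not under {ancestor}")
        return tuple(str(c) for c in self.components[len(ancestor.components):])


def as_path(p: "ModelPath | str") -> ModelPath:
    if isinstance(p, ModelPath):
        return p
    return ModelPath.parse(p)
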