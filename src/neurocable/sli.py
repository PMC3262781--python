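"""Loader for a restricted legacy SLI command subset.

Supports exactly four verbs — ``create``, ``setfield``, ``reset`` and
``step`` — enough to import single-cell scripts written in the legacy
scripting dialect into the model container *without running them*:

* ``create neutral <path>``      → a cell (namespace) node
* ``create compartment <path>``  → a segment flagged as
  actual-parameterized (its fields are already scaled values)
* ``setfield <path> <field> <v>``→ stores the value verbatim;
  Cm, Em, Vm_init, inject, Ra, Rm map onto the actual compartment
  parameters (no rescaling), dia/len are kept as DIA/LENGTH annotations
* ``reset`` / ``step T -time``   → recorded as pending run directives

Both ``setfield /cell/soma ...`` and the typeset form
``setfield/cell/soma ...`` (verb glued to the path) are accepted.
Any other verb raises an unsupported-command error naming it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import ModelContainer, ModelError

SUPPORTED_VERBS = ("create", "setfield", "reset", "step")

#: SLI field name → canonical actual-parameter name
FIELD_MAP = {
    "Cm": "Cm",
    "Em": "Em",
    "Vm_init": "InitVm",
    "inject": "Inject",
    "Ra": "Ra",
    "Rm": "Rm",
    "dia": "DIA",
    "len": "LENGTH",
}


class SliError(Exception):
    pass


@dataclass
class SliReport:
    """What an SLI script defined: model nodes plus pending directives."""

    cells: list[str] = field(default_factory=list)
    segments: list[str] = field(default_factory=list)
    fields_set: int = 0
    pending_reset: bool = False
    #: simulated durations (s) requested by ``step T -time``, to be
    #: executed only when the user later issues ``run``
    pending_runs: list[float] = field(default_factory=list)


def _split_glued(token: str, rest: list[str]) -> list[str]:
    """Handle the typeset form where the verb is glued to the path."""
    if "/" in token and not token.startswith("/"):
        verb, path = token.split("/", 1)
        return [verb, "/" + path] + rest
    return [token] + rest


def _tokenize(line: str) -> list[str]:
    # normalize the unicode minus that typeset listings carry
    parts = line.replace("−", "-").split()
    if not parts:
        return []
    return _split_glued(parts[0], parts[1:])


def sli_load(source: str, container: ModelContainer,
             is_filename: bool = True) -> SliReport:
    """Import the model defined by an SLI script into ``container``.

    The simulation itself is *not* run; ``reset``/``step`` lines are
    recorded in the returned report as pending directives.
    """
    if is_filename:
        with open(source) as fh:
            text = fh.read()
    else:
        text = source
    report = SliReport()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("//")[0].strip()
        if not line:
            continue
        tokens = _tokenize(line)
        # a line may chain several commands ("reset step 0.5 -time")
        i = 0
        while i < len(tokens):
            verb = tokens[i]
            if verb == "create":
                if i + 1 >= len(tokens) or (
                        i + 2 >= len(tokens) and "/" not in tokens[i + 1]):
                    raise SliError(f"line {lineno}: create needs a type and "
                                   "a path")
                args = _split_glued(tokens[i + 1],
                                    tokens[i + 2:i + 3])
                etype, path = args[0], args[1]
                if etype == "neutral":
                    container.create_cell(path)
                    report.cells.append(path)
                elif etype == "compartment":
                    seg = container.create_segment(path)
                    seg.actual_parameterized = True
                    report.segments.append(path)
                else:
                    raise SliError(
                        f"line {lineno}: unsupported element type {etype!r}")
                i += 1 + len(args)
            elif verb == "setfield":
                if i + 3 > len(tokens):
                    raise SliError(f"line {lineno}: setfield needs "
                                   "path, field and value")
                path, fname, value = tokens[i + 1], tokens[i + 2], tokens[i + 3]
                try:
                    node = container.resolve(path)
                except ModelError:
                    raise SliError(
                        f"line {lineno}: setfield on unknown path {path}"
                    ) from None
                canonical = FIELD_MAP.get(fname, fname)
                try:
                    node.parameters[canonical] = float(value)
                except ValueError:
                    node.parameters[canonical] = value
                report.fields_set += 1
                i += 4
            elif verb == "reset":
                report.pending_reset = True
                i += 1
            elif verb == "step":
                if i + 1 >= len(tokens):
                    raise SliError(f"line {lineno}: step needs an argument")
                t = float(tokens[i + 1])
                i += 2
                if i < len(tokens) and tokens[i] == "-time":
                    i += 1
                else:
                    raise SliError(
                        f"line {lineno}: only 'step T -time' is supported")
                report.pending_runs.append(t)
            else:
                raise SliError(
                    f"line {lineno}: unsupported command {verb!r}")
    return report
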