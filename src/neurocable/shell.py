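"""Interactive shell: a thin command router over the other modules.

The shell owns one model container, a configuration (library search
path, run directory, time step) and a component registry, and maps the
printed command surface — ``list components``, ``ndf_load``,
``sli_load``, ``morphology_summarize``, ``show_parameter``,
``set_runtime_parameter``, ``add_output``, ``run``, ``explore``,
``quit`` — onto the owning modules.  Commands are accepted both with a
space before the path and in the typeset glued form
(``morphology_summarize/cell``).

The shell is a pure router: every effect is byte-identical to calling
the module operations directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import yaml

from . import experiment, sli
from .config import Config
from .model import ModelContainer, ModelError, ParameterError
from .paths import PathError

log = logging.getLogger(__name__)

COMMANDS = ("list", "ndf_load", "sli_load", "morphology_summarize",
            "show_parameter", "set_runtime_parameter", "add_output",
            "run", "explore", "quit", "help")


@dataclass
class Component:
    name: str
    description: str
    module: str
    layer: int
    type_description: str
    status: str = "available"
    last_error: str | None = None


@dataclass
class ComponentRegistry:
    components: list[Component] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.components]
        assert len(names) == len(set(names)), "component names must be unique"

    def mark_loaded(self) -> None:
        for c in self.components:
            if c.status == "available":
                c.status = "loaded"

    def get(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    def render(self) -> str:
        blocks = []
        for c in self.components:
            entry = {
                "description": c.description,
                "module": c.module,
                "status": c.status,
                "type": {"description": c.type_description,
                         "layer": c.layer},
            }
            if c.last_error:
                entry["last-error"] = c.last_error
            blocks.append(yaml.safe_dump({c.name: entry},
                                         default_flow_style=False,
                                         sort_keys=True))
        return "".join(blocks)


def default_registry() -> ComponentRegistry:
    reg = ComponentRegistry([
        Component("model-container", "internal storage for neuronal models",
                  "neurocable.model", 2, "intermediary"),
        Component("solver", "implicit branched-cable compartmental solver",
                  "neurocable.solver", 1, "computational"),
        Component("experiment", "scheduler, outputs and event delivery",
                  "neurocable.experiment", 3, "orchestration"),
        Component("ndf", "declarative model file reader/writer",
                  "neurocable.ndf", 2, "description"),
        Component("sli", "legacy script subset importer",
                  "neurocable.sli", 2, "description"),
        Component("contours", "EM contour to equivalent-cylinder importer",
                  "neurocable.contours", 2, "description"),
    ])
    reg.mark_loaded()
    return reg


class ShellQuit(Exception):
    """Raised by ``quit`` to terminate a REPL loop."""


class Shell:
    def __init__(self, config: Config | None = None):
        self.config = config or Config()
        self.container = ModelContainer(
            library_paths=self.config.library_paths)
        self.registry = default_registry()
        #: outputs registered by add_output: (label, path, field)
        self.outputs: list[tuple[str, str, str]] = []
        #: pending run durations imported from SLI scripts
        self.pending_runs: list[float] = []
        self.last_output_file: str | None = None

    # -- command surface ---------------------------------------------------

    def dispatch(self, line: str) -> str:
        """Execute one command line; returns its printout."""
        tokens = self._tokenize(line)
        if not tokens:
            return ""
        cmd, args = tokens[0], tokens[1:]
        if cmd not in COMMANDS:
            return self._help(f"unknown command {cmd!r}")
        try:
            return getattr(self, f"_cmd_{cmd}")(args)
        except ShellQuit:
            raise
        except (ModelError, ParameterError, PathError, sli.SliError,
                experiment.ExperimentError, OSError, ValueError) as e:
            context = f" [{args[0]}]" if args else ""
            return f"error{context}: {e}"

    @staticmethod
    def _tokenize(line: str) -> list[str]:
        parts = line.strip().split()
        if not parts:
            return []
        head = parts[0]
        # typeset glued form: command/path/with/components
        if "/" in head and not head.startswith("/"):
            cmd, path = head.split("/", 1)
            return [cmd, "/" + path] + parts[1:]
        return parts

    # -- individual commands -----------------------------------------------

    def _cmd_help(self, args) -> str:
        return self._help()

    def _help(self, prefix: str = "") -> str:
        text = "commands: " + ", ".join(COMMANDS)
        return f"{prefix}\n{text}" if prefix else text

    def _cmd_quit(self, args) -> str:
        raise ShellQuit()

    def _cmd_list(self, args) -> str:
        if args and args[0] != "components":
            return self._help(f"unknown listing {args[0]!r}")
        return self.registry.render()

    def _cmd_ndf_load(self, args) -> str:
        if len(args) != 1:
            return self._help("ndf_load <file>")
        comp = self.registry.get("model-container")
        try:
            created = self.container.read_ndf(args[0])
        except Exception as e:
            comp.last_error = f"{args[0]}: {e}"
            return f"error [{args[0]}]: {e}"
        comp.last_error = None
        return f"loaded {args[0]}: " + ", ".join(
            str(n.path) for n in created)

    def _cmd_sli_load(self, args) -> str:
        if len(args) != 1:
            return self._help("sli_load <file>")
        fname = self.container.find_library_file(args[0])
        report = sli.sli_load(fname, self.container)
        self.pending_runs.extend(report.pending_runs)
        parts = [f"loaded {args[0]}:",
                 f"{len(report.cells)} cell(s),",
                 f"{len(report.segments)} segment(s),",
                 f"{report.fields_set} field(s)"]
        if report.pending_runs:
            parts.append(
                f"; pending run of {report.pending_runs[0]:g} s")
        return " ".join(parts)

    def _cmd_morphology_summarize(self, args) -> str:
        if len(args) != 1:
            return self._help("morphology_summarize <path>")
        self.container.morphology_summarize(args[0])
        return f"summarized {args[0]}"

    def _cmd_show_parameter(self, args) -> str:
        if len(args) != 2:
            return self._help("show_parameter <path> <name>")
        value = self.container.show_parameter(args[0], args[1])
        return f"{args[0]} {args[1]} = {value:g}" \
            if isinstance(value, (int, float)) else \
            f"{args[0]} {args[1]} = {value}"

    def _cmd_set_runtime_parameter(self, args) -> str:
        if len(args) != 3:
            return self._help("set_runtime_parameter <path> <name> <value>")
        path, name, raw = args
        raw = raw.strip('"“”')
        try:
            value: float | str = float(raw)
        except ValueError:
            value = raw
        self.container.set_parameter(path, name, value)
        return f"{path} {name} = {value}"

    def _cmd_add_output(self, args) -> str:
        if len(args) != 2:
            return self._help("add_output <path> <field>")
        path, fieldname = args
        self.container.resolve(path)  # fail early with path context
        label = f"output{len(self.outputs)}" if self.outputs else "output"
        self.outputs.append((label, path, fieldname))
        return f"output {label}: {path} {fieldname}"

    def _cmd_run(self, args) -> str:
        if not args:
            return self._help("run <path> [duration]")
        path = args[0]
        if len(args) > 1:
            duration = float(args[1])
        elif self.pending_runs:
            duration = self.pending_runs.pop(0)
        else:
            return self._help("run: no duration given and none pending")
        outputs = [tuple(o) for o in self.outputs]
        if not outputs:
            outputs = [("output", None, "Vm")]
        outfile = experiment.run_simulation(
            self.container, path, duration, dt=self.config.dt,
            outputs=outputs, output_file=self.config.output_path,
            event_dir=self.config.run_dir)
        self.last_output_file = outfile
        import math

        n_rows = int(math.floor(duration / self.config.dt + 0.5))
        return f"ran {path} for {duration:g} s ({n_rows} rows) -> {outfile}"

    def _cmd_explore(self, args) -> str:
        lines: list[str] = []

        def walk(node, depth: int) -> None:
            pad = "  " * depth
            params = " ".join(
                f"{k}={v:g}" if isinstance(v, (int, float)) else f"{k}={v}"
                for k, v in sorted(node.parameters.items()))
            lines.append(f"{pad}{node.path.name or '/'} "
                         f"({node.kind})" + (f" {params}" if params else ""))
            for child in node.children:
                walk(child, depth + 1)

        roots = args if args else [str(c.path) for c in self.container.cells()]
        for r in roots:
            walk(self.container.resolve(r), 0)
        return "\n".join(lines) if lines else "(empty model)"

    # -- batch driver ------------------------------------------------------

    def run_batch(self, lines) -> list[str]:
        out = []
        for line in lines:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                out.append(self.dispatch(line))
            except ShellQuit:
                break
        return out
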