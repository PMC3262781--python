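"""Implicit branched-cable solver over compiled compartment arrays.

The biological model tree is compiled into flat arrays: one
:class:`CompartmentRecord` per segment in Hines order (every parent
numbered before its children), a compartment→mechanism map, and channel
and synapse instance tables.  The membrane equation

    Cm dV/dt = (Em − V)/Rm + Inject + Σ_axial g·(V_parent − V)
               − Σ_channels GBAR·area·(∏ x^p)·(V − EREV)
               − Σ_synapses g_syn(t)·(V − EREV)

is advanced with fixed-step Crank–Nicolson.  Gating variables are
updated on staggered half-steps by exact exponential relaxation toward
their voltage-dependent steady state, then held while the linear
voltage system is solved by symmetric tree (Hines) elimination — one
sweep from the leaves to the root and a back-substitution from the root
to the leaves, with no fill-in beyond parent links.

Axial coupling between a child and its parent uses the half-resistance
convention g = 2/(Ra_child + Ra_parent): each compartment contributes
half of its own axial resistance to the link.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import GateKinetics, get_kinetics
from .model import (CellNode, ModelContainer, ModelError, ChannelNode,
                    SegmentNode, SynapseNode, specific_to_actual)
from .paths import ModelPath, as_path

#: default integration step, s
DEFAULT_DT = 1e-5

#: divergence guard: abort when any |Vm| exceeds this, V
VM_LIMIT = 1.0


class SolverError(Exception):
    pass


@dataclass
class CompartmentRecord:
    """Actual electrical parameters of one compartment in the compiled
    arrays; ``parent`` is −1 for a root."""

    parent: int
    Cm: float
    Em: float
    InitVm: float
    Inject: float
    Ra: float
    Rm: float


@dataclass
class ChannelInstance:
    comp: int
    area: float
    gbar: float
    erev: float
    gate_names: tuple[str, ...]
    powers: tuple[int, ...]
    kinetics: tuple[GateKinetics, ...]
    path: ModelPath


@dataclass
class SynapseInstance:
    comp: int
    gmax: float
    tau1: float
    tau2: float
    erev: float
    event_filename: str | None
    path: ModelPath


@dataclass
class CompiledModel:
    """Solver-ready flat representation of one cell."""

    records: list[CompartmentRecord]
    mech_map: list[int]
    channels: list[ChannelInstance]
    synapses: list[SynapseInstance]
    comp_paths: list[ModelPath]
    path_to_comp: dict[str, int]

    @property
    def n_compartments(self) -> int:
        return len(self.records)

    def dump(self) -> str:
        """Diagnostic text dump, one compartment per line in the field
        order parent, Cm, Em, InitVm, Inject, Ra, Rm."""
        lines = []
        for i, r in enumerate(self.records):
            lines.append(
                f"{i} {r.parent} {r.Cm:.17g} {r.Em:.17g} {r.InitVm:.17g} "
                f"{r.Inject:.17g} {r.Ra:.17g} {r.Rm:.17g}")
        lines.append("piC2m " + " ".join(str(i) for i in self.mech_map))
        return "\n".join(lines) + "\n"


def _segment_area(seg: SegmentNode) -> float | None:
    """Membrane area used to scale channel conductance densities."""
    if not seg.has_parameter("DIA"):
        return None
    dia = float(seg.get_parameter("DIA"))
    length = float(seg.get_parameter("LENGTH")) if seg.has_parameter("LENGTH") else 0.0
    if length > 0:
        return math.pi * dia * length
    return math.pi * dia * dia


def compile_all(container: ModelContainer, cellpath) -> CompiledModel:
    """Compile the cell (or segment subtree) at ``cellpath``.

    Compartments are numbered in canonical Hines order: depth-first
    pre-order with children visited in path-name order, so every parent
    index is smaller than its children's.  The mechanism map is
    CSR-style: entry i is the index of compartment i's first mechanism
    in the concatenated channel+synapse table, with a trailing −1
    sentinel.
    """
    root = container.resolve(cellpath)
    if isinstance(root, CellNode):
        roots = list(root.root_segments)
    elif isinstance(root, SegmentNode):
        roots = [root]
    else:
        raise SolverError(f"{cellpath} is a {root.kind}, expected cell")
    if not roots:
        raise SolverError(f"{cellpath} has no segments to compile")

    ordered: list[SegmentNode] = []

    def visit(seg: SegmentNode) -> None:
        ordered.append(seg)
        for child in sorted(seg.segment_children, key=lambda s: str(s.path)):
            visit(child)

    for r in sorted(roots, key=lambda s: str(s.path)):
        visit(r)

    index = {str(s.path): i for i, s in enumerate(ordered)}
    records: list[CompartmentRecord] = []
    channels: list[ChannelInstance] = []
    synapses: list[SynapseInstance] = []
    mech_map: list[int] = []
    for i, seg in enumerate(ordered):
        try:
            p = specific_to_actual(seg)
        except ModelError as e:
            raise SolverError(f"{seg.path}: {e}") from e
        parent = (index[str(seg.parent_segment.path)]
                  if seg.parent_segment is not None and
                  str(seg.parent_segment.path) in index else -1)
        records.append(CompartmentRecord(
            parent=parent, Cm=p.Cm, Em=p.Em, InitVm=p.InitVm,
            Inject=p.Inject, Ra=p.Ra, Rm=p.Rm))
        mech_map.append(len(channels) + len(synapses))
        area = _segment_area(seg)
        for child in seg.children:
            if isinstance(child, ChannelNode):
                if area is None:
                    raise SolverError(
                        f"{seg.path}: channel {child.path} needs a membrane "
                        "area (DIA/LENGTH) to scale GBAR")
                gates = child.gates
                names = tuple(gates)
                channels.append(ChannelInstance(
                    comp=i, area=area,
                    gbar=float(child.get_parameter("GBAR")),
                    erev=float(child.get_parameter("EREV")),
                    gate_names=names,
                    powers=tuple(gates[g][0] for g in names),
                    kinetics=tuple(get_kinetics(gates[g][1]) for g in names),
                    path=child.path))
            elif isinstance(child, SynapseNode):
                fname = child.parameters.get("EVENT_FILENAME")
                synapses.append(SynapseInstance(
                    comp=i,
                    gmax=float(child.get_parameter("GMAX")),
                    tau1=float(child.get_parameter("TAU1")),
                    tau2=float(child.get_parameter("TAU2")),
                    erev=float(child.get_parameter("EREV")),
                    event_filename=str(fname) if fname is not None else None,
                    path=child.path))
    mech_map.append(-1)
    return CompiledModel(
        records=records, mech_map=mech_map, channels=channels,
        synapses=synapses, comp_paths=[s.path for s in ordered],
        path_to_comp=index)


def hines_solve(diag, offdiag, parent, rhs):
    """Solve the symmetric tree system A·x = rhs.

    ``diag[i]`` is A[i,i]; ``offdiag[i]`` is A[i, parent[i]] =
    A[parent[i], i] (ignored for roots, parent[i] < 0).  ``parent`` must
    satisfy parent[i] < i (Hines order).  Elimination runs from the last
    compartment toward the root, back-substitution from the root out.
    """
    d = np.array(diag, dtype=float)
    r = np.array(rhs, dtype=float)
    n = d.shape[0]
    for i in range(n - 1, 0, -1):
        p = parent[i]
        if p < 0:
            continue
        f = offdiag[i] / d[i]
        d[p] -= f * offdiag[i]
        r[p] -= f * r[i]
    x = np.empty(n)
    for i in range(n):
        p = parent[i]
        if p < 0:
            x[i] = r[i] / d[i]
        else:
            x[i] = (r[i] - offdiag[i] * x[p]) / d[i]
    return x


class VariableAddress:
    """Opaque handle on one state variable inside a live solver."""

    def __init__(self, solver: "HinesSolver", comp: int, fieldname: str):
        self._solver = solver
        self._comp = comp
        self._field = fieldname

    def get(self) -> float:
        if self._solver is None:
            raise SolverError("address dereferenced after finish()")
        return self._solver._read(self._comp, self._field)

    def _invalidate(self) -> None:
        self._solver = None

    def __repr__(self) -> str:
        return f"<VariableAddress comp={self._comp} field={self._field}>"


class HinesSolver:
    """Fixed-step implicit integrator for one compiled cell.

    Mirrors the life cycle of a compartmental solver component:
    ``compile_all`` → ``reset`` → repeated ``advance`` → ``finish``.
    """

    FIELDS = ("Vm",)

    def __init__(self, name, model: ModelContainer, dt: float = DEFAULT_DT):
        self.name = as_path(name)
        self.model = model
        self.dt = float(dt)
        self.compiled: CompiledModel | None = None
        self._addresses: list[VariableAddress] = []
        self._finished = False

    # -- compilation -------------------------------------------------------

    def compile_all(self) -> CompiledModel:
        cm = compile_all(self.model, self.name)
        self.compiled = cm
        n = cm.n_compartments
        rec = cm.records
        self._parent = np.array([r.parent for r in rec], dtype=int)
        self._Cm = np.array([r.Cm for r in rec])
        self._Em = np.array([r.Em for r in rec])
        self._InitVm = np.array([r.InitVm for r in rec])
        self._Inject = np.array([r.Inject for r in rec])
        self._Rm = np.array([r.Rm for r in rec])
        # axial link conductance of compartment i to its parent
        g_ax = np.zeros(n)
        for i in range(1, n):
            p = rec[i].parent
            if p >= 0:
                g_ax[i] = 2.0 / (rec[i].Ra + rec[p].Ra)
        self._g_axial = g_ax
        # per-synapse runtime state lives in experiment.SynapseState
        from .experiment import SynapseState

        self._syn_states = [
            SynapseState(s.gmax, s.tau1, s.tau2) for s in cm.synapses]
        self._syn_events: list[np.ndarray] = [
            np.empty(0) for _ in cm.synapses]
        self.reset()
        return cm

    CompileAll = compile_all

    def _require_compiled(self) -> CompiledModel:
        if self.compiled is None:
            raise SolverError("model not compiled; call compile_all() first")
        if self._finished:
            raise SolverError("solver already finished")
        return self.compiled

    # -- event plumbing ----------------------------------------------------

    def set_events(self, synapse_path, times) -> None:
        """Attach a sorted spike-time train to a compiled synapse."""
        cm = self._require_compiled()
        key = str(as_path(synapse_path))
        for i, syn in enumerate(cm.synapses):
            if str(syn.path) == key:
                self._syn_events[i] = np.asarray(sorted(times), dtype=float)
                self._syn_ptr[i] = 0
                return
        raise SolverError(f"no compiled synapse at {key}")

    # -- state -------------------------------------------------------------

    def reset(self) -> None:
        cm = self._require_compiled()
        self.Vm = self._InitVm.copy()
        self._nsteps = 0
        self.gates: list[np.ndarray] = []
        for ch in cm.channels:
            v = self.Vm[ch.comp]
            self.gates.append(np.array(
                [k.steady_state(v) for k in ch.kinetics]))
        for st in self._syn_states:
            st.reset()
        self._syn_ptr = [0] * len(self._syn_states)

    @property
    def clock(self) -> float:
        return self._nsteps * self.dt

    def _read(self, comp: int, fieldname: str) -> float:
        if fieldname == "Vm":
            return float(self.Vm[comp])
        raise SolverError(f"unknown field {fieldname!r}")

    def get_address(self, path, fieldname: str) -> VariableAddress:
        cm = self._require_compiled()
        key = str(as_path(path))
        if key not in cm.path_to_comp:
            raise SolverError(f"no compartment at {key}")
        if fieldname not in self.FIELDS:
            raise SolverError(f"unknown field {fieldname!r}; "
                              f"supported: {self.FIELDS}")
        addr = VariableAddress(self, cm.path_to_comp[key], fieldname)
        self._addresses.append(addr)
        return addr

    GetAddress = get_address

    def synapse_conductance(self, i: int = 0) -> float:
        """Current conductance (S) of compiled synapse ``i``."""
        self._require_compiled()
        return self._syn_states[i].conductance()

    # -- integration -------------------------------------------------------

    def _step(self) -> None:
        cm = self.compiled
        dt = self.dt
        n = len(self.Vm)
        t_new = (self._nsteps + 1) * dt
        g_mech = np.zeros(n)  # extra membrane conductance, S
        b_mech = np.zeros(n)  # its reversal-weighted drive, A
        # gates: exponential relaxation using rates frozen at current Vm
        # (staggered half-step values), then the channel conductance for
        # the voltage step
        for ci, ch in enumerate(cm.channels):
            v = self.Vm[ch.comp]
            x = self.gates[ci]
            gopen = 1.0
            for gi, kin in enumerate(ch.kinetics):
                a = kin.alpha(v)
                b = kin.beta(v)
                tau = 1.0 / (a + b)
                xinf = a * tau
                xg = xinf + (x[gi] - xinf) * math.exp(-dt / tau)
                x[gi] = min(1.0, max(0.0, xg))
                gopen *= x[gi] ** ch.powers[gi]
            g = ch.gbar * ch.area * gopen
            g_mech[ch.comp] += g
            b_mech[ch.comp] += g * ch.erev
        # synapses: decay dual-exponential states, deliver events due in
        # (t, t + dt], then add their conductance
        from .experiment import deliver_events

        for si, st in enumerate(self._syn_states):
            st.advance(dt)
            self._syn_ptr[si] = deliver_events(
                st, self._syn_events[si], self._syn_ptr[si], t_new, dt)
            g = st.conductance()
            g_mech[cm.synapses[si].comp] += g
            b_mech[cm.synapses[si].comp] += g * cm.synapses[si].erev
        # Crank-Nicolson linear system on the tree
        g_leak = 1.0 / self._Rm
        g_memb = g_leak + g_mech
        c_dt = self._Cm / dt
        b = g_leak * self._Em + b_mech + self._Inject
        diag = c_dt + 0.5 * g_memb
        off = np.zeros(n)
        GV = g_memb * self.Vm  # explicit half of G·V
        for i in range(1, n):
            p = self._parent[i]
            if p < 0:
                continue
            g = self._g_axial[i]
            diag[i] += 0.5 * g
            diag[p] += 0.5 * g
            off[i] = -0.5 * g
            dv = self.Vm[i] - self.Vm[p]
            GV[i] += g * dv
            GV[p] -= g * dv
        rhs = c_dt * self.Vm - 0.5 * GV + b
        self.Vm = hines_solve(diag, off, self._parent, rhs)
        self._nsteps += 1
        if not np.all(np.isfinite(self.Vm)) or np.any(np.abs(self.Vm) > VM_LIMIT):
            worst = int(np.nanargmax(np.abs(self.Vm)))
            raise SolverError(
                f"divergence at t={self.clock:g}s: |Vm|="
                f"{abs(self.Vm[worst]):g} V at {cm.comp_paths[worst]}")

    def advance(self, t_target: float) -> None:
        """Take fixed-dt steps until the clock reaches ``t_target``."""
        self._require_compiled()
        tol = 1e-6 * self.dt
        if t_target < self.clock - tol:
            raise SolverError(
                f"cannot advance backwards: clock={self.clock}, "
                f"target={t_target}")
        while self.clock < t_target - tol:
            self._step()

    Advance = advance

    def finish(self) -> None:
        for addr in self._addresses:
            addr._invalidate()
        self._addresses.clear()
        self._finished = True

    Finish = finish
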