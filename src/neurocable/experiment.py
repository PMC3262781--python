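"""Simulation orchestration: scheduler loop, output recording, spike events.

Every participant in a simulation (the cable solver, output sinks,
event sources) is a *schedulee* exposing ``advance(t)`` and
``finish()``.  The scheduler advances all of them in lock-step through
an arithmetic time grid t_k = k·dt and calls ``finish`` once at the
end.

Synaptic input arrives as trains of afferent spike times (YAML files, a
top-level sequence of seconds).  Each delivered spike increments a
dual-exponential conductance

    g(t) = GMAX · norm · (e^{−Δ/TAU1} − e^{−Δ/TAU2}),   Δ = t − t0,

summed over past events, with ``norm`` chosen so a single event peaks
at exactly GMAX.  When TAU1 = TAU2 the waveform degenerates to the
alpha function g(t) = GMAX·(Δ/τ)·e^{1−Δ/τ}.  The state recursion uses
exact exponential decay per step, so events that fall on the time grid
reproduce the closed form to rounding error.
"""

from __future__ import annotations

import logging
import math
import os

import numpy as np
import yaml

from .model import ModelContainer
from .solver import DEFAULT_DT, HinesSolver

log = logging.getLogger(__name__)


class ExperimentError(Exception):
    pass


# -- event trains -----------------------------------------------------------

class EventTrain:
    """Sorted afferent spike times (s) for one synapse."""

    def __init__(self, times):
        times = [float(t) for t in times]
        if any(t < 0 for t in times):
            raise ExperimentError("spike times must be >= 0")
        if times != sorted(times):
            log.warning("event train was not sorted; sorting")
            times = sorted(times)
        self.times = np.asarray(times, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        return iter(self.times)


def load_events(filename: str) -> EventTrain:
    """Load a YAML sequence of spike times (seconds)."""
    with open(filename) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = []
    if not isinstance(data, list):
        raise ExperimentError(
            f"{filename}: expected a top-level YAML sequence of times")
    for item in data:
        if not isinstance(item, (int, float)) or isinstance(item, bool):
            raise ExperimentError(f"{filename}: non-numeric entry {item!r}")
    return EventTrain(data)


# -- dual-exponential synapse state ----------------------------------------

class SynapseState:
    """Conductance state of one synapse under dual-exponential dynamics."""

    def __init__(self, gmax: float, tau1: float, tau2: float):
        if tau1 <= 0 or tau2 <= 0:
            raise ExperimentError("synaptic time constants must be positive")
        self.gmax = float(gmax)
        self.tau1 = float(tau1)
        self.tau2 = float(tau2)
        self._alpha_mode = (tau1 == tau2)
        if not self._alpha_mode:
            tp = (tau1 * tau2 / (tau1 - tau2)) * math.log(tau1 / tau2)
            self._norm = 1.0 / (math.exp(-tp / tau1) - math.exp(-tp / tau2))
        self.reset()

    def reset(self) -> None:
        # dual-exp: partial sums of the two exponentials; alpha mode:
        # a = Σ e^{-Δ/τ}, s = Σ Δ·e^{-Δ/τ}
        self._A = 0.0
        self._B = 0.0

    def advance(self, dt: float) -> None:
        """Decay the state exactly over one step of length dt."""
        if self._alpha_mode:
            d = math.exp(-dt / self.tau1)
            self._B = d * (self._B + dt * self._A)
            self._A *= d
        else:
            self._A *= math.exp(-dt / self.tau1)
            self._B *= math.exp(-dt / self.tau2)

    def add_event(self) -> None:
        self._A += 1.0
        if not self._alpha_mode:
            self._B += 1.0

    def conductance(self) -> float:
        if self._alpha_mode:
            return self.gmax * math.e * self._B / self.tau1
        return self.gmax * self._norm * (self._A - self._B)

    def closed_form(self, t: float, event_times) -> float:
        """Analytic g(t) for a list of past events (reference path)."""
        g = 0.0
        for t0 in event_times:
            d = t - t0
            if d < 0:
                continue
            if self._alpha_mode:
                g += self.gmax * (d / self.tau1) * math.exp(1.0 - d / self.tau1)
            else:
                g += self.gmax * self._norm * (
                    math.exp(-d / self.tau1) - math.exp(-d / self.tau2))
        return g


def deliver_events(state: SynapseState, times, ptr: int, t: float,
                   dt: float) -> int:
    """Apply every event with time t0 ∈ (t − dt, t] to ``state``.

    ``times`` is the sorted train, ``ptr`` the index of the first
    undelivered event; returns the advanced pointer.  Events already in
    the past (t0 ≤ t − dt) are skipped with a warning.
    """
    n = len(times)
    tol = 1e-9 * max(dt, 1.0)
    while ptr < n and times[ptr] <= t - dt + tol:
        log.warning("skipping stale event at t0=%g (clock %g)",
                    times[ptr], t)
        ptr += 1
    while ptr < n and times[ptr] <= t + tol:
        state.add_event()
        ptr += 1
    return ptr


# -- schedulees -------------------------------------------------------------

class OutputSink:
    """Records addressed state variables, one text row per advance.

    Columns: time first, then one column per output, ``%.10g``,
    whitespace-separated, preceded by a single ``#``-comment header.
    """

    def __init__(self, filename: str):
        self.filename = filename
        self.outputs: list[tuple[str, object]] = []
        self._fh = None
        self.rows_written = 0

    def add_output(self, label: str, address) -> None:
        if address is None:
            raise ExperimentError("invalid address")
        existing = {lab for lab, _ in self.outputs}
        if label in existing:
            k = 2
            while f"{label}_{k}" in existing:
                k += 1
            log.warning("duplicate output label %r renamed to %r",
                        label, f"{label}_{k}")
            label = f"{label}_{k}"
        self.outputs.append((label, address))

    AddOutput = add_output

    def _ensure_open(self) -> None:
        if self._fh is None:
            d = os.path.dirname(self.filename)
            if d:
                os.makedirs(d, exist_ok=True)
            self._fh = open(self.filename, "w")
            labels = " ".join(lab for lab, _ in self.outputs)
            self._fh.write(f"# time {labels}".rstrip() + "\n")

    def advance(self, t: float) -> None:
        self._ensure_open()
        values = "".join(
            " %.10g" % addr.get() for _, addr in self.outputs)
        self._fh.write("%.10g%s\n" % (t, values))
        self.rows_written += 1

    Advance = advance

    def finish(self) -> None:
        self._ensure_open()  # duration-zero runs still produce a file
        self._fh.close()
        self._fh = None

    Finish = finish


class EventSource:
    """Schedulee binding a spike train file to one compiled synapse.

    Delivery itself happens inside the solver's sub-steps (events must
    land on the correct integration step); this object owns loading and
    attachment and participates in the schedule for life-cycle symmetry.
    """

    def __init__(self, solver: HinesSolver, synapse_path, train: EventTrain):
        self.synapse_path = synapse_path
        self.train = train
        solver.set_events(synapse_path, train.times)

    def advance(self, t: float) -> None:
        pass

    def finish(self) -> None:
        pass


class Scheduler:
    """Advances all schedulees in lock-step over t_k = k·dt."""

    def __init__(self, schedulees):
        self.schedulees = list(schedulees)

    def run(self, duration: float, dt: float) -> int:
        if duration <= 0:
            raise ExperimentError("duration must be positive")
        # round-half-up tie-break for durations not a multiple of dt
        n_steps = int(math.floor(duration / dt + 0.5))
        for k in range(1, n_steps + 1):
            t = k * dt
            for s in self.schedulees:
                s.advance(t)
        for s in self.schedulees:
            s.finish()
        return n_steps


# -- one-call front-end -----------------------------------------------------

def run_simulation(container: ModelContainer, modelpath, duration: float,
                   dt: float = DEFAULT_DT,
                   outputs=(("output", None, "Vm"),),
                   output_file: str = "output",
                   event_dir: str = ".") -> str:
    """Compile, reset and run one cell for ``duration`` seconds.

    ``outputs`` is a sequence of (label, compartment path or None for
    the first compartment, field) triples.  Synapses carrying an
    EVENT_FILENAME parameter are bound to their spike-train files,
    resolved against ``event_dir``.  Returns the output file path.
    """
    solver = HinesSolver(modelpath, container, dt=dt)
    compiled = solver.compile_all()

    schedulees: list = [solver]
    sink = OutputSink(output_file)
    for spec_ in outputs:
        label, path, fieldname = spec_
        if path is None:
            path = compiled.comp_paths[0]
        sink.add_output(label, solver.get_address(path, fieldname))
    schedulees.append(sink)
    for syn in compiled.synapses:
        if syn.event_filename:
            fname = syn.event_filename
            if not os.path.isabs(fname):
                fname = os.path.join(event_dir, fname)
            schedulees.append(
                EventSource(solver, syn.path, load_events(fname)))

    Scheduler(schedulees).run(duration, dt)
    return output_file
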