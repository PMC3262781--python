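# Methods

This note documents the models, numerical schemes and design choices
behind `neurocable`, and what the shipped tests do and do not
demonstrate.

## Model representation

A neuron model lives in the model container as a tree of nodes —
cells, segments, channels, synapses — addressed by absolute slash
paths whose components may carry integer indices (`b1s06[182]`).
Cells are namespaces, not electrical nodes: a segment's electrical
parent is its *nearest segment ancestor* by path, so `/cell/soma` under
`/cell` is a root (soma) compartment. The first root segment created
or loaded under a cell is designated its soma; all printed examples and
fixtures are single-root models. Unknown parameter names are stored
with a logged warning instead of being rejected, so library files can
carry annotations without breaking older readers.

All quantities are SI (V, s, m, Ω, F, S, A).

### Specific → actual translation

Membrane parameters are stored as *specific* quantities per unit
area/length and converted to one compartment's lumped values when the
model is compiled:

* cylinder (LENGTH > 0): area = π·DIA·LENGTH, Cm = CM·area,
  Rm = RM/area, Ra = 4·RA·LENGTH/(π·DIA²);
* sphere (LENGTH = 0): area = π·DIA², Ra = RA/(π·DIA/2).

These are the standard cable-modelling formulas; the tests pin the
dimensional identities Rm·area = RM and Cm/area = CM to machine
precision. Segments imported from legacy SLI scripts are flagged
*actual-parameterized*: their `setfield` values (Cm, Em, Vm_init,
inject, Ra, Rm) are already scaled, are stored verbatim, and bypass
this translation entirely at compile time — the compiled record equals
the script's values bit-exactly.

### Morphology annotations

`morphology_summarize` writes SOMATOPETAL_BRANCHPOINTS on every
segment of a subtree: the number of *strictly intermediate* nodes on
the path from the segment toward its soma that have ≥ 2 segment
children. "Between the segment and the soma" is read exclusively: a
branching node does not count for itself, nor does the soma. The count
is monotone non-decreasing along any root-to-tip path; both this
annotation and `segment_tips` (childless segments, depth-first
pre-order) are tested against brute-force traversals of an
independently built networkx graph.

## Numerical integration

### Scheme

The membrane equation on the tree is advanced with fixed-step
Crank–Nicolson. Each step:

1. every gating variable relaxes exponentially toward its steady state,
   x ← x∞ + (x − x∞)·e^(−dt/τ), with α, β frozen at the current
   (staggered half-step) voltage, then is clamped to [0, 1];
2. synapse states decay exactly over dt and spikes due in
   (t, t + dt] are delivered;
3. channel and synaptic conductances are held constant over the step
   and enter the Crank–Nicolson system
   (C/dt + G/2)·V⁺ = (C/dt − G/2)·V + b, where G is the symmetric
   tree-structured conductance matrix (membrane + axial terms) and b
   collects reversal-weighted drives and injected currents.

The linear solve is a Hines factorization: compartments are numbered
parents-first (depth-first pre-order with children visited in
path-name order, which also makes compilation independent of model
construction order), elimination sweeps from the last compartment to
the root and back-substitution from the root outward, with no fill-in
beyond parent links. Equivalence with a dense solve of the same system
is tested to < 1e-10 relative on random trees.

Axial coupling between child c and parent p uses the half-resistance
convention g = 2/(Ra_c + Ra_p): each compartment contributes half its
own axial resistance to the link. A single-compartment model has no
axial term.

For passive membranes the scheme is plain Crank–Nicolson: second-order
accurate (the RC-charging error drops ≈ 4× when dt is halved, which
the tests fit explicitly) and A-stable (at dt = 10·τ the iteration is
a bounded contraction toward steady state with amplification
(1 − 5)/(1 + 5) = −2/3; the approach oscillates but its distance to
steady state shrinks every step — this is the expected CN behaviour,
not an artifact).

### Parameters and guards

* `dt` defaults to 1e-5 s, the value used in all worked examples;
  it is supplied by the scheduler and fixed for a run.
* Gates are initialized at steady state for InitVm on reset.
* Divergence guard: any non-finite Vm or |Vm| > 1 V aborts with the
  offending compartment's path. Biophysical voltages are two orders of
  magnitude below this.
* `advance(t)` takes whole steps until the internal clock
  (an integer step counter times dt, immune to float drift) reaches t
  within 1e-6·dt.

### Channel kinetics

The shipped `channels/hodgkin-huxley.ndf` carries the classic
squid-axon kinetics at 6.3 °C in SI units with rest at −0.070 V:
Na⁺ with m³h gating (ḡ = 1200 S/m², E_rev = +0.045 V) and K⁺ with n⁴
(ḡ = 360 S/m², E_rev = −0.082 V). Rate functions take three forms —
linoid, exponential, sigmoid — with the linoid's removable singularity
evaluated by its limit A·σ within 1e-9 V of the pole. The library file
is the normative definition for this package; gate specs are encoded
as `GATE_<g>_POWER` / `GATE_<g>_KINETICS` parameters so the file
format's keyword set stays minimal.

### Synapses

Synaptic conductance is dual-exponential,
g(t) = GMAX·norm·(e^(−Δ/TAU1) − e^(−Δ/TAU2)) summed over delivered
spikes, normalized so a single event peaks at exactly GMAX (peak
normalization was chosen over unit-area normalization; defaults
TAU1 = 1 ms, TAU2 = 2 ms, EREV = 0 V). TAU1 = TAU2 degenerates to the
alpha function GMAX·(Δ/τ)·e^(1−Δ/τ), implemented with its own
two-state recursion. State decay uses exact exponential factors, so
spikes landing on the time grid reproduce the closed form to rounding
error; off-grid spikes are delivered at the end of the step containing
them, a first-order approximation consistent with the fixed-step
design. Delivery is causal (g ≡ 0 before the first spike) and linear
(superposition is exact by construction). Spike trains are YAML files:
a top-level sequence of seconds; unsorted input is sorted with a
warning, stale events (already more than one step in the past) are
skipped with a warning.

## Scheduler and output

All participants — solver, output sinks, event sources — implement
`advance(t)`/`finish()`. The scheduler advances them in lock-step over
the arithmetic grid t_k = k·dt, k = 1…round(duration/dt), computing
each t_k as a product rather than accumulating a float sum, so a 0.5 s
run at dt = 1e-5 emits exactly 50,000 rows. Output files are
whitespace-separated text, time first, `%.10g`, one `#` header line;
every value is also readable through the live `VariableAddress`
handles, and the tests cross-check file contents against direct state
reads.

## File formats

The NDF model dialect is deliberately minimal: `#!ndf` header; blocks
`CELL | SEGMENT | CHANNEL | SYNAPSE <name>`, `PARAMETER <name>
<value>`, `CHILD <file>::<prototype>` import references, `END`;
`#` comments; indentation ignored. Rendering is canonical — document
order, parameters sorted, numbers at 17 significant digits — so equal
documents render byte-identically and export∘import is the identity on
the model tree (tested over 100 random trees). It is a documented
local dialect, not compatible with any external format of the same
name. Library files resolve against an ordered search path (first
match wins); prototypes are deep-copied on import, so mutating one
instance never affects another.

The SLI subset accepts both `setfield /cell/soma f v` and the typeset
glued form `setfield/cell/soma f v`, plus Unicode minus signs.
`step T -time` is interpreted as "simulate T seconds", with
round-half-up of T/dt steps, and is deferred until a later `run`.

## Contour import

Serial-section EM contour stacks reduce to equivalent cylinders by
conserving the two quantities cable modelling needs: total length
(Σ thicknessᵢ) and lateral membrane area (Σ perimeterᵢ·thicknessᵢ),
giving DIA = area/(π·LENGTH). A volume-preserving criterion would be a
reasonable alternative but is not implemented. Polygon area and
perimeter go through shapely. Only unbranched stacks are supported;
branching within a contour series is out of scope. Recovery is exact
up to the polygonal perimeter deficit (relative error (π/N)²/6 for an
N-gon, ≈ 2.5e-5 at 256 vertices), and membrane-area conservation holds
to machine precision by construction.

## Synthetic fixtures

The fixtures module generates all test inputs; nothing is downloaded.
Random trees attach each new segment to a uniformly chosen existing
one, with parameters drawn from documented ranges around the standard
soma values (RM 0.5–2 Ω·m², RA 1–4 Ω·m, CM 0.008–0.03 F/m², DIA
2–20 µm, LENGTH 10–100 µm); Poisson trains use exponential gaps. Every
generator takes an explicit seed and owns its RNG stream, so identical
specs yield byte-identical fixtures.

These fixtures emulate the *structural* variety of dendritic trees
(branching, parameter spread), not the statistics of real
reconstructions: real morphologies have correlated diameters and
tapering, thousands of compartments, and spines. Passing tests
therefore demonstrate correctness of the algorithms on valid inputs,
not biological realism of any particular model.

## Problem sizes

The shipped suite and the acceptance script run, by choice, at sizes
where the independent oracles are cheap and exact: random trees up to
200 segments for morphology, 20 for dense-solve comparisons, 0.5 s of
single-compartment integration at dt = 1e-5, 0.1 s of the firing soma
at two step sizes. All algorithms are O(n) per step in the number of
compartments and have no size-dependent branches, so behaviour at
these sizes is representative.

## Known limitations

* One cell per solver instance; no network matrices or parallel event
  transport.
* Fixed time step; no adaptive or variable-order integration.
* Channel conductances are frozen over each step (linearized CN)
  rather than Newton-iterated; at the default dt this is the dominant
  but well-controlled error term for active membranes (spike counts
  shift by ≤ 1 under dt halving).
* The NDF dialect and the four-verb SLI subset are intentionally
  restricted; real legacy scripts using messages, functions or control
  flow are rejected with explicit errors.
* Contour import assumes closed, non-self-intersecting polygons and
  does not validate self-intersection.
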