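# neurocable

A compact compartmental neuron simulator built as a federation of small,
independently usable components:

* a **model container** that stores biological neuron models — cells,
  dendritic segments, Hodgkin–Huxley channels, synapses — as a tree
  addressed by slash paths (`/cell/soma`, `/Purkinje/segments/b1s06[182]`),
  and translates *specific* membrane parameters (RM in Ω·m², CM in F/m²,
  RA in Ω·m, as reported in the literature) into the *actual* values of
  each compartment (Rm = RM/area, Cm = CM·area, Ra = 4·RA·L/(π·d²))
  consumed by the solver;
* an implicit **branched-cable solver** that compiles the tree into
  Hines-ordered flat arrays and integrates

      Cm dV/dt = (Em − V)/Rm + I_inject + Σ g_axial(V_parent − V)
                 − Σ ḡ·area·(∏ x^p)(V − E_rev) − g_syn(t)(V − E_syn)

  with fixed-step Crank–Nicolson, staggered exponential gate updates,
  and an O(n) symmetric tree factorization (no fill-in beyond parent
  links);
* a **channel library** shipping the classic squid-axon Na⁺ (m³h) and
  K⁺ (n⁴) kinetics in `channels/hodgkin-huxley.ndf`;
* an **experiment layer**: a lock-step scheduler, text output sinks, and
  event-driven dual-exponential synapses fed by YAML spike-train files;
* a declarative, diffable **model file dialect (NDF)** with canonical
  rendering and exact round-trips;
* a loader for a four-verb subset of the legacy **SLI** scripting
  dialect (`create`, `setfield`, `reset`, `step`), which imports a model
  without running it;
* an **EM contour importer** that reduces serial-section contour stacks
  to equivalent cylinders conserving lateral membrane area;
* an interactive **shell** (`neurocable shell`) routing the whole
  surface: `list components`, `ndf_load`, `sli_load`,
  `morphology_summarize`, `show_parameter`, `set_runtime_parameter`,
  `add_output`, `run`, `explore`.

It is aimed at teaching, prototyping and testing of single-cell
biophysical models: every piece is plain Python over numpy, and every
numerical claim in the test suite is checked against an independent
oracle (closed forms, dense linear solves, graph-library traversals).

## Worked example

A single cylindrical soma (20 µm × 44.7 µm, RM 1 Ω·m², CM 0.0164 F/m²,
RA 2.5 Ω·m, leak at −80 mV, resting at −68 mV) charged by a 1 nA current:

```python
from neurocable import ModelContainer, HinesSolver, OutputSink, Scheduler

nmc = ModelContainer()
nmc.create_cell("/cell")
soma = nmc.create_segment("/cell/soma")
soma.set_parameters({
    "Vm_init": -0.0680, "RM": 1.000, "RA": 2.50, "CM": 0.0164,
    "ELEAK": -0.0800, "DIA": 2e-05, "LENGTH": 4.47e-05,
})
soma.set_parameter("INJECT", 1e-9)

solver = HinesSolver("/cell", nmc, dt=1e-5)
solver.compile_all()
out = OutputSink("/tmp/output")
out.add_output("output", solver.get_address("/cell/soma", "Vm"))
Scheduler([solver, out]).run(duration=0.5, dt=1e-5)
```

The compartment's actual parameters are Cm ≈ 4.606e-11 F,
Rm ≈ 3.561e+08 Ω (τ = RM·CM = 16.4 ms), so the membrane charges from
−68 mV toward Em + I·Rm ≈ +276 mV along the RC curve; `/tmp/output`
holds 50,000 whitespace-separated rows `t Vm`, ending at

```
0.5 0.2760513268
```

within 4e-9 V of the closed form V(t) = V∞ + (V₀ − V∞)·e^(−t/τ).
Importing the shipped channels first makes the same soma fire:

```python
soma_path = "/cell/soma"
nmc.import_child(soma_path, "channels/hodgkin-huxley.ndf::/na")
nmc.import_child(soma_path, "channels/hodgkin-huxley.ndf::/k")
```

which yields 10 action potentials in the first 100 ms at dt = 1e-5 s.

The same model as a legacy SLI script, loaded without running:

```
create neutral/cell
create compartment/cell/soma
setfield/cell/soma Cm 4.57537e-11
...
reset step 0.5 -time
```

`sli_load` stores these already-scaled values bit-exactly and records
the `step 0.5 -time` as a pending run directive for the shell's `run`.

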