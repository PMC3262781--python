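import math

import numpy as np
import pytest

from neurocable.fixtures import random_tree, single_soma, soma_parameters
from neurocable.model import ModelContainer
from neurocable.solver import (HinesSolver, SolverError, compile_all,
                               hines_solve)

from conftest import soma_actual


def rc_closed_form(t, p, inject):
    """Analytic membrane charging of a single passive compartment."""
    tau = p["Rm"] * p["Cm"]
    vinf = p["Em"] + inject * p["Rm"]
    return vinf + (p["InitVm"] - vinf) * np.exp(-t / tau)


# -- compilation ------------------------------------------------------------

def test_compile_single_soma_record(soma_container):
    cm = compile_all(soma_container, "/cell")
    assert cm.n_compartments == 1
    r = cm.records[0]
    ref = soma_actual()
    assert r.parent == -1
    assert r.Cm == pytest.approx(ref["Cm"], rel=1e-14)
    assert r.Rm == pytest.approx(ref["Rm"], rel=1e-14)
    assert r.Ra == pytest.approx(ref["Ra"], rel=1e-14)
    assert (r.Em, r.InitVm, r.Inject) == (-0.08, -0.068, 1e-9)
    assert cm.mech_map == [0, -1]  # no mechanisms
    assert "piC2m 0 -1" in cm.dump()


def test_compile_y_tree_ordering(y_tree):
    cm = compile_all(y_tree, "/cell")
    assert cm.n_compartments == 4
    for i, r in enumerate(cm.records):
        assert r.parent < i


@pytest.mark.parametrize("seed", [0, 1])
def test_compile_random_tree_isomorphic(seed):
    nmc = random_tree(50, seed)
    cm = compile_all(nmc, "/cell")
    assert cm.n_compartments == 50
    # the compiled parent relation must mirror the model tree exactly
    for i, seg_path in enumerate(cm.comp_paths):
        seg = nmc.resolve(seg_path)
        p = cm.records[i].parent
        if seg.parent_segment is None:
            assert p == -1
        else:
            assert cm.comp_paths[p] == seg.parent_segment.path


def test_compile_errors_name_the_offending_segment():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    nmc.create_segment("/cell/soma")  # no parameters at all
    with pytest.raises(SolverError, match="/cell/soma"):
        compile_all(nmc, "/cell")


# -- addresses --------------------------------------------------------------

def test_address_tracks_initial_condition(soma_container):
    s = HinesSolver("/cell", soma_container)
    s.compile_all()
    addr = s.get_address("/cell/soma", "Vm")
    assert addr.get() == -0.068
    with pytest.raises(SolverError):
        s.get_address("/cell/soma", "Xm")
    s.finish()
    with pytest.raises(SolverError):
        addr.get()


def test_two_addresses_are_independent():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    a = nmc.create_segment("/cell/a")
    b = nmc.create_segment("/cell/a/b")
    a.set_parameters(soma_parameters())
    b.set_parameters({**soma_parameters(), "Vm_init": -0.05})
    s = HinesSolver("/cell", nmc)
    s.compile_all()
    assert s.get_address("/cell/a", "Vm").get() == -0.068
    assert s.get_address("/cell/a/b", "Vm").get() == -0.05


# -- passive dynamics -------------------------------------------------------

def test_equilibrium_is_preserved():
    nmc = single_soma(inject=0.0)
    nmc.resolve("/cell/soma").set_parameter("Vm_init", -0.08)  # = ELEAK
    s = HinesSolver("/cell", nmc)
    s.compile_all()
    for k in range(1, 1001):
        s.advance(k * s.dt)
    assert abs(s.Vm[0] - (-0.08)) < 1e-12


def test_rc_charging_matches_closed_form(soma_container):
    s = HinesSolver("/cell", soma_container, dt=1e-5)
    s.compile_all()
    ref = soma_actual()
    n = 5000  # 0.05 s
    vs = np.empty(n)
    for k in range(n):
        s.advance((k + 1) * s.dt)
        vs[k] = s.Vm[0]
    t = (np.arange(n) + 1) * s.dt
    exact = rc_closed_form(t, ref, 1e-9)
    assert np.max(np.abs(vs - exact)) < 1e-4


def test_crank_nicolson_second_order_convergence(soma_container):
    # halving dt should cut the closed-form error by about 4x
    ref = soma_actual()
    errs = []
    for dt in (4e-4, 2e-4):
        s = HinesSolver("/cell", single_soma(inject=1e-9), dt=dt)
        s.compile_all()
        n = int(round(0.02 / dt))
        vs = np.empty(n)
        for k in range(n):
            s.advance((k + 1) * dt)
            vs[k] = s.Vm[0]
        t = (np.arange(n) + 1) * dt
        errs.append(np.max(np.abs(vs - rc_closed_form(t, ref, 1e-9))))
    ratio = errs[0] / errs[1]
    assert 3.0 < ratio < 5.0


def test_two_compartment_steady_state_matches_dense_solve():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    a = nmc.create_segment("/cell/a")
    b = nmc.create_segment("/cell/a/b")
    a.set_parameters({**soma_parameters(), "INJECT": 1e-9})
    b.set_parameters({**soma_parameters(), "DIA": 1e-5, "LENGTH": 8e-5})
    s = HinesSolver("/cell", nmc, dt=1e-4)
    cm = s.compile_all()
    s.advance(0.5)  # about 30 membrane time constants
    ra, rb = cm.records
    g_ax = 2.0 / (ra.Ra + rb.Ra)
    G = np.array([[1 / ra.Rm + g_ax, -g_ax],
                  [-g_ax, 1 / rb.Rm + g_ax]])
    rhs = np.array([ra.Em / ra.Rm + ra.Inject, rb.Em / rb.Rm + rb.Inject])
    v_exact = np.linalg.solve(G, rhs)
    assert np.max(np.abs(s.Vm - v_exact) / np.abs(v_exact)) < 1e-9


def test_linearity_of_passive_response():
    vs = {}
    for inject in (0.0, 1e-9, 2e-9):
        s = HinesSolver("/cell", single_soma(inject=inject), dt=1e-5)
        s.compile_all()
        s.advance(0.01)
        vs[inject] = s.Vm[0]
    # deviation from the unstimulated trajectory scales with the current
    assert (vs[2e-9] - vs[0.0]) == pytest.approx(
        2 * (vs[1e-9] - vs[0.0]), rel=1e-9)


def test_a_stability_with_huge_step():
    # dt = 10*Rm*Cm: Crank-Nicolson stays bounded and approaches V_inf
    ref = soma_actual()
    tau = ref["Rm"] * ref["Cm"]
    s = HinesSolver("/cell", single_soma(inject=1e-9), dt=10 * tau)
    s.compile_all()
    vinf = ref["Em"] + 1e-9 * ref["Rm"]
    prev_gap = abs(s.Vm[0] - vinf)
    bound = prev_gap
    for k in range(1, 21):
        s.advance(k * s.dt)
        # bounded: never further from V_inf than the start was
        gap = abs(s.Vm[0] - vinf)
        assert gap <= bound + 1e-15
        # distance to steady state shrinks every step
        assert gap < prev_gap
        prev_gap = gap
    # amplification factor (1-5)/(1+5): gap shrinks by (2/3)^20 ~ 3e-4
    assert prev_gap < 1e-3 * bound


def test_voltage_bounds_passive(soma_container):
    ref = soma_actual()
    s = HinesSolver("/cell", soma_container, dt=1e-5)
    s.compile_all()
    vinf = ref["Em"] + 1e-9 * ref["Rm"]
    lo = min(ref["Em"], ref["InitVm"], vinf) - 1e-12
    hi = max(ref["Em"], ref["InitVm"], vinf) + 1e-12
    for k in range(1, 501):
        s.advance(k * s.dt)
        assert lo <= s.Vm[0] <= hi


# -- the tree solve itself --------------------------------------------------

@pytest.mark.parametrize("seed", range(10))
def test_hines_solve_equals_dense_solve(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 21))
    parent = np.full(n, -1)
    for i in range(1, n):
        parent[i] = int(rng.integers(0, i))
    diag = rng.uniform(1.0, 3.0, n)
    off = -rng.uniform(0.1, 0.5, n)
    off[0] = 0.0
    rhs = rng.normal(size=n)
    A = np.diag(diag)
    for i in range(1, n):
        A[i, parent[i]] = off[i]
        A[parent[i], i] = off[i]
    x_dense = np.linalg.solve(A, rhs)
    x_hines = hines_solve(diag, off, parent, rhs)
    denom = np.max(np.abs(x_dense))
    assert np.max(np.abs(x_hines - x_dense)) / denom < 1e-10


def test_construction_order_does_not_change_trajectory():
    def build(order):
        nmc = ModelContainer()
        nmc.create_cell("/cell")
        nmc.create_segment("/cell/soma").set_parameters(
            {**soma_parameters(), "INJECT": 1e-9})
        for name in order:
            nmc.create_segment(f"/cell/soma/{name}").set_parameters(
                {**soma_parameters(), "DIA": 5e-6})
        return nmc

    trajs = []
    for order in (("a", "b", "c"), ("c", "a", "b")):
        s = HinesSolver("/cell", build(order), dt=1e-5)
        cm = s.compile_all()
        idx = cm.path_to_comp["/cell/soma/b"]
        vs = []
        for k in range(1, 201):
            s.advance(k * s.dt)
            vs.append(s.Vm[idx])
        trajs.append(vs)
    assert trajs[0] == trajs[1]


# -- guards -----------------------------------------------------------------

def test_advance_requires_compile(soma_container):
    s = HinesSolver("/cell", soma_container)
    with pytest.raises(SolverError, match="compile"):
        s.advance(1e-3)


def test_advance_backwards_rejected(soma_container):
    s = HinesSolver("/cell", soma_container)
    s.compile_all()
    s.advance(1e-3)
    with pytest.raises(SolverError, match="backwards"):
        s.advance(1e-4)


def test_divergence_guard_aborts():
    nmc = single_soma(inject=1e-5)  # absurd current: V_inf >> 1 V
    s = HinesSolver("/cell", nmc, dt=1e-3)
    s.compile_all()
    with pytest.raises(SolverError, match="divergence"):
        s.advance(1.0)


# -- active membrane --------------------------------------------------------

def count_spikes(vs, threshold=0.0):
    vs = np.asarray(vs)
    return int(np.sum((vs[1:] > threshold) & (vs[:-1] <= threshold)))


def hh_soma():
    from neurocable.config import shipped_library_dir

    nmc = single_soma(inject=1e-9)
    nmc.library_paths = [shipped_library_dir()]
    nmc.import_child("/cell/soma", "channels/hodgkin-huxley.ndf::/na")
    nmc.import_child("/cell/soma", "channels/hodgkin-huxley.ndf::/k")
    return nmc


def test_hh_soma_fires_and_is_dt_stable():
    counts = {}
    for dt in (1e-5, 5e-6):
        s = HinesSolver("/cell", hh_soma(), dt=dt)
        s.compile_all()
        n = int(round(0.1 / dt))
        vs = np.empty(n)
        for k in range(n):
            s.advance((k + 1) * dt)
            vs[k] = s.Vm[0]
        counts[dt] = count_spikes(vs)
    assert counts[1e-5] >= 1
    assert abs(counts[1e-5] - counts[5e-6]) <= 1


def test_gates_initialized_at_steady_state_and_bounded():
    s = HinesSolver("/cell", hh_soma(), dt=1e-5)
    s.compile_all()
    from neurocable.channels import steady_state

    m0 = s.gates[0][s.compiled.channels[0].gate_names.index("m")]
    assert m0 == pytest.approx(steady_state("hh_na_m", -0.068), rel=1e-12)
    for k in range(1, 2001):
        s.advance(k * s.dt)
        for x in s.gates:
            assert np.all(x >= 0.0) and np.all(x <= 1.0)
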