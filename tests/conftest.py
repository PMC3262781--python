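import math

import pytest

from neurocable.config import shipped_library_dir
from neurocable.fixtures import single_soma, soma_parameters
from neurocable.model import ModelContainer


@pytest.fixture
def soma_container() -> ModelContainer:
    """The standard single-soma cell with 1 nA injection."""
    return single_soma(inject=1e-9)


@pytest.fixture
def library_dir() -> str:
    return shipped_library_dir()


@pytest.fixture
def y_tree() -> ModelContainer:
    """soma -> a -> {b, c}: one branch point at a."""
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    for p in ("/cell/soma", "/cell/soma/a", "/cell/soma/a/b",
              "/cell/soma/a/c"):
        seg = nmc.create_segment(p)
        seg.set_parameters(soma_parameters())
    return nmc


def soma_actual() -> dict:
    """Reference actual values of the standard soma, computed from the
    scaling formulas independently of the implementation."""
    p = soma_parameters()
    area = math.pi * p["DIA"] * p["LENGTH"]
    return {
        "area": area,
        "Cm": p["CM"] * area,
        "Rm": p["RM"] / area,
        "Ra": 4.0 * p["RA"] * p["LENGTH"] / (math.pi * p["DIA"] ** 2),
        "Em": p["ELEAK"],
        "InitVm": p["Vm_init"],
    }


def tree_equal(c1: ModelContainer, root1, c2: ModelContainer, root2) -> bool:
    """Deep field-by-field equality of two model subtrees."""
    n1, n2 = c1.resolve(root1), c2.resolve(root2)

    def eq(a, b) -> bool:
        if type(a) is not type(b):
            return False
        if a.path.name != b.path.name:
            return False
        if set(a.parameters) != set(b.parameters):
            return False
        for k in a.parameters:
            va, vb = a.parameters[k], b.parameters[k]
            if isinstance(va, (int, float)) != isinstance(vb, (int, float)):
                return False
            if isinstance(va, (int, float)):
                if float(va) != float(vb):
                    return False
            elif va != vb:
                return False
        if len(a.children) != len(b.children):
            return False
        return all(eq(x, y) for x, y in zip(a.children, b.children))

    return eq(n1, n2)
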