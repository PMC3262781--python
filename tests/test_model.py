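import math

import networkx as nx
import pytest

from neurocable.fixtures import random_tree, soma_parameters
from neurocable.model import (ModelContainer, ModelError, ParameterError,
                              specific_to_actual)

from conftest import soma_actual


# -- construction -----------------------------------------------------------

def test_create_cell_and_resolve_identity():
    nmc = ModelContainer()
    cell = nmc.create_cell("/cell")
    assert nmc.resolve("/cell") is cell
    assert cell.root_segments == []
    nested = nmc.create_cell("/a")
    assert nmc.resolve("/a") is nested


def test_duplicate_cell_path_rejected():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    with pytest.raises(ModelError, match="duplicate"):
        nmc.create_cell("/cell")


def test_segment_parent_rules():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    soma = nmc.create_segment("/cell/soma")
    # a root segment under a cell has no parent segment
    assert soma.parent_segment is None
    assert nmc.resolve("/cell").root_segments == [soma]
    d1 = nmc.create_segment("/cell/soma/d1")
    assert d1.parent_segment is soma
    assert soma.segment_children == [d1]
    with pytest.raises(ModelError):
        nmc.create_segment("/nocell/s")


# -- parameters -------------------------------------------------------------

def test_set_parameter_readback_and_overwrite():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    soma = nmc.create_segment("/cell/soma")
    soma.set_parameter("INJECT", 1e-9)
    assert nmc.show_parameter("/cell/soma", "INJECT") == 1e-9
    soma.set_parameter("INJECT", 2e-9)
    assert nmc.show_parameter("/cell/soma", "INJECT") == 2e-9


def test_full_soma_parameter_mapping_readable(soma_container):
    for name, value in soma_parameters().items():
        assert soma_container.show_parameter("/cell/soma", name) == value
    assert soma_container.show_parameter("/cell/soma", "RM") == 1.000


def test_inject_defaults_to_zero():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    nmc.create_segment("/cell/soma")
    assert nmc.show_parameter("/cell/soma", "INJECT") == 0


def test_unknown_parameter_stored_with_warning(caplog):
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    soma = nmc.create_segment("/cell/soma")
    with caplog.at_level("WARNING"):
        soma.set_parameter("ANNOTATION", "hello")
    assert "ANNOTATION" in caplog.text
    assert nmc.show_parameter("/cell/soma", "ANNOTATION") == "hello"


# -- specific -> actual scaling ---------------------------------------------

def test_specific_to_actual_cylinder(soma_container):
    p = specific_to_actual(soma_container.resolve("/cell/soma"))
    ref = soma_actual()
    assert p.Cm == pytest.approx(4.6061e-11, rel=1e-4)
    assert p.Rm == pytest.approx(3.5605e8, rel=1e-4)
    assert p.Ra == pytest.approx(3.5571e5, rel=1e-4)
    # dimensional consistency to machine precision
    assert p.Rm * ref["area"] == pytest.approx(1.0, rel=1e-14)
    assert p.Cm / ref["area"] == pytest.approx(0.0164, rel=1e-14)
    assert p.Em == ref["Em"] and p.InitVm == ref["InitVm"]
    assert p.Inject == 1e-9


def test_unit_area_identity():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    seg = nmc.create_segment("/cell/soma")
    seg.set_parameters({**soma_parameters(),
                        "DIA": 1.0, "LENGTH": 1.0 / math.pi})
    p = specific_to_actual(seg)
    assert p.Cm == pytest.approx(0.0164, rel=1e-14)
    assert p.Rm == pytest.approx(1.0, rel=1e-14)


def test_scaling_linear_in_length():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    a = nmc.create_segment("/cell/a")
    b = nmc.create_segment("/cell/b")
    a.set_parameters(soma_parameters())
    b.set_parameters({**soma_parameters(), "LENGTH": 2 * 4.47e-05})
    pa, pb = specific_to_actual(a), specific_to_actual(b)
    assert pb.Cm == pytest.approx(2 * pa.Cm, rel=1e-14)
    assert pb.Ra == pytest.approx(2 * pa.Ra, rel=1e-14)
    assert pb.Rm == pytest.approx(pa.Rm / 2, rel=1e-14)


def test_sphere_case():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    seg = nmc.create_segment("/cell/soma")
    seg.set_parameters({**soma_parameters(), "LENGTH": 0.0})
    p = specific_to_actual(seg)
    dia = 2e-5
    assert p.Cm == pytest.approx(0.0164 * math.pi * dia**2, rel=1e-14)
    assert p.Ra == pytest.approx(2.5 / (math.pi * dia / 2), rel=1e-14)


@pytest.mark.parametrize("mutation", [
    {"DIA": -1e-6}, {"DIA": 0.0},
])
def test_bad_geometry_rejected(mutation):
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    seg = nmc.create_segment("/cell/soma")
    seg.set_parameters({**soma_parameters(), **mutation})
    with pytest.raises(ParameterError):
        specific_to_actual(seg)


def test_missing_required_parameter_rejected():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    seg = nmc.create_segment("/cell/soma")
    params = soma_parameters()
    params.pop("RM")
    seg.set_parameters(params)
    with pytest.raises(ParameterError, match="RM"):
        specific_to_actual(seg)


# -- library import ---------------------------------------------------------

def test_import_two_channels(soma_container, library_dir):
    soma_container.library_paths = [library_dir]
    soma_container.import_child("/cell/soma",
                                "channels/hodgkin-huxley.ndf::/na")
    soma_container.import_child("/cell/soma",
                                "channels/hodgkin-huxley.ndf::/k")
    soma = soma_container.resolve("/cell/soma")
    kinds = [c.kind for c in soma.children]
    assert kinds == ["channel", "channel"]
    na = soma_container.resolve("/cell/soma/na")
    assert na.gates["m"] == (3, "hh_na_m") and na.gates["h"] == (1, "hh_na_h")


def test_imported_copies_are_independent(library_dir):
    nmc = ModelContainer(library_paths=[library_dir])
    nmc.create_cell("/cell")
    nmc.create_segment("/cell/a")
    nmc.create_segment("/cell/b")
    nmc.import_child("/cell/a", "channels/hodgkin-huxley.ndf::/na")
    nmc.import_child("/cell/b", "channels/hodgkin-huxley.ndf::/na")
    nmc.set_parameter("/cell/a/na", "GBAR", 999.0)
    assert nmc.show_parameter("/cell/b/na", "GBAR") == 1200.0


def test_missing_library_file_error(soma_container):
    with pytest.raises(ModelError, match="missing.ndf"):
        soma_container.import_child("/cell/soma", "missing.ndf::/x")


# -- morphology queries -----------------------------------------------------

def _segment_graph(nmc, cellpath):
    """Independent view of the segment tree as a networkx digraph."""
    g = nx.DiGraph()
    for seg in nmc.segments_of(cellpath):
        g.add_node(str(seg.path))
        if seg.parent_segment is not None:
            g.add_edge(str(seg.parent_segment.path), str(seg.path))
    return g


def test_single_soma_is_its_own_tip(soma_container):
    assert [str(p) for p in soma_container.segment_tips("/cell")] == \
        ["/cell/soma"]


def test_y_tree_tips(y_tree):
    assert [str(p) for p in y_tree.segment_tips("/cell")] == \
        ["/cell/soma/a/b", "/cell/soma/a/c"]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_random_tree_tips_match_graph_oracle(seed):
    nmc = random_tree(200, seed)
    g = _segment_graph(nmc, "/cell")
    tips = {str(p) for p in nmc.segment_tips("/cell")}
    assert tips == {n for n in g.nodes if g.out_degree(n) == 0}
    # pre-order: every tip appears after its ancestors
    order = [str(s.path) for s in nmc.segments_of("/cell")]
    pos = {p: i for i, p in enumerate(order)}
    for u, v in g.edges:
        assert pos[u] < pos[v]


def test_branchpoint_annotation_y_tree(y_tree):
    y_tree.morphology_summarize("/cell")
    assert y_tree.show_parameter("/cell/soma", "SOMATOPETAL_BRANCHPOINTS") == 0
    # node a branches, and it is strictly between b and the soma
    assert y_tree.show_parameter("/cell/soma/a/b",
                                 "SOMATOPETAL_BRANCHPOINTS") == 1
    # a's own branching does not count for a itself (endpoint)
    assert y_tree.show_parameter("/cell/soma/a",
                                 "SOMATOPETAL_BRANCHPOINTS") == 0


def test_unbranched_chain_has_no_branchpoints():
    nmc = ModelContainer()
    nmc.create_cell("/cell")
    path = "/cell/soma"
    nmc.create_segment(path).set_parameters(soma_parameters())
    for k in range(4):
        path += f"/s{k}"
        nmc.create_segment(path).set_parameters(soma_parameters())
    nmc.morphology_summarize("/cell")
    assert nmc.show_parameter(path, "SOMATOPETAL_BRANCHPOINTS") == 0


def test_derived_parameter_unknown_before_summarize(y_tree):
    from neurocable.model import ParameterError
    with pytest.raises(ParameterError):
        y_tree.show_parameter("/cell/soma/a/b", "SOMATOPETAL_BRANCHPOINTS")


@pytest.mark.parametrize("seed", [3, 4])
def test_branchpoints_match_graph_oracle_and_are_monotone(seed):
    nmc = random_tree(120, seed)
    nmc.morphology_summarize("/cell")
    g = _segment_graph(nmc, "/cell")
    soma = "/cell/soma"
    for seg in nmc.segments_of("/cell"):
        p = str(seg.path)
        nodes = nx.shortest_path(g.to_undirected(as_view=True), p, soma)
        expected = sum(1 for n in nodes[1:-1] if g.out_degree(n) >= 2)
        assert seg.parameters["SOMATOPETAL_BRANCHPOINTS"] == expected
        # monotone non-decreasing toward the tips
        if seg.parent_segment is not None:
            assert expected >= \
                seg.parent_segment.parameters["SOMATOPETAL_BRANCHPOINTS"]
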