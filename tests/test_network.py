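import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hapnet.io import ConfigurationError, DoseSensitivityMap, InteractionSet, ValidationError
from hapnet.network import (
    DEFAULT_SCORER,
    SCORERS,
    CompiledModule,
    PathwayNetwork,
    build_pathway_network,
    min_haploinsufficient_score,
    normalized_module_scores,
    score_edge,
    score_module,
)

from _oracles import oracle_edge_score, oracle_module_score
from conftest import make_matrix

calls_st = st.integers(-2, 2)
gds_st = st.integers(1, 3)


# ---------------------------------------------------------------------------
# edge scoring
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("c1,c2,w1,w2,value,branch", [
    (-1, 0, 3, 1, -3, "deletion"),
    (0, 0, 2, 3, 0, "gain"),
    (-2, 1, 2, 1, -4, "deletion"),   # gain term suppressed
    (1, 2, 1, 2, 5, "gain"),
    (-1, -1, 1, 1, -2, "deletion"),
])
def test_score_edge_examples(c1, c2, w1, w2, value, branch):
    es = score_edge(c1, c2, w1, w2)
    assert es.value == value
    assert es.branch == branch


def test_score_edge_domain_error():
    with pytest.raises(ValidationError):
        score_edge(-3, 0, 1, 1)
    with pytest.raises(ValidationError):
        score_edge(0, 5, 1, 1)


@given(calls_st, calls_st, gds_st, gds_st)
def test_score_edge_symmetric(c1, c2, w1, w2):
    assert score_edge(c1, c2, w1, w2) == score_edge(c2, c1, w2, w1)


@given(calls_st, calls_st, gds_st, gds_st)
def test_score_edge_sign_invariants(c1, c2, w1, w2):
    es = score_edge(c1, c2, w1, w2)
    if es.branch == "deletion":
        assert es.value <= 0
    else:
        assert es.value >= 0


@given(calls_st, calls_st, gds_st, gds_st)
def test_score_edge_matches_oracle(c1, c2, w1, w2):
    assert score_edge(c1, c2, w1, w2).value == oracle_edge_score(c1, c2, w1, w2)


@given(calls_st, calls_st, gds_st, gds_st)
def test_score_edge_monotone_in_call(c1, c2, w1, w2):
    if c1 < 2:
        assert score_edge(c1 + 1, c2, w1, w2).value >= score_edge(c1, c2, w1, w2).value


@given(calls_st, gds_st, gds_st)
def test_deleted_edge_score_non_increasing_in_gds(c2, w1, w2):
    # haploinsufficient genes weigh more: raising a GDS weight on a deleted
    # edge can only push the score further down
    if w1 < 3:
        assert (score_edge(-1, c2, w1 + 1, w2).value
                <= score_edge(-1, c2, w1, w2).value)


def test_mixed_partner_scorer_retains_gain_term():
    s = SCORERS["mixed_partner"]
    assert s.score(-2, 1, 2, 1) == -3  # -4 + 1, partner retained


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def test_build_intrinsic(toy_interactions, toy_gds):
    nw = build_pathway_network("P", ["A", "B", "C"], toy_interactions, toy_gds)
    assert nw.edges == (("A", "B"),)
    assert set(nw.nodes) == {"A", "B", "C"}
    assert nw.gds == {"A": 1, "B": 2, "C": 3}


def test_build_cross_pathway(toy_interactions, toy_gds):
    nw = build_pathway_network("P", ["A", "B", "C"], toy_interactions, toy_gds,
                               mode="cross_pathway", cross_universe={"X"})
    assert nw.edges == (("A", "B"), ("B", "X"))
    assert nw.members == frozenset({"A", "B", "C"})


def test_build_cross_requires_universe(toy_interactions, toy_gds):
    with pytest.raises(ConfigurationError):
        build_pathway_network("P", ["A"], toy_interactions, toy_gds, mode="cross_pathway")


def test_build_expand1(toy_interactions, toy_gds):
    nw = build_pathway_network("P", ["A", "B", "C"], toy_interactions, toy_gds,
                               mode="expand1")
    assert set(nw.nodes) == {"A", "B", "C", "X"}
    assert nw.edges == (("A", "B"), ("B", "X"))


def test_build_expand2_reaches_second_step(toy_gds):
    iset = InteractionSet.from_pairs([("A", "X"), ("X", "Y"), ("Y", "Z")])
    nw1 = build_pathway_network("P", ["A"], iset, toy_gds, mode="expand1")
    nw2 = build_pathway_network("P", ["A"], iset, toy_gds, mode="expand2")
    assert set(nw1.nodes) == {"A", "X"}
    assert set(nw2.nodes) == {"A", "X", "Y"}
    assert nw2.edges == (("A", "X"), ("X", "Y"))


def test_build_unscorable(toy_gds):
    iset = InteractionSet.from_pairs([("Q", "R")])
    nw = build_pathway_network("P", ["A", "B"], iset, toy_gds)
    assert not nw.scorable
    assert nw.n_edges == 0


def test_intrinsic_nodes_all_members(toy_interactions, toy_gds):
    nw = build_pathway_network("P", ["A", "B", "C"], toy_interactions, toy_gds)
    assert set(nw.nodes) <= nw.members
    with pytest.raises(ValidationError):
        PathwayNetwork("BAD", {"A": 1, "Z": 1}, (("A", "Z"),),
                       mode="intrinsic", members=frozenset({"A"}))


# ---------------------------------------------------------------------------
# module scores
# ---------------------------------------------------------------------------


def test_min_score_example():
    nw = PathwayNetwork("P", {"A": 1, "B": 2, "C": 3}, (("A", "B"), ("B", "C")),
                        members=frozenset("ABC"))
    assert min_haploinsufficient_score(nw) == -8


def test_min_score_edgeless():
    nw = PathwayNetwork("P", {"A": 1}, (), members=frozenset("A"))
    assert min_haploinsufficient_score(nw) == 0


def test_min_score_single_edge():
    nw = PathwayNetwork("P", {"A": 1, "B": 1}, (("A", "B"),), members=frozenset("AB"))
    assert min_haploinsufficient_score(nw) == -2


def test_score_module_examples(path_network):
    nw = PathwayNetwork("P", {"A": 1, "B": 1}, (("A", "B"),), members=frozenset("AB"))
    assert score_module(nw, {"A": -1, "B": -1}) == -2
    assert score_module(nw, {"A": 0, "B": 0}) == 0
    assert score_module(path_network, {"A": -1, "B": 0, "C": 1}) == 0


def test_score_module_absent_gene_is_zero(path_network):
    assert score_module(path_network, {"A": -1}) == -1


def test_normalized_scores(path_network):
    # min score of the chain is -4; cohort: all -1 then mixed
    m = make_matrix({"A": [-1, -1], "B": [-1, 0], "C": [-1, 1]})
    table = normalized_module_scores(path_network, m)
    assert table.min_haploinsufficient_score == -4
    assert table.normalized[0] == pytest.approx(-1.0)
    assert table.raw[1] == 0
    assert table.mean_normalized == pytest.approx(-0.5)


def test_normalized_half():
    nw = PathwayNetwork("P", {"A": 1, "B": 2, "C": 3}, (("A", "B"), ("B", "C")),
                        members=frozenset("ABC"))
    m = make_matrix({"A": [-1], "B": [-1], "C": [0]})
    table = normalized_module_scores(nw, m)
    assert table.raw[0] == -5  # AB: -3, BC: -2
    assert table.normalized[0] == pytest.approx(-5 / 8)


def test_normalized_positive_can_reach_plus_one():
    nw = PathwayNetwork("P", {"A": 1, "B": 1}, (("A", "B"),), members=frozenset("AB"))
    m = make_matrix({"A": [1], "B": [1]})
    table = normalized_module_scores(nw, m)
    assert table.normalized[0] == pytest.approx(1.0)


def test_unscorable_network_flagged():
    nw = PathwayNetwork("P", {"A": 1}, (), members=frozenset("A"))
    m = make_matrix({"A": [0, -1]})
    table = normalized_module_scores(nw, m)
    assert not table.scorable
    assert np.isnan(table.normalized).all()


def test_missing_genes_counted(path_network):
    m = make_matrix({"A": [-1], "B": [-1]})  # C absent from matrix
    compiled = CompiledModule(path_network, m.genes)
    assert compiled.n_missing_genes == 1
    assert compiled.raw_scores(m.values.to_numpy())[0] == -3  # BC edge: C treated as 0


def test_continuous_matrix_rejected(path_network):
    m = make_matrix({"A": [0.1]}, mode="continuous")
    with pytest.raises(ConfigurationError):
        normalized_module_scores(path_network, m)


# ---------------------------------------------------------------------------
# oracle equivalence (vectorized vs brute force)
# ---------------------------------------------------------------------------


def test_compiled_matches_scalar_exhaustive():
    nw = PathwayNetwork("P", {"A": 1, "B": 2, "C": 3},
                        (("A", "B"), ("B", "C"), ("A", "C")), members=frozenset("ABC"))
    genes = ["A", "B", "C"]
    for assignment in itertools.product([-2, -1, 0, 1, 2], repeat=3):
        calls = dict(zip(genes, assignment))
        m = make_matrix({g: [calls[g]] for g in genes})
        compiled = CompiledModule(nw, m.genes)
        vec = compiled.raw_scores(m.values.to_numpy())[0]
        assert vec == score_module(nw, calls) == oracle_module_score(nw.edges, nw.gds, calls)


@given(st.integers(0, 2**32 - 1))
def test_monotone_module_score_in_single_call(seed):
    rng = np.random.default_rng(seed)
    genes = ["A", "B", "C", "D"]
    edges = tuple(sorted((a, b) for a, b in itertools.combinations(genes, 2)
                         if rng.random() < 0.6))
    if not edges:
        return
    gds = {g: int(rng.integers(1, 4)) for g in genes}
    nw = PathwayNetwork("P", gds, edges, members=frozenset(genes))
    calls = {g: int(rng.integers(-2, 3)) for g in genes}
    g = rng.choice(genes)
    if calls[g] > -2:
        lowered = dict(calls, **{g: calls[g] - 1})
        assert score_module(nw, lowered) <= score_module(nw, calls)
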