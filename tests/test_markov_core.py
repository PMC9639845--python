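import numpy as np
import pytest

from genetrank.markov_core import (
    SolverOptions,
    StateDistribution,
    add_restart,
    batch_absorption,
    batch_personalized_stationary,
    build_transition,
    hit_probabilities,
    hit_score,
    solve_absorption_exact,
    stationary_restart_distribution,
    uniform_absorption,
)
from genetrank.ppin_io import GeneSet, InteractionNetwork
from genetrank import fixtures


def rows_sum_to_one(model):
    return np.allclose(np.asarray(model.matrix.sum(axis=1)).ravel(), 1.0, atol=1e-12)


def test_unweighted_transition_rows_are_uniform(path4):
    model = build_transition(path4.network, path4.P)
    M = model.matrix.toarray()
    net = path4.network
    s, a = net.index_of("s"), net.index_of("a")
    # out-degree 2 on the path interior: each step probability 1/2
    assert M[s, net.index_of("t1")] == pytest.approx(0.5)
    assert M[s, a] == pytest.approx(0.5)
    for t in path4.P.ids:
        i = net.index_of(t)
        row = np.zeros(net.n)
        row[i] = 1.0
        assert np.allclose(M[i], row)
    assert rows_sum_to_one(model)


def test_weighted_transition_follows_vertex_and_edge_weights():
    # u -> v1 (edge .5, vertex 1.0) and u -> v2 (edge .5, vertex .5):
    # normalized step probabilities 2/3 and 1/3
    net = InteractionNetwork(
        {("u", "v1"): 0.5, ("u", "v2"): 0.5, ("v1", "u"): 1.0, ("v2", "u"): 1.0},
        vertex_weights={"v1": 1.0, "v2": 0.5},
        directed=True,
    )
    model = build_transition(net, GeneSet(("v1",), "T"))
    M = model.matrix.toarray()
    u = net.index_of("u")
    assert M[u, net.index_of("v1")] == pytest.approx(2 / 3)
    assert M[u, net.index_of("v2")] == pytest.approx(1 / 3)


def test_source_weight_variant_reduces_to_degree_normalization(path4):
    M = path4.network.walk_matrix("source").toarray()
    s = path4.network.index_of("s")
    assert M[s].sum() == pytest.approx(1.0)
    assert M[s, path4.network.index_of("a")] == pytest.approx(0.5)


def test_restart_zero_leaves_chain_unchanged(path4):
    base = build_transition(path4.network, path4.P)
    same = add_restart(base, GeneSet(("s",), "S'"), 0.0)
    assert np.allclose(same.matrix.toarray(), base.matrix.toarray())


def test_restart_adds_to_existing_arc(triangle):
    # a--b arc exists; restart into {b} accumulates on top of the walk mass
    base = build_transition(triangle.network, GeneSet(("c",), "T"))
    r = 0.4
    chain = add_restart(base, GeneSet(("b",), "S'"), r)
    net = triangle.network
    a, b = net.index_of("a"), net.index_of("b")
    walk = base.matrix.toarray()[a, b]
    assert chain.matrix.toarray()[a, b] == pytest.approx((1 - r) * walk + r)
    assert rows_sum_to_one(chain)


def test_restart_validation(path4):
    base = build_transition(path4.network, path4.P)
    with pytest.raises(ValueError, match="outside"):
        add_restart(base, GeneSet(("s",)), 1.0)
    with pytest.raises(ValueError, match="intersects"):
        add_restart(base, GeneSet(("t1",)), 0.3)


@pytest.mark.parametrize("r", [0.0, 0.3, 0.7])
def test_all_chains_are_row_stochastic(path4, star, fig1_motif, r):
    for inst in (path4, star, fig1_motif):
        base = build_transition(inst.network, inst.P)
        chain = add_restart(base, GeneSet((inst.X.ids[0],)), r)
        assert rows_sum_to_one(chain)


@pytest.mark.parametrize("r", [0.0, 0.5])
def test_single_target_absorbs_everything(path3, r):
    base = build_transition(path3.network, path3.P)
    chain = add_restart(base, GeneSet(("s",)), r)
    hv = hit_probabilities(chain, StateDistribution.point_mass(path3.network, "s"))
    assert hv["t"] == pytest.approx(1.0, abs=1e-5)


def test_star_targets_split_evenly(star):
    base = build_transition(star.network, star.P)
    hv = hit_probabilities(base, StateDistribution.point_mass(star.network, "s"))
    assert hv["t1"] == pytest.approx(0.5, abs=1e-5)
    assert hv["t2"] == pytest.approx(0.5, abs=1e-5)


@pytest.mark.parametrize(
    "r,expected", [(0.0, (2 / 3, 1 / 3)), (0.5, (0.8, 0.2))]
)
def test_two_target_path_absorption(path4, r, expected):
    """Hand-solved absorption split on t1--s--a--t2, re-derived by the exact
    oracle before the iterative solver is checked against it."""
    base = build_transition(path4.network, path4.P)
    chain = add_restart(base, GeneSet(("s",)), r) if r else base
    init = StateDistribution.point_mass(path4.network, "s")
    oracle = solve_absorption_exact(chain, init)
    assert oracle["t1"] == pytest.approx(expected[0], abs=1e-12)
    assert oracle["t2"] == pytest.approx(expected[1], abs=1e-12)
    hv = hit_probabilities(chain, init, tol=1e-6)
    assert np.abs(hv.probabilities - oracle.probabilities).max() < 1e-5


def test_absorbed_mass_never_decreases(path4):
    base = build_transition(path4.network, path4.P)
    chain = add_restart(base, GeneSet(("s",)), 0.4)
    MT = chain.matrix.T
    t_idx = chain.target_indices
    pi = StateDistribution.point_mass(path4.network, "s").probabilities
    prev = 0.0
    for _ in range(200):
        pi = MT @ pi
        mass = pi[t_idx].sum()
        assert mass >= prev - 1e-15
        prev = mass


def test_restart_biases_toward_source_adjacent_target(path4):
    """On t1--s--a--t2, t1 is adjacent to the restart vertex: its hitting
    probability grows strictly with r."""
    base = build_transition(path4.network, path4.P)
    init = StateDistribution.point_mass(path4.network, "s")
    values = []
    for r in [0.0, 0.2, 0.4, 0.6, 0.8]:
        chain = add_restart(base, GeneSet(("s",)), r) if r else base
        values.append(solve_absorption_exact(chain, init)["t1"])
    assert all(b > a for a, b in zip(values, values[1:]))


def test_unreachable_target_degenerate_cases():
    # directed: a -> b -> c with T = {a}; from b the walk can never hit a
    net = InteractionNetwork(
        {("a", "b"): 1.0, ("b", "c"): 1.0}, directed=True
    )
    base = build_transition(net, GeneSet(("a",), "T"))
    chain = add_restart(base, GeneSet(("b",), "S'"), 0.3)
    init = StateDistribution.point_mass(net, "b")
    with pytest.raises(ValueError, match="singular"):
        solve_absorption_exact(chain, init)
    hv = hit_probabilities(chain, init, tol=1e-6, max_iter=500)
    assert not hv.converged
    H, _, _ = batch_absorption(net, net.indices_of(["b"]), net.indices_of(["a"]), 0.3)
    assert np.allclose(H, 0.0)


def test_init_on_targets_rejected(path4):
    base = build_transition(path4.network, path4.P)
    with pytest.raises(ValueError, match="mass on targets"):
        hit_probabilities(base, StateDistribution.point_mass(path4.network, "t1"))


def test_hit_score_identity_for_singleton_source(path3, path4):
    for inst in (path3, path4):
        scores = hit_score(inst, inst.X.ids[0], 0.0)
        for t, q in scores.items():
            assert q == pytest.approx(1.0, abs=1e-6)


def test_hit_score_hand_values(path4):
    scores = hit_score(path4, "s", 0.5)
    assert scores["t1"] == pytest.approx(1.2, abs=1e-5)
    assert scores["t2"] == pytest.approx(0.6, abs=1e-5)


def test_hit_score_undefined_when_baseline_vanishes(fig1_motif):
    # t2 is shielded by absorbing t1/t4: its baseline hitting probability is 0
    scores = hit_score(fig1_motif, "s1", 0.4)
    assert np.isnan(scores["t2"])
    assert np.isfinite(scores["t3"])


def test_triangle_personalized_stationary(triangle):
    sd = stationary_restart_distribution(triangle.network, GeneSet(("a",)), 0.5)
    got = dict(zip(triangle.network.vertices, sd.probabilities))
    assert got["a"] == pytest.approx(0.6, abs=1e-6)
    assert got["b"] == pytest.approx(0.2, abs=1e-6)
    assert got["c"] == pytest.approx(0.2, abs=1e-6)


def test_plain_walk_stationary_is_degree_proportional(path4):
    net = path4.network
    sd = stationary_restart_distribution(net, GeneSet(("s",)), 0.0)
    deg = np.array([net.out_degree(v) for v in net.vertices], dtype=float)
    assert np.allclose(sd.probabilities, deg / deg.sum(), atol=1e-6)


def test_full_restart_set_on_vertex_transitive_graph(triangle):
    sd = stationary_restart_distribution(
        triangle.network, GeneSet(("a", "b", "c")), 0.5
    )
    assert np.allclose(sd.probabilities, 1 / 3, atol=1e-6)


def test_batch_engines_match_per_source_route(smallworld):
    """The factorized multi-source solvers agree with per-chain iteration."""
    net = smallworld.network
    X, P = smallworld.X, smallworld.P
    s_idx = net.indices_of(X.ids[:4])
    t_idx = net.indices_of(P.ids)
    r = 0.35
    H, _, _ = batch_absorption(net, s_idx, t_idx, r, SolverOptions())
    base = build_transition(net, P)
    for row, s in enumerate(X.ids[:4]):
        chain = add_restart(base, GeneSet((s,)), r)
        hv = hit_probabilities(chain, StateDistribution.point_mass(net, s))
        assert np.abs(hv.probabilities - H[row]).max() < 1e-5
    # personalized stationary: batch vs the public fixed-point solver
    Pi = batch_personalized_stationary(net, s_idx[:2], r, SolverOptions())
    for row, s in enumerate(X.ids[:2]):
        sd = stationary_restart_distribution(net, GeneSet((s,)), r)
        assert np.abs(sd.probabilities - Pi[row]).max() < 1e-5


def test_uniform_baseline_matches_iterative_route(smallworld):
    net = smallworld.network
    den = uniform_absorption(net, smallworld.X.ids, smallworld.P.ids)
    base = build_transition(net, smallworld.P)
    hv = hit_probabilities(
        base, StateDistribution.uniform_on(net, smallworld.X.ids)
    )
    assert np.abs(hv.probabilities - den).max() < 1e-5


def test_hit_vector_tsv_export(tmp_path, path4):
    base = build_transition(path4.network, path4.P)
    hv = hit_probabilities(base, StateDistribution.point_mass(path4.network, "s"))
    dest = tmp_path / "hits.tsv"
    hv.to_tsv(dest)
    rows = [line.split("\t") for line in dest.read_text().splitlines()]
    assert [r[0] for r in rows] == list(path4.P.ids)
    assert float(rows[0][1]) == pytest.approx(2 / 3, abs=1e-5)
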