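import numpy as np
import pandas as pd
import pytest

from genetrank.fixtures import reference_gene_list
from genetrank.ppin_io import GeneSet
from genetrank.prioritization import (
    average_scores,
    contender_score,
    count_hits,
    cumulative_sets,
    saturation,
    sweep,
    top_k,
)
from genetrank.scoring import ScoreTable


def tables(scores, r=0.5):
    """Forward table plus a reverse table of all -inf (never the max)."""
    scores = np.asarray(scores, dtype=float)
    m, k = scores.shape
    src = tuple(f"x{i}" for i in range(m))
    tgt = tuple(f"p{j}" for j in range(k))
    fwd = ScoreTable("X_to_P", r, "genetrank", src, tgt, np.exp(scores))
    rev = ScoreTable("P_to_X", r, "genetrank", tgt, src, np.full((k, m), 1e-300))
    return fwd, rev


# -- average scores and top-k ----------------------------------------------

def test_average_of_top_tau_values():
    fwd, rev = tables([[3.0, 1.0, -1.0]])
    ranking = average_scores(fwd, rev, tau=2)
    assert ranking.frame.loc[0, "avg_score"] == pytest.approx(2.0)


def test_tau_one_uses_largest_max_score():
    fwd, rev = tables([[3.0, 1.0, -1.0], [2.5, 2.4, 2.3]])
    ranking = average_scores(fwd, rev, tau=1)
    assert ranking.genes == ("x0", "x1")
    assert ranking.frame["avg_score"].tolist() == pytest.approx([3.0, 2.5])


def test_max_is_taken_across_directions():
    fwd, _ = tables([[1.0, 1.0]])
    rev = ScoreTable(
        "P_to_X", 0.5, "genetrank", ("p0", "p1"), ("x0",),
        np.exp(np.array([[5.0], [1.0]])),
    )
    ranking = average_scores(fwd, rev, tau=1)
    assert ranking.frame.loc[0, "avg_score"] == pytest.approx(5.0)


def test_ties_break_by_gene_id():
    fwd, rev = tables([[2.0], [2.0], [3.0]])
    ranking = average_scores(fwd, rev, tau=1)
    assert ranking.genes == ("x2", "x0", "x1")


def test_tau_bounds_enforced():
    fwd, rev = tables([[1.0, 2.0]])
    with pytest.raises(ValueError, match="tau"):
        average_scores(fwd, rev, tau=3)


def test_gene_with_no_defined_score_is_excluded(caplog):
    fwd, rev = tables([[1.0, 2.0], [1.0, 1.0]])
    scores = fwd.scores.copy()
    scores[1] = np.nan
    fwd = ScoreTable(fwd.direction, fwd.r, fwd.method, fwd.sources, fwd.targets, scores)
    rev = ScoreTable(rev.direction, rev.r, rev.method, rev.sources, rev.targets,
                     np.full_like(rev.scores, np.nan))
    with caplog.at_level("WARNING", logger="genetrank"):
        ranking = average_scores(fwd, rev, tau=1)
    assert ranking.genes == ("x0",)
    assert "excluded" in caplog.text


def test_top_k_truncates_and_handles_short_lists():
    fwd, rev = tables([[5.0], [4.0], [3.0]])
    ranking = average_scores(fwd, rev, tau=1)
    assert top_k(ranking, 2).ids == ("x0", "x1")
    assert top_k(ranking, 1).ids == ("x0",)
    assert top_k(ranking, 99).ids == ("x0", "x1", "x2")


# -- cumulative sets, saturation, hits --------------------------------------

def rankings_from_lists(gene_lists):
    out = []
    for i, genes in enumerate(gene_lists):
        frame = pd.DataFrame(
            {"gene": genes, "avg_score": np.arange(len(genes), 0, -1.0),
             "n_defined": 1, "rank": np.arange(1, len(genes) + 1)}
        )
        out.append(
            __import__("genetrank").prioritization.RankedGeneList(1, 0.8 - i * 0.1,
                                                                  "genetrank", frame)
        )
    return out


def test_disjoint_consecutive_sets_grow_linearly():
    rks = rankings_from_lists([["a", "b"], ["c", "d"], ["e", "f"]])
    cums = cumulative_sets(rks, k=2)
    assert [len(c) for c in cums] == [2, 4, 6]  # k*l under zero overlap


def test_identical_sets_do_not_grow():
    rks = rankings_from_lists([["a", "b"], ["a", "b"], ["a", "b"]])
    cums = cumulative_sets(rks, k=2)
    assert [len(c) for c in cums] == [2, 2, 2]


def test_first_cumulative_set_is_first_top_k():
    rks = rankings_from_lists([["a", "b", "c"], ["d", "e", "f"]])
    cums = cumulative_sets(rks, k=2)
    assert set(cums[0].ids) == {"a", "b"}


def test_saturation_values():
    assert saturation(GeneSet(("a", "b", "c", "d")), 10, 5) == (0.4, 0.08)
    assert saturation(GeneSet(tuple("abcdefghij")), 10, 5)[0] == 1.0


def test_count_hits():
    assert count_hits(GeneSet(("a", "b")), GeneSet(("c",))) == 0
    ref = GeneSet(("a", "b"))
    assert count_hits(GeneSet(("a", "b", "c")), ref) == 2


def test_reference_list_fixture():
    ref = reference_gene_list()
    assert len(ref) == 6
    assert "O15304" in ref  # SIVA1
    assert "O00429" in ref  # DNM1L


# -- contenders -------------------------------------------------------------

def test_absorbing_contender_skips_renormalization(path4):
    tab = contender_score(path4, "X_to_P", 0.5, "genetrank_as")
    assert tab.score("s", "t1") == pytest.approx(0.8, abs=1e-6)
    assert tab.score("s", "t2") == pytest.approx(0.2, abs=1e-6)


def test_pr_affinity_on_triangle(triangle):
    tab = contender_score(triangle, "X_to_P", 0.5, "pr_affinity")
    # ppr_a(b) = 0.2 and ppr_b(a) = 0.6: affinity is the smaller one
    assert tab.score("a", "b") == pytest.approx(0.2, abs=1e-6)
    assert tab.score("a", "c") == pytest.approx(0.2, abs=1e-6)


def test_renorm_contender_needs_restart(path4):
    with pytest.raises(ValueError, match="r > 0"):
        contender_score(path4, "X_to_P", 0.0, "genetrank_renorm")


def test_unknown_method_rejected(path4):
    with pytest.raises(ValueError, match="unknown method"):
        contender_score(path4, "X_to_P", 0.5, "pagerank")


# -- sweep ------------------------------------------------------------------

def test_sweep_single_cell_degenerates(smallworld):
    res = sweep(smallworld, [0.5], [1], [3], ["genetrank"])
    surf = res.surface("genetrank", 1)
    assert len(surf.frame) == 1
    row = surf.frame.iloc[0]
    assert row["cum_size"] == 3
    assert row["sat"] == pytest.approx(3 / len(smallworld.X))
    assert row["rel_sat"] == pytest.approx(row["sat"] / 3)


def test_sweep_skips_degenerate_r_zero(smallworld):
    res = sweep(
        smallworld, [0.0, 0.4], [1], [3],
        ["genetrank", "genetrank_as", "genetrank_renorm", "pr_affinity"],
    )
    skipped = {(m, r) for m, r, _ in res.skipped}
    assert ("genetrank", 0.0) in skipped
    assert ("genetrank_renorm", 0.0) in skipped
    assert ("pr_affinity", 0.0) in skipped
    # the absorbing-no-renorm contender is defined at r=0 and is kept
    assert ("genetrank_as", 0.0) not in skipped
    assert res.surface("genetrank_as", 1).r_values == (0.4, 0.0)


def test_sweep_processing_orders(smallworld):
    dec = sweep(smallworld, [0.2, 0.6, 0.4], [1], [3], ["genetrank"])
    inc = sweep(smallworld, [0.2, 0.6, 0.4], [1], [3], ["genetrank"],
                order="increasing")
    assert dec.surface("genetrank", 1).r_values == (0.6, 0.4, 0.2)
    assert inc.surface("genetrank", 1).r_values == (0.2, 0.4, 0.6)


def test_sweep_saturation_laws_and_hits(smallworld):
    """Sat non-decreasing along the grid; relative Sat bounded; cumulative
    hits non-decreasing."""
    ref = GeneSet(smallworld.X.ids[::4], "reference")
    ks = [2, 4, 6]
    res = sweep(smallworld, [0.7, 0.5, 0.3, 0.1], [1, 3], ks, ["genetrank"],
                reference=ref)
    X_size = len(smallworld.X)
    for tau in (1, 3):
        surf = res.surface("genetrank", tau).frame
        hits = res.hits[("genetrank", tau)].frame
        n_r = len(res.surface("genetrank", tau).r_values)
        for k in ks:
            sats = surf[surf.k == k]["sat"].to_numpy()
            rels = surf[surf.k == k]["rel_sat"].to_numpy()
            assert (np.diff(sats) >= 0).all()
            ls = np.arange(1, n_r + 1)
            assert (rels <= np.minimum(1 / k, ls / X_size) + 1e-12).all()
            cum = hits[hits.k == k]["cum_hits"].to_numpy()
            assert (np.diff(cum) >= 0).all()


def test_sweep_validates_arguments(smallworld):
    with pytest.raises(ValueError, match="nonempty"):
        sweep(smallworld, [], [1], [3])
    with pytest.raises(ValueError, match="order"):
        sweep(smallworld, [0.5], [1], [3], order="sideways")
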