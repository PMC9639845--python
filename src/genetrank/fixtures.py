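"""Deterministic toy and synthetic instances for testing and examples.

Toy instances have absorption probabilities solvable by hand; the
small-world generator emulates the short-path, high-clustering regime of
real protein interaction networks, with the pathway gene set planted as a
connected induced subgraph and the experimental set sampled from the rest.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np

from .ppin_io import GeneSet, Instance, InteractionNetwork, write_gene_set, write_network_tsv

__all__ = [
    "TOY_NAMES",
    "VALIDATED_REFERENCE",
    "make_toy",
    "make_smallworld_instance",
    "export_instance",
    "reference_gene_list",
]

#: UniProtKB accessions of the experimentally validated TRAIL-sensitivity
#: regulators usable for hit counting: SIVA1, BLOC1S1, PRSS56, SLC25A1,
#: UBE2D4, DNM1L.  (UQCC3/Q6UW78 is excluded: absent from the source network.)
VALIDATED_REFERENCE = ("O15304", "P78537", "P0CW18", "P53007", "Q9Y2X8", "O00429")


def reference_gene_list() -> GeneSet:
    """The bundled reference list of validated genes for hit counting."""
    return GeneSet(VALIDATED_REFERENCE, "validated")


def _undirected(*pairs: tuple[str, str]) -> dict[tuple[str, str], float]:
    return {(u, v): 1.0 for u, v in pairs}


def _toy_path3() -> Instance:
    net = InteractionNetwork(_undirected(("s", "a"), ("a", "t")))
    return Instance(net, GeneSet(("s",), "X"), GeneSet(("t",), "P"))


def _toy_star() -> Instance:
    net = InteractionNetwork(_undirected(("c", "s"), ("c", "t1"), ("c", "t2")))
    return Instance(net, GeneSet(("s",), "X"), GeneSet(("t1", "t2"), "P"))


def _toy_path4() -> Instance:
    net = InteractionNetwork(_undirected(("t1", "s"), ("s", "a"), ("a", "t2")))
    return Instance(net, GeneSet(("s",), "X"), GeneSet(("t1", "t2"), "P"))


def _toy_triangle() -> Instance:
    net = InteractionNetwork(_undirected(("a", "b"), ("b", "c"), ("a", "c")))
    return Instance(net, GeneSet(("a",), "X"), GeneSet(("b", "c"), "P"))


def _toy_fig1_motif() -> Instance:
    """Motif with a subsidiary target and an over-proximal target.

    Sources {s1, s2, s3}; targets {t1..t4}.  Every path from a source to t2
    passes through t1 or t4, so under absorbing targets t2 is never hit;
    t3 is adjacent to all three sources, so its restart-free hitting
    probability is large and renormalization tones it down.
    """
    net = InteractionNetwork(
        _undirected(
            ("s1", "t3"), ("s2", "t3"), ("s3", "t3"),
            ("s1", "t1"), ("s3", "t4"),
            ("t1", "t2"), ("t4", "t2"),
        )
    )
    return Instance(
        net, GeneSet(("s1", "s2", "s3"), "X"), GeneSet(("t1", "t2", "t3", "t4"), "P")
    )


_CATALOG = {
    "path3": _toy_path3,
    "star": _toy_star,
    "path4_two_targets": _toy_path4,
    "triangle": _toy_triangle,
    "fig1_motif": _toy_fig1_motif,
}

TOY_NAMES = tuple(sorted(_CATALOG))


def make_toy(name: str) -> Instance:
    """Build a named toy instance; unknown names list the catalog."""
    try:
        return _CATALOG[name]()
    except KeyError:
        raise ValueError(f"unknown toy {name!r}; available: {TOY_NAMES}") from None


def make_smallworld_instance(
    n: int = 200,
    mean_degree: int = 8,
    rewire_p: float = 0.1,
    x_size: int = 30,
    p_size: int = 8,
    seed: int = 0,
    max_tries: int = 20,
) -> Instance:
    """Seeded small-world instance with a planted pathway.

    A Watts-Strogatz ring lattice with rewiring is generated (largest
    component kept if rewiring disconnects it), vertices are relabeled to
    zero-padded ids, the pathway P is grown as a connected induced subgraph
    by breadth-first search from a random vertex, and X is sampled uniformly
    from the remaining vertices.  Fully determined by the seed.
    """
    if n <= x_size + p_size:
        raise ValueError("need n > x_size + p_size")
    rng = np.random.default_rng(seed)
    for attempt in range(max_tries):
        g_seed = int(rng.integers(0, 2**31 - 1))
        G = nx.watts_strogatz_graph(n, mean_degree, rewire_p, seed=g_seed)
        comps = sorted(nx.connected_components(G), key=len, reverse=True)
        keep = comps[0]
        if len(keep) <= x_size + p_size:
            continue
        break
    else:
        raise RuntimeError("could not generate a usable connected graph")
    return _plant_sets(G, keep, x_size, p_size, rng, n)


def _plant_sets(G, keep, x_size, p_size, rng, n) -> Instance:
    width = len(str(n - 1))
    label = {v: f"G{v:0{width}d}" for v in G.nodes}
    kept = sorted(keep)
    edges = {
        (label[u], label[v]): 1.0
        for u, v in G.edges
        if u in keep and v in keep and u != v
    }
    net = InteractionNetwork(edges)

    # grow P as a connected induced subgraph by BFS from a random start
    start = kept[int(rng.integers(len(kept)))]
    order = list(nx.bfs_tree(G.subgraph(keep), start).nodes)
    p_nodes = sorted(order[:p_size])
    rest = sorted(set(kept) - set(p_nodes))
    x_nodes = sorted(rng.choice(len(rest), size=x_size, replace=False))
    X = GeneSet(tuple(label[rest[i]] for i in x_nodes), "X")
    P = GeneSet(tuple(label[v] for v in p_nodes), "P")
    return Instance(net, X, P)


def export_instance(instance: Instance, out_dir: str | Path, name: str = "instance") -> dict[str, Path]:
    """Write network TSV and gene-set files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": out / f"{name}_network.tsv",
        "X": out / f"{name}_X.txt",
        "P": out / f"{name}_P.txt",
    }
    write_network_tsv(instance.network, paths["network"])
    write_gene_set(instance.X, paths["X"])
    write_gene_set(instance.P, paths["P"])
    return paths
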