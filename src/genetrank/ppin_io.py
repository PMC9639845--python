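"""Reading and preprocessing of protein interaction networks.

Interaction files (MITAB 2.5-style or plain TSV edge lists) are parsed into
raw records, preprocessed into a clean :class:`InteractionNetwork` (self-loops
removed, multi-edges collapsed, largest connected component kept), and gene
sets are restricted to the surviving vertices to form an :class:`Instance`.

Vertices are protein identifiers (typically UniProtKB accessions) kept
verbatim; weights, when given, must lie in (0, 1] and default to 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger("genetrank")

__all__ = [
    "GeneSet",
    "InteractionNetwork",
    "Instance",
    "load_interactions",
    "preprocess_network",
    "make_instance",
    "read_gene_set",
    "write_gene_set",
    "read_vertex_weights",
    "write_network_tsv",
]


@dataclass(frozen=True)
class GeneSet:
    """An ordered collection of unique gene/protein identifiers."""

    ids: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if list(self.ids).count(i) > 1})
            raise ValueError(f"duplicate identifiers in gene set {self.label!r}: {dupes}")
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def __contains__(self, item: str) -> bool:
        return item in set(self.ids)

    @classmethod
    def from_iterable(cls, ids: Iterable[str], label: str = "") -> "GeneSet":
        """Build a gene set preserving first-occurrence order, dropping repeats."""
        seen: dict[str, None] = {}
        for i in ids:
            seen.setdefault(str(i))
        return cls(tuple(seen), label)


class InteractionNetwork:
    """A vertex- and edge-weighted graph after preprocessing.

    Undirected networks store both arc orientations internally so that the
    random-walk machinery is direction-agnostic.  Invariants: no self-loops,
    at most one arc per ordered pair, a single connected component, all
    weights in (0, 1].
    """

    def __init__(
        self,
        edges: dict[tuple[str, str], float],
        vertex_weights: Optional[dict[str, float]] = None,
        directed: bool = False,
    ) -> None:
        verts: set[str] = set()
        for (u, v), w in edges.items():
            if u == v:
                raise ValueError(f"self-loop {u!r} not allowed")
            if not (0.0 < w <= 1.0):
                raise ValueError(f"edge weight {w} for ({u}, {v}) outside (0, 1]")
            verts.update((u, v))
        self.directed = bool(directed)
        self.vertices: tuple[str, ...] = tuple(sorted(verts))
        self._index = {v: i for i, v in enumerate(self.vertices)}
        arcs = dict(edges)
        if not directed:
            for (u, v), w in list(edges.items()):
                other = arcs.setdefault((v, u), w)
                if other != w:
                    raise ValueError(f"asymmetric weights on undirected edge ({u}, {v})")
        self._arcs = arcs
        vw = np.ones(len(self.vertices))
        if vertex_weights:
            for v, w in vertex_weights.items():
                if v in self._index:
                    if not (0.0 < w <= 1.0):
                        raise ValueError(f"vertex weight {w} for {v!r} outside (0, 1]")
                    vw[self._index[v]] = w
        self.vertex_weights = vw
        rows = [self._index[u] for (u, _v) in arcs]
        cols = [self._index[v] for (_u, v) in arcs]
        data = [arcs[(u, v)] for (u, v) in arcs]
        n = len(self.vertices)
        self._adjacency = sp.csr_array((data, (rows, cols)), shape=(n, n))
        if n and not self._connected():
            raise ValueError("network is not connected; preprocess first")

    # -- basic queries -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        """Number of edges (arc pairs counted once for undirected graphs)."""
        return len(self._arcs) if self.directed else len(self._arcs) // 2

    def __contains__(self, vertex: str) -> bool:
        return vertex in self._index

    def index_of(self, vertex: str) -> int:
        return self._index[vertex]

    def indices_of(self, ids: Sequence[str]) -> np.ndarray:
        return np.array([self._index[v] for v in ids], dtype=np.intp)

    def adjacency(self) -> sp.csr_array:
        """Arc-weight matrix in vertex order (copy-safe CSR view)."""
        return self._adjacency

    def out_degree(self, vertex: str) -> int:
        i = self._index[vertex]
        return int(self._adjacency.indptr[i + 1] - self._adjacency.indptr[i])

    def _connected(self) -> bool:
        n_comp = sp.csgraph.connected_components(
            self._adjacency, directed=self.directed, connection="weak",
            return_labels=False,
        )
        return n_comp == 1

    # -- random-walk kernel --------------------------------------------
    def walk_matrix(self, weight_variant: str = "target") -> sp.csr_array:
        """Row-normalized walk matrix over all vertices (no absorbing states).

        ``target`` (default): step u->v proportional to w_uv * w_v.
        ``source``: step u->v proportional to w_uv alone, the edge-weight-only
        normalization that reduces to 1/d(u) on unweighted graphs.
        Rows of vertices with no out-neighbors are left zero (dangling).
        """
        if weight_variant not in ("target", "source"):
            raise ValueError(f"unknown weight variant {weight_variant!r}")
        A = self._adjacency.copy().astype(float)
        if weight_variant == "target":
            A = A @ sp.diags_array(self.vertex_weights)
            A = sp.csr_array(A)
        rowsum = np.asarray(A.sum(axis=1)).ravel()
        inv = np.divide(1.0, rowsum, out=np.zeros_like(rowsum), where=rowsum > 0)
        return sp.csr_array(sp.diags_array(inv) @ A)

    def dangling_indices(self) -> np.ndarray:
        """Vertices with no outgoing arcs (possible only in directed inputs)."""
        deg = np.diff(self._adjacency.indptr)
        return np.flatnonzero(deg == 0)


@dataclass(frozen=True)
class Instance:
    """A (network, X, P) triplet with X and P restricted to the network."""

    network: InteractionNetwork
    X: GeneSet
    P: GeneSet
    dropped_X: GeneSet = field(default_factory=lambda: GeneSet((), "dropped_X"))
    dropped_P: GeneSet = field(default_factory=lambda: GeneSet((), "dropped_P"))

    def __post_init__(self) -> None:
        overlap = set(self.X.ids) & set(self.P.ids)
        if overlap:
            raise ValueError(
                f"X and P overlap (source/target sets must be disjoint): {sorted(overlap)}"
            )
        for gs in (self.X, self.P):
            missing = [g for g in gs.ids if g not in self.network]
            if missing:
                raise ValueError(f"gene(s) not in network: {missing}")


# ---------------------------------------------------------------------------
# File readers
# ---------------------------------------------------------------------------

def _strip_namespace(token: str) -> str:
    # MITAB ids look like "uniprotkb:P12345"; keep the accession verbatim.
    if ":" in token:
        prefix, rest = token.split(":", 1)
        if prefix.lower() == "uniprotkb":
            return rest
    return token


def _mitab_species_match(fields: Sequence[str], species_filter: str) -> bool:
    # Taxid columns (10 and 11, 1-based) look like "taxid:9606(Homo sapiens)".
    want = species_filter.lower()
    if len(fields) < 11:
        return True  # no species info to filter on
    for col in (9, 10):
        cell = fields[col].lower()
        if want in cell:
            continue
        # allow a bare taxid to match "taxid:9606(...)"
        if f"taxid:{want}" in cell:
            continue
        return False
    return True


def load_interactions(
    path: str | Path,
    format: str = "tsv",
    species_filter: Optional[str] = None,
) -> list[tuple[str, str, Optional[float]]]:
    """Parse an interaction file into raw (u, v, weight) records.

    ``tsv``: 2-4 whitespace/tab-separated columns u, v[, edge_weight[, ignored]].
    ``mitab``: tab-separated, interactor accessions taken from columns 1-2,
    species filtering against the taxid columns when requested.
    No deduplication or self-loop filtering happens here.
    """
    path = Path(path)
    if format not in ("tsv", "mitab"):
        raise ValueError(f"unknown format {format!r}")
    records: list[tuple[str, str, Optional[float]]] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if format == "tsv" and len(fields) == 1:
                fields = line.split()
            try:
                if format == "mitab":
                    u, v = _strip_namespace(fields[0]), _strip_namespace(fields[1])
                    if species_filter and not _mitab_species_match(fields, species_filter):
                        continue
                    weight = None
                else:
                    u, v = fields[0], fields[1]
                    weight = float(fields[2]) if len(fields) >= 3 and fields[2] else None
                if not u or not v:
                    raise ValueError("empty identifier")
            except (IndexError, ValueError) as exc:
                skipped += 1
                logger.warning("skipping malformed row %d of %s: %s", lineno, path, exc)
                continue
            records.append((u, v, weight))
    if skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, skipped)
    if not records:
        raise ValueError(f"no usable interaction records in {path}")
    return records


def preprocess_network(
    records: Sequence[tuple[str, str, Optional[float]]],
    directed: bool = False,
    vertex_weights: Optional[dict[str, float]] = None,
) -> InteractionNetwork:
    """Clean raw records into a connected interaction network.

    Self-interactions are removed, parallel records between the same pair are
    collapsed to one edge keeping the maximum weight, and only the largest
    connected component is retained (ties broken by the component holding the
    lexicographically smallest vertex).
    """
    if not records:
        raise ValueError("empty record list")
    n_raw = len(records)
    no_loops = [(u, v, w) for u, v, w in records if u != v]
    collapsed: dict[tuple[str, str], float] = {}
    for u, v, w in no_loops:
        key = (u, v) if directed else (min(u, v), max(u, v))
        w = 1.0 if w is None else float(w)
        collapsed[key] = max(collapsed.get(key, 0.0), w)
    if not collapsed:
        raise ValueError("no edges remain after self-loop removal")

    G: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    for (u, v), w in collapsed.items():
        G.add_edge(u, v, weight=w)
    comps = (
        list(nx.weakly_connected_components(G))
        if directed
        else list(nx.connected_components(G))
    )
    biggest = max(len(c) for c in comps)
    lcc = min(
        (c for c in comps if len(c) == biggest),
        key=lambda c: min(c),
    )
    edges = {
        (u, v): w for (u, v), w in collapsed.items() if u in lcc and v in lcc
    }
    net = InteractionNetwork(edges, vertex_weights=vertex_weights, directed=directed)
    logger.info(
        "preprocess: %d records -> %d after self-loop removal -> %d edges collapsed "
        "-> LCC %d vertices / %d edges",
        n_raw, len(no_loops), len(collapsed), net.n, net.n_edges,
    )
    if net.n == 0:
        raise ValueError("empty network after preprocessing")
    return net


def make_instance(network: InteractionNetwork, X_raw: GeneSet, P_raw: GeneSet) -> Instance:
    """Restrict X and P to the network, recording dropped identifiers."""
    if not len(X_raw) or not len(P_raw):
        raise ValueError("X and P must be nonempty")
    keep_x = [g for g in X_raw.ids if g in network]
    drop_x = [g for g in X_raw.ids if g not in network]
    keep_p = [g for g in P_raw.ids if g in network]
    drop_p = [g for g in P_raw.ids if g not in network]
    if drop_x or drop_p:
        logger.warning(
            "dropped %d gene(s) from X and %d from P absent from the network",
            len(drop_x), len(drop_p),
        )
    if not keep_x:
        raise ValueError(f"X empty after restriction; dropped {drop_x}")
    if not keep_p:
        raise ValueError(f"P empty after restriction; dropped {drop_p}")
    overlap = set(keep_x) & set(keep_p)
    if overlap:
        raise ValueError(f"X and P overlap after restriction: {sorted(overlap)}")
    return Instance(
        network=network,
        X=GeneSet(tuple(keep_x), X_raw.label or "X"),
        P=GeneSet(tuple(keep_p), P_raw.label or "P"),
        dropped_X=GeneSet(tuple(drop_x), "dropped_X"),
        dropped_P=GeneSet(tuple(drop_p), "dropped_P"),
    )


# ---------------------------------------------------------------------------
# Small text formats
# ---------------------------------------------------------------------------

def read_gene_set(path: str | Path, label: str = "") -> GeneSet:
    """Newline-delimited accession list; '#' lines ignored."""
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return GeneSet.from_iterable(ids, label or Path(path).stem)


def write_gene_set(gs: GeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gs.ids))


def read_vertex_weights(path: str | Path) -> dict[str, float]:
    """Two-column TSV: vertex id, weight in (0, 1]."""
    weights: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            vid, w = line.split("\t")[:2]
            weights[vid] = float(w)
    return weights


def write_network_tsv(network: InteractionNetwork, path: str | Path) -> None:
    """3-column TSV export (u, v, weight); undirected pairs written once."""
    with open(path, "w") as fh:
        seen = set()
        for (u, v), w in sorted(network._arcs.items()):
            key = (u, v) if network.directed else (min(u, v), max(u, v))
            if key in seen:
                continue
            seen.add(key)
            fh.write(f"{u}\t{v}\t{w:g}\n")
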