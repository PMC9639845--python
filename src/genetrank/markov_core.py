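"""Absorbing restart Markov chains and hitting-probability solvers.

The walk lives on the interaction network.  Targets T are absorbing states;
at every non-target step the walk either follows an edge (probability 1-r,
split proportionally to edge and vertex weights) or restarts uniformly into
the restart set S' (probability r).  Hitting probabilities of the targets
are obtained by power iteration with an L1 stopping rule, with an exact
linear-system solver as independent oracle.  Hit scores renormalize the
restarted hitting probabilities by the restart-free baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .ppin_io import GeneSet, InteractionNetwork, Instance

__all__ = [
    "SolverOptions",
    "ChainModel",
    "StateDistribution",
    "HitVector",
    "build_transition",
    "add_restart",
    "hit_probabilities",
    "solve_absorption_exact",
    "hit_score",
    "stationary_restart_distribution",
]

#: scores whose baseline hitting probability falls below this are undefined
EPS_DENOMINATOR = 1e-12


@dataclass(frozen=True)
class SolverOptions:
    """Iterative-solver settings shared across the package.

    tol is the L1 distance between successive state vectors below which
    iteration stops; eps_denominator is the zero cutoff for renormalization
    baselines; weight_variant selects the walk kernel (see
    InteractionNetwork.walk_matrix); baseline selects whether the hit-score
    denominator uses one chain started uniformly over the whole source set
    ("uniform") or one chain per source ("per_source").
    """

    tol: float = 1e-6
    max_iter: int = 1_000_000
    eps_denominator: float = EPS_DENOMINATOR
    weight_variant: str = "target"
    baseline: str = "uniform"

    def __post_init__(self) -> None:
        if self.baseline not in ("uniform", "per_source"):
            raise ValueError(f"unknown baseline mode {self.baseline!r}")


@dataclass(frozen=True)
class ChainModel:
    """Transition structure with absorbing targets and optional restart."""

    network: InteractionNetwork
    matrix: sp.csr_array
    targets: GeneSet
    restart_set: Optional[GeneSet] = None
    r: float = 0.0
    dangling: tuple[str, ...] = ()

    @property
    def target_indices(self) -> np.ndarray:
        return self.network.indices_of(self.targets.ids)

    def transient_indices(self) -> np.ndarray:
        mask = np.ones(self.network.n, dtype=bool)
        mask[self.target_indices] = False
        return np.flatnonzero(mask)


@dataclass(frozen=True)
class StateDistribution:
    """Probability vector over network vertices at some iteration step."""

    network: InteractionNetwork
    probabilities: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (self.network.n,):
            raise ValueError("distribution length does not match vertex count")
        if (p < -1e-15).any() or not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("not a probability distribution")
        object.__setattr__(self, "probabilities", p)

    @classmethod
    def uniform_on(cls, network: InteractionNetwork, support: Sequence[str]) -> "StateDistribution":
        p = np.zeros(network.n)
        idx = network.indices_of(list(support))
        p[idx] = 1.0 / len(idx)
        return cls(network, p)

    @classmethod
    def point_mass(cls, network: InteractionNetwork, vertex: str) -> "StateDistribution":
        p = np.zeros(network.n)
        p[network.index_of(vertex)] = 1.0
        return cls(network, p)


@dataclass(frozen=True)
class HitVector:
    """Hitting probabilities of the targets plus solver provenance."""

    targets: tuple[str, ...]
    probabilities: np.ndarray
    r: float = 0.0
    restart_label: str = ""
    tol: float = 0.0
    iterations: int = 0
    converged: bool = True

    def __getitem__(self, target: str) -> float:
        return float(self.probabilities[self.targets.index(target)])

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.targets, map(float, self.probabilities)))

    def to_tsv(self, path) -> None:
        """Two-column export: target id, hitting probability."""
        with open(path, "w") as fh:
            for t, p in self.as_dict().items():
                fh.write(f"{t}\t{p:.12g}\n")


# ---------------------------------------------------------------------------
# Chain construction
# ---------------------------------------------------------------------------

def build_transition(
    network: InteractionNetwork,
    T: GeneSet,
    weight_variant: str = "target",
) -> ChainModel:
    """Restart-free chain: weighted walk off non-targets, identity on targets."""
    missing = [t for t in T.ids if t not in network]
    if missing:
        raise ValueError(f"target(s) not in network: {missing}")
    n = network.n
    W = network.walk_matrix(weight_variant).tolil()
    t_idx = network.indices_of(T.ids)
    for i in t_idx:
        W.rows[i] = [int(i)]
        W.data[i] = [1.0]
    M = sp.csr_array(W.tocsr())
    rowsum = np.asarray(M.sum(axis=1)).ravel()
    dangle_idx = np.flatnonzero(rowsum < 0.5)
    dangling = tuple(network.vertices[i] for i in dangle_idx)
    return ChainModel(network, M, T, None, 0.0, dangling)


def add_restart(model: ChainModel, S_prime: GeneSet, r: float) -> ChainModel:
    """Blend the walk with a uniform restart into S' at rate r.

    Non-target rows are scaled by (1-r) and r/|S'| is added toward every
    vertex of S' (accumulating where an arc already exists); target rows stay
    identity.  Dangling non-target rows send their entire mass to S'.
    """
    if not (0.0 <= r < 1.0):
        raise ValueError(f"restart rate {r} outside [0, 1)")
    if not len(S_prime):
        raise ValueError("restart set is empty")
    overlap = set(S_prime.ids) & set(model.targets.ids)
    if overlap:
        raise ValueError(f"restart set intersects targets: {sorted(overlap)}")
    net = model.network
    n = net.n
    t_idx = model.target_indices
    s_idx = net.indices_of(S_prime.ids)

    M = model.matrix.astype(float).tocsr()
    nontarget = np.ones(n, dtype=bool)
    nontarget[t_idx] = False
    scale = np.where(nontarget, 1.0 - r, 1.0)
    M = sp.csr_array(sp.diags_array(scale) @ M)

    restart_rows = np.flatnonzero(nontarget)
    dangle = net.indices_of(list(model.dangling)) if model.dangling else np.array([], dtype=np.intp)
    add_rows, add_cols, add_vals = [], [], []
    base = r / len(s_idx)
    full = 1.0 / len(s_idx)  # dangling rows restart with probability one
    dangle_set = set(int(i) for i in dangle)
    for i in restart_rows:
        amount = full if int(i) in dangle_set else base
        if amount == 0.0:
            continue
        for j in s_idx:
            add_rows.append(i)
            add_cols.append(j)
            add_vals.append(amount)
    if add_vals:
        M = sp.csr_array(
            M + sp.csr_array((add_vals, (add_rows, add_cols)), shape=(n, n))
        )
    return ChainModel(net, M, model.targets, S_prime, r, model.dangling)


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def hit_probabilities(
    model: ChainModel,
    init: StateDistribution,
    tol: float = 1e-6,
    max_iter: int = 1_000_000,
) -> HitVector:
    """Power-iterate pi <- pi M until converged to tolerance tol.

    Iteration stops once the L1 distance between successive iterates falls
    below tol AND the surviving transient mass is below tol.  The second
    condition is what actually bounds the distance to the limit: for an
    absorbing chain every remaining transient unit eventually lands on some
    target, so the hitting probabilities are within tol of their limits at
    the stopping point, uniformly in the restart rate.  (The step-size
    condition alone can stop arbitrarily far from the limit when restart
    makes absorption slow.)

    Returns the limit restricted to the targets with convergence metadata.
    The init must be supported on non-target vertices.
    """
    t_idx = model.target_indices
    if init.probabilities[t_idx].sum() > 1e-12:
        raise ValueError("initial distribution has mass on targets")
    MT = sp.csr_array(model.matrix.T)
    pi = init.probabilities.copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        nxt = MT @ pi
        transient_mass = 1.0 - nxt[t_idx].sum()
        if np.abs(nxt - pi).sum() < tol and transient_mass < tol:
            pi = nxt
            converged = True
            break
        pi = nxt
    return HitVector(
        targets=model.targets.ids,
        probabilities=pi[t_idx].copy(),
        r=model.r,
        restart_label=",".join(model.restart_set.ids) if model.restart_set else "",
        tol=tol,
        iterations=it,
        converged=converged,
    )


def solve_absorption_exact(model: ChainModel, init: StateDistribution) -> HitVector:
    """Absorption probabilities via the fundamental linear system.

    Solves (I - Q) H = R on the transient states, where Q and R are the
    transient-to-transient and transient-to-target blocks of the chain, then
    weights rows by the initial distribution.  Exact oracle for the iterative
    solver on small graphs.
    """
    t_idx = model.target_indices
    tr_idx = model.transient_indices()
    M = model.matrix.tocsr()
    Q = M[tr_idx][:, tr_idx].toarray()
    R = M[tr_idx][:, t_idx].toarray()
    A = np.eye(len(tr_idx)) - Q
    try:
        H = np.linalg.solve(A, R)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular absorption system: some initial mass can never reach a target"
        ) from exc
    cond = np.linalg.cond(A)
    if cond > 1e12:
        raise ValueError(
            "near-singular absorption system: some initial mass can never reach a target"
        )
    p0 = init.probabilities
    probs = p0[tr_idx] @ H + p0[t_idx]
    return HitVector(
        targets=model.targets.ids,
        probabilities=probs,
        r=model.r,
        restart_label=",".join(model.restart_set.ids) if model.restart_set else "",
        tol=0.0,
        iterations=0,
        converged=True,
    )


def hit_score(
    instance: Instance,
    s: str,
    r: float,
    options: SolverOptions = SolverOptions(),
    direction: str = "X_to_P",
) -> dict[str, float]:
    """Renormalized hit scores Q(s, t) from one source to every target.

    The numerator is the hitting probability under the chain restarted at {s}
    with rate r started from s; the denominator is the restart-free hitting
    probability started uniformly over the full source set (or from s alone
    in per-source baseline mode).  Targets with (near-)zero baseline give NaN.
    """
    S, T = _direction_sets(instance, direction)
    if s not in set(S.ids):
        raise ValueError(f"source {s!r} not in the {direction} source set")
    base = build_transition(instance.network, T, options.weight_variant)
    restart_chain = add_restart(base, GeneSet((s,), "S'"), r)
    num = hit_probabilities(
        restart_chain,
        StateDistribution.point_mass(instance.network, s),
        options.tol,
        options.max_iter,
    )
    den_support = S.ids if options.baseline == "uniform" else (s,)
    den = hit_probabilities(
        base,
        StateDistribution.uniform_on(instance.network, den_support),
        options.tol,
        options.max_iter,
    )
    scores: dict[str, float] = {}
    defined = 0
    for t, p_num, p_den in zip(T.ids, num.probabilities, den.probabilities):
        if p_den < options.eps_denominator:
            scores[t] = float("nan")
        else:
            scores[t] = float(p_num / p_den)
            defined += 1
    if defined == 0:
        raise ValueError(
            f"all baseline hitting probabilities vanish for direction {direction}; "
            "instance unusable in this direction"
        )
    return scores


def stationary_restart_distribution(
    network: InteractionNetwork,
    S_prime: GeneSet,
    r: float,
    tol: float = 1e-6,
    max_iter: int = 1_000_000,
    weight_variant: str = "target",
) -> StateDistribution:
    """Stationary distribution of the non-absorbing restart walk.

    Solves pi = (1-r) pi W + r u_{S'} by fixed-point iteration.  At r = 0 the
    plain walk's stationary distribution is computed via the lazy chain
    (I + W)/2, which shares its stationary distribution and always converges
    on connected graphs; on undirected unweighted graphs this is the
    degree-proportional distribution.
    """
    if not (0.0 <= r < 1.0):
        raise ValueError(f"restart rate {r} outside [0, 1)")
    W = network.walk_matrix(weight_variant)
    WT = sp.csr_array(W.T)
    n = network.n
    u = np.zeros(n)
    s_idx = network.indices_of(S_prime.ids)
    u[s_idx] = 1.0 / len(s_idx)
    dangle = network.dangling_indices()
    pi = u.copy() if r > 0 else np.full(n, 1.0 / n)
    converged = False
    for _ in range(max_iter):
        step = WT @ pi
        if dangle.size:
            step = step + pi[dangle].sum() * u  # dangling rows restart fully
        if r > 0:
            nxt = (1.0 - r) * step + r * u
        else:
            nxt = 0.5 * pi + 0.5 * step  # lazy walk, same stationary vector
        if np.abs(nxt - pi).sum() < tol:
            pi = nxt
            converged = True
            break
        pi = nxt
    if not converged:
        raise RuntimeError("stationary iteration did not converge")
    pi = np.maximum(pi, 0.0)
    pi /= pi.sum()
    return StateDistribution(network, pi)


# ---------------------------------------------------------------------------
# Batched engines (vectorized across sources; used by the scoring layer)
# ---------------------------------------------------------------------------

def _direction_sets(instance: Instance, direction: str) -> tuple[GeneSet, GeneSet]:
    if direction == "X_to_P":
        return instance.X, instance.P
    if direction == "P_to_X":
        return instance.P, instance.X
    raise ValueError(f"unknown direction {direction!r}")


def _absorption_blocks(
    network: InteractionNetwork, target_idx: np.ndarray, weight_variant: str
) -> tuple[np.ndarray, np.ndarray, sp.csc_array, np.ndarray, np.ndarray]:
    """Transient-state blocks of the absorbing walk.

    Returns (transient indices, position-in-transient lookup, Q transient->
    transient, R transient->target dense, per-row walk mass).
    """
    n = network.n
    t_mask = np.zeros(n, dtype=bool)
    t_mask[target_idx] = True
    tr_idx = np.flatnonzero(~t_mask)
    pos = -np.ones(n, dtype=np.intp)
    pos[tr_idx] = np.arange(len(tr_idx))
    W_tr = sp.csr_array(network.walk_matrix(weight_variant)[tr_idx])
    Q = sp.csc_array(W_tr[:, tr_idx])
    R = W_tr[:, target_idx].toarray()
    walk_out = np.asarray(W_tr.sum(axis=1)).ravel()  # < 1 only on dangling rows
    return tr_idx, pos, Q, R, walk_out


def batch_absorption(
    network: InteractionNetwork,
    source_idx: np.ndarray,
    target_idx: np.ndarray,
    r: float,
    options: SolverOptions = SolverOptions(),
) -> tuple[np.ndarray, int, bool]:
    """Hitting probabilities for every per-source restart chain at once.

    Row i holds the target hitting probabilities of the chain restarted at
    source_idx[i] (rate r) started from that source.  Each such chain differs
    from the restart-free chain by a rank-1 update (all restart mass flows
    into one column), so a single sparse LU factorization of I - (1-r)Q
    serves every source through the Sherman-Morrison identity:
    h_s = Z[s] / (1 - y[s]) with Z = B^-1 (1-r) R and y = B^-1 c, where c is
    the per-row restart mass.  Sources whose restart component cannot reach
    any target (1 - y[s] ~ 0) get a zero row.

    Returns the (m x |T|) array plus (0, True) placeholder metadata kept for
    interface parity with the iterative solvers.
    """
    t_mask = np.zeros(network.n, dtype=bool)
    t_mask[target_idx] = True
    if t_mask[source_idx].any():
        raise ValueError("sources must be disjoint from targets")
    tr_idx, pos, Q, R, walk_out = _absorption_blocks(
        network, target_idx, options.weight_variant
    )
    n_tr = len(tr_idx)
    B = sp.csc_matrix(sp.eye_array(n_tr, format="csc") - (1.0 - r) * Q)
    try:
        lu = spla.splu(B)
    except RuntimeError as exc:
        raise ValueError(
            "singular absorption system: no target reachable from part of the network"
        ) from exc
    Z = lu.solve((1.0 - r) * R)
    # restart mass per transient row: r, plus the whole walk deficit of
    # dangling rows (their entire remaining mass restarts)
    c = r + (1.0 - r) * (1.0 - walk_out)
    y = lu.solve(c) if c.any() else np.zeros(n_tr)
    s_pos = pos[source_idx]
    denom = 1.0 - y[s_pos]
    H = np.zeros((len(source_idx), len(target_idx)))
    ok = denom > 1e-9
    H[ok] = Z[s_pos[ok]] / denom[ok, None]
    return H, 0, True


def uniform_absorption(
    network: InteractionNetwork,
    source_ids: Sequence[str],
    target_ids: Sequence[str],
    options: SolverOptions = SolverOptions(),
) -> np.ndarray:
    """Restart-free hitting probabilities from the uniform-over-S start.

    Solves the transposed fundamental system once: h = p0' (I - Q)^-1 R with
    p0 uniform on the source set.
    """
    s_idx = network.indices_of(list(source_ids))
    t_idx = network.indices_of(list(target_ids))
    tr_idx, pos, Q, R, _walk_out = _absorption_blocks(
        network, t_idx, options.weight_variant
    )
    n_tr = len(tr_idx)
    if np.isin(s_idx, t_idx).any():
        raise ValueError("sources must be disjoint from targets")
    p0 = np.zeros(n_tr)
    p0[pos[s_idx]] = 1.0 / len(s_idx)
    B = sp.csc_matrix(sp.eye_array(n_tr, format="csc") - Q)
    try:
        x = spla.splu(B.T.tocsc()).solve(p0)
    except RuntimeError as exc:
        raise ValueError(
            "singular absorption system: no target reachable from part of the network"
        ) from exc
    return x @ R


def batch_personalized_stationary(
    network: InteractionNetwork,
    source_idx: np.ndarray,
    r: float,
    options: SolverOptions = SolverOptions(),
) -> np.ndarray:
    """Personalized stationary distributions, one restart chain per source.

    Row i is the stationary distribution of the non-absorbing walk restarted
    at source_idx[i] with rate r > 0.  Since all restart (and dangling) mass
    of chain s flows into column s, pi_s is proportional to row s of
    (I - (1-r)W)^-1; one LU factorization of the transpose serves every
    source, each row normalized to total mass one.
    """
    if not (0.0 < r < 1.0):
        raise ValueError("batched personalized stationary requires r in (0, 1)")
    n = network.n
    W = network.walk_matrix(options.weight_variant)
    B = sp.csc_matrix(sp.eye_array(n, format="csc") - (1.0 - r) * sp.csc_array(W))
    lu = spla.splu(B.T.tocsc())
    E = np.zeros((n, len(source_idx)))
    E[source_idx, np.arange(len(source_idx))] = 1.0
    X = lu.solve(E).T  # row i = e_{s_i} B^{-1}
    return X / X.sum(axis=1, keepdims=True)
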