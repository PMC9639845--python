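"""Gene rankings, saturation indices over a restart-rate filtration, hits.

From the bidirectional score tables, each experimental gene x receives the
arithmetic mean of its top-tau values of max(log Q(x,p), log Q(p,x)) over
pathway genes p.  Sweeping the restart rate and accumulating the top-k gene
sets along the grid yields a filtration whose saturation index (fraction of
X discovered so far) and relative saturation (saturation / k) quantify how
progressively the network is explored.  Hits count the overlap of top-k sets
with a reference list of validated genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import scoring
from .markov_core import SolverOptions, stationary_restart_distribution, uniform_absorption
from .ppin_io import GeneSet, Instance
from .scoring import METHODS, ScoreTable

logger = logging.getLogger("genetrank")

__all__ = [
    "RankedGeneList",
    "SaturationSurface",
    "HitReport",
    "SweepResult",
    "average_scores",
    "top_k",
    "cumulative_sets",
    "saturation",
    "count_hits",
    "contender_score",
    "sweep",
]


@dataclass(frozen=True)
class RankedGeneList:
    """Genes of X ordered by their top-tau average max-log-score."""

    tau: int
    r: float
    method: str
    frame: pd.DataFrame  # gene, avg_score, n_defined, rank (sorted by rank)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.frame["gene"])

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out.insert(1, "tau", self.tau)
        out.insert(2, "r", self.r)
        out.to_csv(path, sep="\t", index=False)


def average_scores(fwd: ScoreTable, rev: ScoreTable, tau: int) -> RankedGeneList:
    """Rank sources by the mean of their top-tau max-of-both-directions logs.

    For each source x, m(x, p) = max(log Q(x, p), log Q(p, x)) over targets p
    with at least one side defined; the tau largest m-values are averaged.
    Sources with no defined target are excluded (warned).  Ties in the
    average are broken by gene id, ascending.
    """
    scoring._check_aligned(fwd, rev)
    n_targets = len(fwd.targets)
    if not (1 <= tau <= n_targets):
        raise ValueError(f"tau={tau} outside [1, {n_targets}]")
    m = np.fmax(fwd.log_scores, rev.log_scores.T)  # NaN only if both undefined
    rows = []
    short = 0
    for i, gene in enumerate(fwd.sources):
        vals = m[i][~np.isnan(m[i])]
        if vals.size == 0:
            logger.warning("gene %s has no defined pair score; excluded", gene)
            continue
        if vals.size < tau:
            short += 1
        top = np.sort(vals)[::-1][:tau]
        rows.append({"gene": gene, "avg_score": float(top.mean()), "n_defined": int(vals.size)})
    if short:
        logger.info("%d gene(s) had fewer than tau=%d defined values", short, tau)
    if not rows:
        raise ValueError("no gene has a defined score")
    frame = pd.DataFrame(rows).sort_values(
        ["avg_score", "gene"], ascending=[False, True], kind="mergesort"
    )
    frame["rank"] = np.arange(1, len(frame) + 1)
    return RankedGeneList(tau, fwd.r, fwd.method, frame.reset_index(drop=True))


def top_k(ranking: RankedGeneList, k: int) -> GeneSet:
    """The first k genes of the ranking (all of them if fewer exist)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return GeneSet(ranking.genes[:k], f"top{k}")


def cumulative_sets(rankings: Sequence[RankedGeneList], k: int) -> list[GeneSet]:
    """Running unions of top-k sets along the given processing order."""
    acc: dict[str, None] = {}
    out = []
    for rk in rankings:
        for g in top_k(rk, k).ids:
            acc.setdefault(g)
        out.append(GeneSet(tuple(sorted(acc)), f"cum_top{k}"))
    return out


def saturation(cumulative: GeneSet, X_size: int, k: int) -> tuple[float, float]:
    """(saturation, relative saturation) of one cumulative gene set."""
    if X_size < 1 or k < 1:
        raise ValueError("X_size and k must be >= 1")
    sat = len(cumulative) / X_size
    return sat, sat / k


def count_hits(top_set: GeneSet, reference: GeneSet) -> int:
    """Number of reference genes present in the given set."""
    return len(set(top_set.ids) & set(reference.ids))


def contender_score(
    instance: Instance,
    direction: str,
    r: float,
    method: str,
    options: SolverOptions = SolverOptions(),
) -> ScoreTable:
    """Score table under one of the four scoring methods.

    genetrank: restart + absorbing targets + renormalization by the
    restart-free baseline. genetrank_as: the raw absorbing hitting
    probabilities (no renormalization). genetrank_renorm: personalized
    restart stationary value renormalized by the plain-walk stationary value
    (no absorption). pr_affinity: min of the two personalized PageRank
    values (no absorption, no renormalization; symmetric).
    """
    return scoring.score_matrix(instance, direction, r, method, options)


# ---------------------------------------------------------------------------
# Restart-rate sweep
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaturationSurface:
    """Saturation and relative saturation on the (r, k) grid for one tau."""

    method: str
    tau: int
    order: str
    r_values: tuple[float, ...]  # in processing order
    ks: tuple[int, ...]
    frame: pd.DataFrame  # tau, k, r, cum_size, sat, rel_sat
    cumulative: dict[int, list[GeneSet]]  # per k, nested along the grid

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class HitReport:
    """Per-(r, k) and cumulative hit counts against a reference list."""

    method: str
    tau: int
    reference: GeneSet
    frame: pd.DataFrame  # tau, k, r, hits, cum_hits

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SweepResult:
    """All rankings, surfaces and hit reports of a restart-rate sweep."""

    order: str
    r_values: tuple[float, ...]
    surfaces: dict[tuple[str, int], SaturationSurface]
    hits: dict[tuple[str, int], HitReport]
    skipped: tuple[tuple[str, float, str], ...]
    failures: tuple[tuple[str, float, str], ...]

    def surface(self, method: str, tau: int) -> SaturationSurface:
        return self.surfaces[(method, tau)]


def _method_skips_r(method: str, r: float, include_r0_genetrank: bool) -> Optional[str]:
    if r == 0.0:
        if method == "genetrank" and not include_r0_genetrank:
            return "score degenerates at r=0 (numerator equals a restart-free chain)"
        if method in ("genetrank_renorm", "pr_affinity"):
            return "method needs r > 0"
    return None


def sweep(
    instance: Instance,
    r_grid: Sequence[float],
    taus: Sequence[int],
    ks: Sequence[int],
    methods: Sequence[str] = ("genetrank",),
    reference: Optional[GeneSet] = None,
    order: str = "decreasing",
    options: SolverOptions = SolverOptions(),
    include_r0_genetrank: bool = False,
) -> SweepResult:
    """Full filtration: score both directions at every r, rank, accumulate.

    The grid is processed in the declared order (default decreasing, which
    zooms out from the immediate vicinity of the sources).  Per-r failures
    are recorded and the sweep continues.
    """
    if not len(r_grid) or not len(taus) or not len(ks):
        raise ValueError("r grid, tau list and k list must be nonempty")
    if order not in ("decreasing", "increasing"):
        raise ValueError("order must be 'decreasing' or 'increasing'")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    r_values = tuple(sorted(set(float(r) for r in r_grid), reverse=(order == "decreasing")))
    net = instance.network
    X, P = instance.X, instance.P

    # Renormalization baselines are r-independent; compute them once.
    baselines: dict[tuple[str, str], np.ndarray] = {}
    for method in methods:
        if method == "genetrank":
            baselines[(method, "X_to_P")] = uniform_absorption(net, X.ids, P.ids, options)
            baselines[(method, "P_to_X")] = uniform_absorption(net, P.ids, X.ids, options)
        elif method == "genetrank_renorm":
            pi0 = stationary_restart_distribution(
                net, X, 0.0, options.tol, options.max_iter, options.weight_variant
            ).probabilities
            baselines[(method, "X_to_P")] = pi0
            baselines[(method, "P_to_X")] = pi0

    rankings: dict[tuple[str, int], list[RankedGeneList]] = {
        (m, t): [] for m in methods for t in taus
    }
    used_r: dict[str, list[float]] = {m: [] for m in methods}
    skipped: list[tuple[str, float, str]] = []
    failures: list[tuple[str, float, str]] = []

    for r in r_values:
        for method in methods:
            why = _method_skips_r(method, r, include_r0_genetrank)
            if why:
                skipped.append((method, r, why))
                logger.info("skipping %s at r=%g: %s", method, r, why)
                continue
            try:
                fwd = scoring.score_matrix(
                    instance, "X_to_P", r, method, options,
                    baseline=baselines.get((method, "X_to_P")),
                )
                if method == "pr_affinity":
                    rev = fwd.transposed()
                else:
                    rev = scoring.score_matrix(
                        instance, "P_to_X", r, method, options,
                        baseline=baselines.get((method, "P_to_X")),
                    )
                for tau in taus:
                    rankings[(method, tau)].append(average_scores(fwd, rev, tau))
            except (ValueError, RuntimeError) as exc:
                failures.append((method, r, str(exc)))
                logger.warning("sweep failure for %s at r=%g: %s", method, r, exc)
                continue
            used_r[method].append(r)

    surfaces: dict[tuple[str, int], SaturationSurface] = {}
    hit_reports: dict[tuple[str, int], HitReport] = {}
    for method in methods:
        for tau in taus:
            rks = rankings[(method, tau)]
            if not rks:
                continue
            rows, hit_rows = [], []
            cum_by_k: dict[int, list[GeneSet]] = {}
            for k in ks:
                cums = cumulative_sets(rks, k)
                cum_by_k[int(k)] = cums
                for rk, cum in zip(rks, cums):
                    sat, rel = saturation(cum, len(X), k)
                    rows.append(
                        {
                            "tau": tau, "k": int(k), "r": rk.r,
                            "cum_size": len(cum), "sat": sat, "rel_sat": rel,
                        }
                    )
                    if reference is not None:
                        hit_rows.append(
                            {
                                "tau": tau, "k": int(k), "r": rk.r,
                                "hits": count_hits(top_k(rk, k), reference),
                                "cum_hits": count_hits(cum, reference),
                            }
                        )
            surfaces[(method, tau)] = SaturationSurface(
                method, tau, order, tuple(used_r[method]), tuple(int(k) for k in ks),
                pd.DataFrame(rows), cum_by_k,
            )
            if reference is not None:
                hit_reports[(method, tau)] = HitReport(
                    method, tau, reference, pd.DataFrame(hit_rows)
                )
    if failures:
        logger.warning("sweep finished with %d failure(s)", len(failures))
    return SweepResult(
        order, r_values, surfaces, hit_reports, tuple(skipped), tuple(failures)
    )
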