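"""Bidirectional score tables, pair ranks and symmetry diagnostics.

A score table holds one score per (source, target) pair for one direction
(X to P, or P to X), one restart rate and one scoring method.  Four methods
are available: the full hit score (restart + absorbing targets +
renormalization by the restart-free baseline) and three ablations that drop
renormalization, absorption, or both (the latter being the symmetric
minimum-personalized-PageRank affinity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .markov_core import (
    SolverOptions,
    batch_absorption,
    batch_personalized_stationary,
    stationary_restart_distribution,
    uniform_absorption,
    _direction_sets,
)
from .ppin_io import GeneSet, Instance

logger = logging.getLogger("genetrank")

__all__ = [
    "METHODS",
    "ScoreTable",
    "SymmetryReport",
    "score_matrix",
    "log_symmetry_ratio",
    "instance_symmetry",
    "subset_symmetry_distribution",
    "pair_ranks",
]

METHODS = ("genetrank", "genetrank_as", "genetrank_renorm", "pr_affinity")


@dataclass(frozen=True)
class ScoreTable:
    """Scores, log scores and pair ranks for one direction at one r."""

    direction: str
    r: float
    method: str
    sources: tuple[str, ...]
    targets: tuple[str, ...]
    scores: np.ndarray  # (|S| x |T|), NaN where undefined

    @property
    def log_scores(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(self.scores)

    @property
    def ranks(self) -> np.ndarray:
        return pair_ranks(self.scores)

    def score(self, s: str, t: str) -> float:
        return float(self.scores[self.sources.index(s), self.targets.index(t)])

    def n_undefined(self) -> int:
        return int(np.isnan(self.scores).sum())

    def frame(self) -> pd.DataFrame:
        """Long-format table: source, target, direction, r, method, score,
        log_score, rank."""
        S, T = np.meshgrid(
            np.arange(len(self.sources)), np.arange(len(self.targets)), indexing="ij"
        )
        return pd.DataFrame(
            {
                "source": [self.sources[i] for i in S.ravel()],
                "target": [self.targets[j] for j in T.ravel()],
                "direction": self.direction,
                "r": self.r,
                "method": self.method,
                "score": self.scores.ravel(),
                "log_score": self.log_scores.ravel(),
                "rank": self.ranks.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.frame().to_csv(path, sep="\t", index=False)

    def transposed(self) -> "ScoreTable":
        """Swap sources and targets, keeping values (for symmetric methods)."""
        other = "P_to_X" if self.direction == "X_to_P" else "X_to_P"
        return ScoreTable(
            other, self.r, self.method, self.targets, self.sources, self.scores.T.copy()
        )


def pair_ranks(scores: np.ndarray) -> np.ndarray:
    """Rank of each pair: 1 + number of strictly greater defined scores.

    Ties share the smallest applicable rank; NaN entries get NaN ranks and do
    not count toward anyone's rank.
    """
    flat = scores.ravel()
    out = np.full(flat.shape, np.nan)
    defined = ~np.isnan(flat)
    vals = flat[defined]
    if vals.size:
        order = np.sort(vals)[::-1]
        # number strictly greater = index of first occurrence in desc order
        out[defined] = 1 + (order[None, :] > vals[:, None]).sum(axis=1)
    return out.reshape(scores.shape)


# ---------------------------------------------------------------------------
# Score computation
# ---------------------------------------------------------------------------

def score_matrix(
    instance: Instance,
    direction: str,
    r: float,
    method: str = "genetrank",
    options: SolverOptions = SolverOptions(),
    baseline: Optional[np.ndarray] = None,
) -> ScoreTable:
    """Compute the (|S| x |T|) score table for one direction and one r.

    ``baseline`` optionally injects a precomputed renormalization vector (the
    restart-free hitting probabilities over targets for ``genetrank``, the
    plain-walk stationary distribution over all vertices for
    ``genetrank_renorm``) so sweeps can reuse it across r values.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    S, T = _direction_sets(instance, direction)
    net = instance.network
    s_idx = net.indices_of(S.ids)
    t_idx = net.indices_of(T.ids)

    if method in ("genetrank", "genetrank_as"):
        num, _, converged = batch_absorption(net, s_idx, t_idx, r, options)
        if not converged:
            logger.warning("absorption iteration hit max_iter at r=%g", r)
        if method == "genetrank_as":
            scores = num
        else:
            if baseline is None:
                if options.baseline == "uniform":
                    baseline = uniform_absorption(net, S.ids, T.ids, options)
                else:
                    baseline, _, _ = batch_absorption(net, s_idx, t_idx, 0.0, options)
            den = np.broadcast_to(np.asarray(baseline, dtype=float), num.shape)
            with np.errstate(divide="ignore", invalid="ignore"):
                scores = np.where(den >= options.eps_denominator, num / den, np.nan)
            if np.isnan(scores).all():
                raise ValueError(
                    f"all baseline hitting probabilities vanish ({direction}); "
                    "instance unusable in this direction"
                )
    elif method == "genetrank_renorm":
        if r <= 0:
            raise ValueError("genetrank_renorm needs r > 0 for a non-trivial score")
        ppr = batch_personalized_stationary(net, s_idx, r, options)
        if baseline is None:
            baseline = stationary_restart_distribution(
                net, S, 0.0, options.tol, options.max_iter, options.weight_variant
            ).probabilities
        den = np.asarray(baseline, dtype=float)[t_idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            scores = np.where(
                den[None, :] >= options.eps_denominator, ppr[:, t_idx] / den[None, :], np.nan
            )
    else:  # pr_affinity
        if r <= 0:
            raise ValueError("pr_affinity needs r > 0 for a non-trivial score")
        ppr_s = batch_personalized_stationary(net, s_idx, r, options)
        ppr_t = batch_personalized_stationary(net, t_idx, r, options)
        scores = np.minimum(ppr_s[:, t_idx], ppr_t[:, s_idx].T)

    n_undef = int(np.isnan(scores).sum())
    if n_undef:
        logger.info(
            "%s %s r=%g: %d undefined pair score(s)", method, direction, r, n_undef
        )
    return ScoreTable(direction, r, method, S.ids, T.ids, np.asarray(scores, dtype=float))


# ---------------------------------------------------------------------------
# Symmetry diagnostics
# ---------------------------------------------------------------------------

def log_symmetry_ratio(log_q_fwd: float, log_q_rev: float) -> float:
    """min/max ratio of the two log scores; NaN when undefined or max is 0.

    Values above 1 arise when both log scores are negative and are reported
    raw (flagged downstream); 1 means perfect symmetry.
    """
    if not np.isfinite(log_q_fwd) or not np.isfinite(log_q_rev):
        return float("nan")
    hi = max(log_q_fwd, log_q_rev)
    if hi == 0.0:
        return float("nan")
    return min(log_q_fwd, log_q_rev) / hi


def instance_symmetry(fwd: ScoreTable, rev: ScoreTable) -> float:
    """Fraction of pairs whose forward score strictly beats the reverse one.

    Both tables must cover the same pairs at the same r; pairs undefined in
    either direction are excluded from the denominator (count logged).
    """
    _check_aligned(fwd, rev)
    q_fwd = fwd.scores
    q_rev = rev.scores.T
    defined = ~np.isnan(q_fwd) & ~np.isnan(q_rev)
    n_def = int(defined.sum())
    if n_def == 0:
        raise ValueError("no pair is defined in both directions")
    n_total = q_fwd.size
    if n_def < n_total:
        logger.info(
            "instance symmetry over %d/%d defined pairs", n_def, n_total
        )
    wins = int((q_fwd[defined] > q_rev[defined]).sum())
    return wins / n_def


def _check_aligned(fwd: ScoreTable, rev: ScoreTable) -> None:
    if fwd.sources != rev.targets or fwd.targets != rev.sources:
        raise ValueError("tables do not cover the same source/target pairs")
    if fwd.r != rev.r:
        raise ValueError("tables computed at different restart rates")


@dataclass(frozen=True)
class SymmetryReport:
    """Per-pair log-score ratios, instance-level symmetry, and the symmetry
    distribution over random source subsets."""

    pairs: pd.DataFrame  # source, target, log_fwd, log_rev, R_log, flagged
    H: float
    subsets: pd.DataFrame  # size, replicate, H
    n_rep: int
    seed: int
    r: float
    method: str

    def summary(self) -> pd.DataFrame:
        g = self.subsets.groupby("size")["H"]
        return g.agg(["mean", "std", "min", "median", "max"]).reset_index()

    def to_tsv(self, path) -> None:
        self.subsets.to_csv(path, sep="\t", index=False)


def pair_ratio_frame(fwd: ScoreTable, rev: ScoreTable) -> pd.DataFrame:
    """Long table of per-pair log scores and their min/max ratio.

    Rows are flagged when the ratio leaves [0, 1] (opposite signs or both
    logs negative), a regime with no agreed interpretation.
    """
    _check_aligned(fwd, rev)
    lf = fwd.log_scores
    lr = rev.log_scores.T
    rows = []
    for i, s in enumerate(fwd.sources):
        for j, t in enumerate(fwd.targets):
            ratio = log_symmetry_ratio(lf[i, j], lr[i, j])
            rows.append(
                {
                    "source": s,
                    "target": t,
                    "log_fwd": lf[i, j],
                    "log_rev": lr[i, j],
                    "R_log": ratio,
                    "flagged": bool(np.isfinite(ratio) and not (0.0 <= ratio <= 1.0)),
                }
            )
    return pd.DataFrame(rows)


def subset_symmetry_distribution(
    instance: Instance,
    sizes: Optional[Sequence[int]] = None,
    n_rep: int = 1000,
    seed: int = 0,
    r: float = 0.5,
    method: str = "genetrank",
    options: SolverOptions = SolverOptions(),
) -> SymmetryReport:
    """Symmetry H over random source subsets of each requested size.

    For each size s, draws n_rep uniform subsets X' of X without replacement
    (one seeded generator for the whole run) and computes the instance
    symmetry of (network, X', P).  Default sizes mirror the study design:
    {|P|, 110, 220} (clipped to |X|), with 1000 replicates.
    """
    if sizes is None:
        sizes = [s for s in (len(instance.P), 110, 220) if s <= len(instance.X)]
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    for s in sizes:
        if s > len(instance.X):
            raise ValueError(f"subset size {s} exceeds |X| = {len(instance.X)}")
        if s < 1:
            raise ValueError("subset sizes must be >= 1")
    rng = np.random.default_rng(seed)
    x_ids = np.array(instance.X.ids)

    fwd = score_matrix(instance, "X_to_P", r, method, options)
    rev = score_matrix(instance, "P_to_X", r, method, options)
    H_full = instance_symmetry(fwd, rev)
    pairs = pair_ratio_frame(fwd, rev)

    records = []
    for size in sizes:
        for rep in range(n_rep):
            chosen = rng.choice(len(x_ids), size=size, replace=False)
            sub_ids = tuple(x_ids[np.sort(chosen)])
            sub = Instance(
                network=instance.network,
                X=GeneSet(sub_ids, "X'"),
                P=instance.P,
            )
            f = score_matrix(sub, "X_to_P", r, method, options)
            b = score_matrix(sub, "P_to_X", r, method, options)
            records.append({"size": size, "replicate": rep, "H": instance_symmetry(f, b)})
    subsets = pd.DataFrame(records, columns=["size", "replicate", "H"])
    return SymmetryReport(pairs, H_full, subsets, n_rep, seed, r, method)
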