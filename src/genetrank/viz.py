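"""Score radar plots and their assembly into a radar MA plot.

Each experimental gene gets a polar "radar": one spoke per top-scoring
pathway gene, carrying the log scores of both walk directions, on a
background colored by the gene's largest log score.  Radars can be placed
at the gene's (LogCount, LogFoldChange) coordinates to build a composite
MA-plot view of the whole gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .scoring import ScoreTable, _check_aligned

logger = logging.getLogger("genetrank")

__all__ = ["RadarSpec", "RadarStyle", "build_radar_spec", "render_radar",
           "render_radar_ma", "read_ma_table", "attach_ma_coordinates"]

# a fixed hash salt makes matplotlib's SVG ids reproducible
matplotlib.rcParams["svg.hashsalt"] = "genetrank"


@dataclass(frozen=True)
class RadarSpec:
    """Everything needed to draw one gene's score radar."""

    gene: str
    spokes: tuple[str, ...]
    fwd_log: np.ndarray  # log Q(x, p) per spoke, NaN where undefined
    rev_log: np.ndarray  # log Q(p, x) per spoke
    background: float  # largest finite log score over both series
    interval: tuple[float, float]  # observed finite log-score range
    ma: Optional[tuple[float, float]] = None  # (LogCount, LogFoldChange)

    @property
    def title(self) -> str:
        lo, hi = self.interval
        return f"{self.gene} [{lo:.2f}, {hi:.2f}]"


@dataclass(frozen=True)
class RadarStyle:
    figsize: tuple[float, float] = (3.0, 3.0)
    cmap: str = "YlOrRd"
    vmin: Optional[float] = None  # background color scale; per-spec if None
    vmax: Optional[float] = None
    fwd_color: str = "tab:green"
    rev_color: str = "tab:blue"
    dpi: int = 100
    radar_frac: float = 0.08  # radar size as a fraction of the MA figure


def build_radar_spec(gene: str, fwd: ScoreTable, rev: ScoreTable, k: int = 5) -> RadarSpec:
    """Pick the gene's top-k targets by two-direction max log score.

    Spokes are ordered by descending max score, ties broken by target id.
    Fewer than k spokes are used (and logged) when the gene has fewer
    defined targets.
    """
    _check_aligned(fwd, rev)
    if gene not in fwd.sources:
        raise ValueError(f"gene {gene!r} not in the score table sources")
    if k < 1:
        raise ValueError("k must be >= 1")
    i = fwd.sources.index(gene)
    lf = fwd.log_scores[i]
    lr = rev.log_scores.T[i]
    m = np.fmax(lf, lr)
    defined = np.flatnonzero(~np.isnan(m))
    if defined.size == 0:
        raise ValueError(f"gene {gene!r} has no defined score")
    if defined.size < k:
        logger.info("gene %s: only %d defined target(s) for k=%d", gene, defined.size, k)
    order = sorted(defined, key=lambda j: (-m[j], fwd.targets[j]))[:k]
    spokes = tuple(fwd.targets[j] for j in order)
    fl = np.array([lf[j] for j in order])
    rl = np.array([lr[j] for j in order])
    finite = np.concatenate([fl[np.isfinite(fl)], rl[np.isfinite(rl)]])
    if finite.size == 0:
        raise ValueError(f"gene {gene!r} has no finite log score")
    return RadarSpec(
        gene=gene,
        spokes=spokes,
        fwd_log=fl,
        rev_log=rl,
        background=float(finite.max()),
        interval=(float(finite.min()), float(finite.max())),
    )


def _draw_radar(ax, spec: RadarSpec, style: RadarStyle, annotate: bool) -> None:
    k = len(spec.spokes)
    angles = np.linspace(0.0, 2.0 * np.pi, k, endpoint=False)
    lo, hi = spec.interval
    pad = 0.05 * (hi - lo) if hi > lo else max(0.1, abs(hi) * 0.1 + 0.1)
    vmin = style.vmin if style.vmin is not None else lo
    vmax = style.vmax if style.vmax is not None else hi
    if vmax <= vmin:
        vmax = vmin + 1.0
    cmap = plt.get_cmap(style.cmap)
    frac = (spec.background - vmin) / (vmax - vmin)
    ax.set_facecolor(cmap(float(np.clip(frac, 0.0, 1.0))))
    ax.set_ylim(lo - pad, hi + pad)
    for series, color in ((spec.fwd_log, style.fwd_color), (spec.rev_log, style.rev_color)):
        ok = np.isfinite(series)
        if k >= 2 and ok.sum() >= 2:
            th = np.concatenate([angles[ok], angles[ok][:1]])
            rr = np.concatenate([series[ok], series[ok][:1]])
            ax.plot(th, rr, color=color, linewidth=0.8, alpha=0.7)
        ax.plot(angles[ok], series[ok], "o", color=color, markersize=3)
    ax.set_xticks(angles)
    if annotate:
        ax.set_xticklabels(spec.spokes, fontsize=7)
        ax.set_title(spec.title, fontsize=9)
    else:
        ax.set_xticklabels([])
    ax.set_yticklabels([])
    ax.tick_params(length=0)
    ax.grid(alpha=0.3, linewidth=0.4)


def _save(fig, path: str | Path, style: RadarStyle) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metadata = {"Date": None} if path.suffix == ".svg" else None
    fig.savefig(path, dpi=style.dpi, metadata=metadata)
    plt.close(fig)
    return path


def render_radar(spec: RadarSpec, path: str | Path, style: RadarStyle = RadarStyle()) -> Path:
    """Write one gene radar; deterministic for a fixed spec and style."""
    fig = plt.figure(figsize=style.figsize)
    ax = fig.add_subplot(111, projection="polar")
    _draw_radar(ax, spec, style, annotate=True)
    return _save(fig, path, style)


def render_radar_ma(
    specs: Sequence[RadarSpec],
    path: str | Path,
    style: RadarStyle = RadarStyle(),
    figsize: tuple[float, float] = (9.0, 7.0),
) -> Path:
    """Compose gene radars at their (LogCount, LogFoldChange) positions.

    Genes sharing coordinates are drawn in lexicographic id order (later on
    top).  Every spec must carry MA coordinates.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("no radar specs given")
    missing = sorted(s.gene for s in specs if s.ma is None)
    if missing:
        raise ValueError(f"missing MA coordinates for genes: {missing}")
    specs.sort(key=lambda s: s.gene)
    xs = np.array([s.ma[0] for s in specs])
    ys = np.array([s.ma[1] for s in specs])

    fig = plt.figure(figsize=figsize)
    ax = fig.add_subplot(111)
    ax.scatter(xs, ys, s=4, color="0.6", zorder=1)
    ax.set_xlabel("LogCount")
    ax.set_ylabel("LogFoldChange")
    ax.margins(0.12)
    fig.canvas.draw()  # freeze data limits before placing insets
    inv = fig.transFigure.inverted()
    w = h = style.radar_frac
    for spec in specs:
        fx, fy = inv.transform(ax.transData.transform(spec.ma))
        sub = fig.add_axes([fx - w / 2, fy - h / 2, w, h], projection="polar")
        sub.patch.set_alpha(0.85)
        _draw_radar(sub, spec, style, annotate=False)
    return _save(fig, path, style)


def read_ma_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns gene, LogCount, LogFoldChange (extra columns kept)."""
    df = pd.read_csv(path, sep="\t")
    need = {"gene", "LogCount", "LogFoldChange"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"MA table lacks column(s): {sorted(missing)}")
    return df


def attach_ma_coordinates(specs: Sequence[RadarSpec], ma: pd.DataFrame) -> list[RadarSpec]:
    """Return new specs carrying (LogCount, LogFoldChange) from the table."""
    table = ma.set_index("gene")
    out, missing = [], []
    for s in specs:
        if s.gene not in table.index:
            missing.append(s.gene)
            continue
        row = table.loc[s.gene]
        out.append(
            RadarSpec(
                s.gene, s.spokes, s.fwd_log, s.rev_log, s.background, s.interval,
                (float(row["LogCount"]), float(row["LogFoldChange"])),
            )
        )
    if missing:
        raise ValueError(f"genes absent from MA table: {sorted(missing)}")
    return out
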