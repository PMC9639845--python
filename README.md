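# genetrank

Gene prioritization on protein–protein interaction networks (PPINs) using
random walks with restart and **absorbing target states**.

## The problem

A differential-expression screen yields a set *X* of candidate genes (for
example, a single-cell signature of drug sensitivity), and the drug's
mechanism of action involves a known signaling pathway *P*. Which genes of
*X* are most likely to *regulate* the pathway? Plain diffusion methods
(random walk with restart, personalized PageRank) answer poorly on PPINs:
their small-world structure lets a walk mix over the whole network in a few
steps, so every source looks similar. `genetrank` implements a walk model
built for this setting, the four scoring variants around it, bidirectional
symmetry diagnostics, saturation indices over a restart-rate filtration, and
score-radar visualization.

## The model

The PPIN is a vertex- and edge-weighted graph. For a source set *S* and a
disjoint target set *T*, a Markov chain walks off non-target vertices with
step probability

&nbsp;&nbsp;&nbsp;&nbsp;M(u,v) = w_uv·w_v / Σ_{v'∈N⁺(u)} w_uv'·w_v'   (u ∉ T),

every target row being the identity (targets are absorbing). A restart rate
r ∈ [0,1) rescales walk steps by (1−r) and adds r/|S′| toward every vertex
of the restart set S′. For each source s, the **hit score** renormalizes the
hitting probability of target t under the chain restarted at {s} by the
restart-free baseline started uniformly over S:

&nbsp;&nbsp;&nbsp;&nbsp;Q⁽ʳ⁾(s,t) = π_{M_s^r}(t) / π_{M⁰}(t).

Absorption stops the walk at the first target reached, so targets shielded
behind other targets are not credited through them; renormalization tones
down targets that are trivially close to the sources. Scores are computed in
both directions (X⇝P and P⇝X); each gene x is ranked by the arithmetic mean
of its top-τ values of max(log Q⁽ʳ⁾(x,p), log Q⁽ʳ⁾(p,x)). Sweeping r and
accumulating the top-k sets yields a filtration measured by the
**saturation index** Sat_{τ,k}(→r_l) = |T_{τ,k}(→r_l)|/|X| and its relative
form Sat/k. Three ablation contenders (`genetrank_as`, `genetrank_renorm`,
`pr_affinity`) drop renormalization, absorption, or both.

Hitting probabilities are solved exactly through one sparse LU
factorization per (direction, r) — each per-source restart chain is a
rank-1 update of the restart-free chain, handled with the Sherman–Morrison
identity — with an independent power-iteration solver and a dense
fundamental-matrix oracle used for cross-checks.

## Worked example

```
$ python examples/01_hit_scores_on_a_toy_chain.py
r = 0.0: hitting probabilities {'t1': 0.666667, 't2': 0.333333}
r = 0.5: hitting probabilities {'t1': 0.799999, 't2': 0.200000}
hit scores at r = 0.5: {'t1': 1.2, 't2': 0.6}
```

On the path t1–s–a–t2, the restart-free walk from s reaches t1 twice as
often as t2 (2/3 vs 1/3). Restarting at s with r = 0.5 pushes that to
0.8/0.2; dividing by the baseline gives hit scores 1.2 and 0.6 — restart
*enriched* the source-adjacent target by 20% and de-emphasized the far one.

```
$ python examples/02_saturation_sweep.py
k= 10: first rel. saturation 0.0044 (= 1/|X| when the first top-k set is full), final saturation 0.106
k= 50: first rel. saturation 0.0044 (= 1/|X| when the first top-k set is full), final saturation 0.445
max saturation over the whole grid: 0.445
```

At the first processed restart value the cumulative set is a single top-k
set, so the relative saturation equals 1/|X| = 1/227 ≈ 0.0044 exactly; the
maximum saturation staying well below 1 shows the progressive, localized
exploration the absorbing + renormalized walk is designed for.

Other examples cover bidirectional symmetry diagnostics
(`03_bidirectional_symmetry.py`) and radar/MA-plot rendering
(`04_radar_plots.py`). A thin CLI wraps the same calls:
`genetrank run|rank|sweep|hits|fixtures export --help`.

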