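"""Per-gene score radars assembled into an MA-plot composite.

Each radar shows, for one experimental gene, the log hit scores toward its
top-k pathway genes in both directions; the background color encodes the
gene's best score.  Placing radars at (LogCount, LogFoldChange) coordinates
gives a differential-expression view annotated with network proximity.
Images are written under scratch/.
"""

import numpy as np

from genetrank import (
    build_radar_spec,
    make_smallworld_instance,
    render_radar,
    render_radar_ma,
    score_matrix,
)
from genetrank.viz import RadarSpec

instance = make_smallworld_instance(
    n=150, mean_degree=6, rewire_p=0.1, x_size=24, p_size=6, seed=5
)
fwd = score_matrix(instance, "X_to_P", 0.5, "genetrank")
rev = score_matrix(instance, "P_to_X", 0.5, "genetrank")

genes = instance.X.ids[:6]
rng = np.random.default_rng(0)  # synthetic MA coordinates for illustration
specs = []
for gene in genes:
    s = build_radar_spec(gene, fwd, rev, k=5)
    specs.append(
        RadarSpec(s.gene, s.spokes, s.fwd_log, s.rev_log, s.background,
                  s.interval, (float(rng.uniform(0, 10)), float(rng.normal())))
    )

single = render_radar(specs[0], "scratch/radar_single.svg")
composite = render_radar_ma(specs, "scratch/radar_ma.svg")
print(f"wrote {single} (one gene, spokes = its top-5 pathway genes)")
print(f"wrote {composite} (radars placed at synthetic MA coordinates)")
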