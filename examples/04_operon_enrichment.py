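"""Test whether resistant genes sit deeper inside operons than sensitive ones.

Simulates annotation with a planted association — resistant genes distal
in a polycistronic transcript at 3x the sensitive rate — then builds the
feature-by-group summary and runs a two-sided Fisher exact test on the
distal/not-distal contrast.  Short intergenic distances (<15 nt,
including overlaps) are summarized the same way as a proxy for
translational coupling.
"""

import pandas as pd

from kevtools import (
    AnalysisConfig,
    GeneFeatureRecord,
    SimulationConfig,
    association_test,
    simulate_annotation,
    summarize_group,
    summary_table,
)
from kevtools.config import OperonConfig

oc = OperonConfig(distal_rate_by_class={"sensitive": 0.16, "resistant": 0.44})
sim = SimulationConfig(n_genes=240, operon_config=oc, seed=9)
classes = {f"g{i:04d}": ("sensitive" if i <= 102 else "resistant") for i in range(1, 241)}
frame = simulate_annotation(sim, classes=classes)

records = {}
for group in ("sensitive", "resistant"):
    ids = {g for g, c in classes.items() if c == group}
    records[group] = [
        GeneFeatureRecord(
            r.gene_id, True, r.operon_position,
            None if pd.isna(r.intergenic_distance) else float(r.intergenic_distance),
            (int(r.utr_length),), r.strand,
        )
        for r in frame.itertuples() if r.gene_id in ids
    ]

config = AnalysisConfig()
summaries = [summarize_group(records[g], g, config) for g in ("sensitive", "resistant")]
print(summary_table(summaries).to_string())

s, r = summaries
odds, p = association_test(
    [[s.n_distal, s.n_listed - s.n_distal], [r.n_distal, r.n_listed - r.n_distal]]
)
print(f"\ndistal-in-operon contrast: odds ratio {odds:.2f}, Fisher p = {p:.2e}")
# An odds ratio well below 1 means distal position is depleted among
# sensitive genes (enriched among resistant) - the translational-coupling
# signature the summary is designed to expose.
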