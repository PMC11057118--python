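"""Inversion calling and signed reversal distance between two plastomes.

Plants three inversions in a copy of a template genome, rebuilds the signed
block permutation from shared gene anchors (one IR copy masked), and computes
the minimum number of reversals (Hannenhalli-Pevzner) separating the two.
"""

from plastarch import SimulationConfig, build_template, rearrangement_report
from plastarch.synthetic_plastomes import (
    _rng_streams,
    apply_events,
    plan_inversions,
)

cfg = SimulationConfig(seed=9, genome_id="query")
template, _ = build_template(cfg)
genome, manifest = build_template(cfg)
rng = _rng_streams(cfg.seed)[1]
events = plan_inversions(genome, rng, 3, region=(0, manifest.regions["LSC"][1]))
genome, manifest = apply_events(genome, events, manifest, rng)

report = rearrangement_report(template, genome)
print(f"shared single-copy anchors: {report['n_anchors']}")
print(f"collinear blocks: {report['n_blocks']}")
print(f"signed permutation: {report['permutation']}")
for call in report["inversions"]:
    s, e = call.query_interval
    print(f"inversion call: [{s}, {e}) spanning {len(call.genes)} genes")
print(f"reversal distance: {report['reversal_distance']} "
      f"(planted inversions: {len(manifest.planted_inversions)})")
# Negative block signs mark inverted segments; with non-interleaving planted
# inversions the reversal distance equals the planted count exactly.
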