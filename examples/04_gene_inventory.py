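"""Gene presence / duplication / fragmentation / loss calls.

Plants one degradation of each mode, classifies every panel gene from
sequence similarity (60% identity and coverage rules), and counts
independent loss events on a small phylogeny.
"""

import dendropy

from plastarch import (
    GeneDegradation,
    SimulationConfig,
    count_loss_events,
    inventory_matrix,
    reference_from_template,
)
from plastarch.synthetic_plastomes import build_template, simulate

template, _ = build_template(SimulationConfig(seed=5, genome_id="t"))
panel = reference_from_template(template)

genomes = []
for gid, degs in (
    ("sp1", [GeneDegradation("ycf15", "delete"),
             GeneDegradation("rps16", "premature_stop", fraction=0.4)]),
    ("sp2", [GeneDegradation("ycf15", "delete"),
             GeneDegradation("ndhF", "truncate", fraction=0.5)]),
    ("sp3", [GeneDegradation("infA", "duplicate")]),
    ("sp4", []),
):
    g, _ = simulate(SimulationConfig(seed=5, genome_id=gid, degradations=degs))
    genomes.append(g)

matrix = inventory_matrix(genomes, panel)
for gid in ("sp1", "sp2", "sp3", "sp4"):
    print(f"{gid}: {matrix.encoded_gene_count(gid)} genes encoded, "
          f"{matrix.cds_count(gid)} protein-coding; "
          f"ycf15={matrix.status(gid, 'ycf15').status}, "
          f"rps16={matrix.status(gid, 'rps16').status}")

tree = dendropy.Tree.get(data="((sp1,sp2),(sp3,sp4));", schema="newick")
tree.is_rooted = True
losses = count_loss_events(matrix, tree)
print(f"independent loss events for ycf15 on the tree: {losses['ycf15']}")
# sp1 and sp2 are sisters, so their shared ycf15 loss counts once.
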