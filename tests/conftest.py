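import pytest

from plastarch.gene_inventory import reference_from_template
from plastarch.synthetic_plastomes import GeneDegradation, SimulationConfig, build_template, simulate

#: degradations spanning every mode, reused by inventory and acceptance tests
STANDARD_DEGRADATIONS = [
    GeneDegradation("ycf15", "delete"),
    GeneDegradation("petA", "delete"),
    GeneDegradation("ndhF", "truncate", fraction=0.5),
    GeneDegradation("accD", "truncate", fraction=0.75),
    GeneDegradation("rps16", "premature_stop", fraction=0.4),
    GeneDegradation("rbcL", "premature_stop", fraction=0.4),
    GeneDegradation("clpP", "intron_delete", index=1),
    GeneDegradation("rpoC1", "intron_delete", index=0),
    GeneDegradation("infA", "duplicate"),
]


@pytest.fixture(scope="session")
def template():
    genome, manifest = build_template(SimulationConfig(seed=7, genome_id="template7"))
    return genome, manifest


@pytest.fixture(scope="session")
def template_genome(template):
    return template[0]


@pytest.fixture(scope="session")
def panel(template_genome):
    return reference_from_template(template_genome)


@pytest.fixture(scope="session")
def degraded():
    cfg = SimulationConfig(seed=7, genome_id="degraded7", degradations=list(STANDARD_DEGRADATIONS))
    return simulate(cfg)
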