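"""Generator invariants: determinism, conservation, manifest bookkeeping."""

import numpy as np
import pytest

from plastarch._util import gc_fraction, revcomp, translate
from plastarch.synthetic_plastomes import (
    GeneDegradation,
    SimulationConfig,
    SimulationError,
    StructuralEvent,
    TruthManifest,
    _rng_streams,
    apply_events,
    build_template,
    plan_inversions,
    simulate,
)


def test_template_layout_and_exact_inverted_repeat(template):
    g, man = template
    cfg = SimulationConfig(seed=7)
    assert len(g.seq) == cfg.lsc_len + cfg.ssc_len + 2 * cfg.ir_len == 152_000
    L, I, S = cfg.lsc_len, cfg.ir_len, cfg.ssc_len
    assert g.seq[L + I + S :] == revcomp(g.seq[L : L + I])
    assert man.regions == {
        "LSC": [0, L], "IRb": [L, L + I], "SSC": [L + I, L + I + S],
        "IRa": [L + I + S, L + 2 * I + S],
    }


def test_template_deterministic_for_seed():
    a, ma = build_template(SimulationConfig(seed=11))
    b, mb = build_template(SimulationConfig(seed=11))
    assert a.seq == b.seq
    assert [f.parts for f in a.features] == [f.parts for f in b.features]
    assert ma.to_json() == mb.to_json()
    c, _ = build_template(SimulationConfig(seed=12))
    assert c.seq != a.seq


@pytest.mark.parametrize("gc", [0.31, 0.37, 0.39])
def test_realized_gc_matches_target(gc):
    g, _ = build_template(SimulationConfig(seed=3, gc_target=gc))
    assert abs(g.gc() - gc) < 0.005


def test_cds_genes_are_valid_orfs(template_genome):
    for name in ("rbcL", "clpP", "ndhA", "rpoC1"):
        (f,) = [x for x in template_genome.genes(name) if True][:1]
        aa = translate(f.extract(template_genome.seq))
        assert aa[0] == "M"
        assert aa[-1] == "*"
        assert "*" not in aa[:-1]


def test_simulate_reproducible_end_to_end():
    cfg = SimulationConfig(
        seed=21,
        events=[StructuralEvent("insert_repeat", {"length": 120})],
        degradations=[GeneDegradation("infA", "delete")],
    )
    g1, m1 = simulate(cfg)
    g2, m2 = simulate(cfg)
    assert g1.seq == g2.seq
    assert m1.to_json() == m2.to_json()
    assert TruthManifest.from_json(m1.to_json()).expected_gene_status == m1.expected_gene_status


def test_inversion_preserves_length_and_flips_gene_block(template):
    import copy

    g, man = template
    man = copy.deepcopy(man)
    rng = _rng_streams(7)[1]
    events = plan_inversions(g, rng, 1, region=(0, man.regions["LSC"][1]))
    (ev,) = events
    start, end = ev.params["start"], ev.params["end"]
    inside_before = [
        (f.name, f.strand) for f in g.sorted_features() if f.start >= start and f.end <= end
    ]
    g2, man2 = apply_events(g, events, man, rng)
    assert len(g2.seq) == len(g.seq)
    assert g2.seq[start:end] == revcomp(g.seq[start:end])
    inside_after = [
        (f.name, f.strand) for f in g2.sorted_features() if f.start >= start and f.end <= end
    ]
    flipped = [(n, "+" if s == "-" else "-") for n, s in reversed(inside_before)]
    assert inside_after == flipped


def test_inversion_cutting_a_gene_is_rejected(template):
    g, man = template
    rbcl = g.genes("rbcL")[0]
    ev = StructuralEvent("inversion", {"start": rbcl.start + 10, "end": rbcl.end + 500})
    import copy

    with pytest.raises(SimulationError, match="rbcL"):
        apply_events(g, [ev], copy.deepcopy(man), np.random.default_rng(0))


def test_ir_expand_conserves_and_duplicates_absorbed_genes():
    from plastarch.synthetic_plastomes import simulate_architecture

    g0, _ = build_template(SimulationConfig(seed=5, genome_id="expanded_5"))
    g, man = simulate_architecture("expanded", seed=5)
    shift = len(g.seq) - len(g0.seq)
    assert shift > 0  # expansion grows the genome by the duplicated stretch
    assert man.expected_arch_class == "expanded"
    assert len(g.genes("ndhF")) == 2  # absorbed SSC gene now in both copies
    ib0, ib1 = man.regions["IRb"]
    ia0, ia1 = man.regions["IRa"]
    assert g.seq[ia0:ia1] == revcomp(g.seq[ib0:ib1])


def test_ir_loss_plus_sir_leaves_one_copy_and_planted_pair():
    from plastarch.synthetic_plastomes import simulate_architecture

    g, man = simulate_architecture("ir_loss_sIR", seed=5)
    assert man.expected_arch_class == "ir_loss_sIR"
    assert len(g.genes("rrn16")) == 1  # single relic copy of the former IR
    (rec,) = [r for r in man.planted_repeats if r["label"] == "sIR"]
    p1, p2, L = rec["pos1"], rec["pos2"], rec["length"]
    assert g.seq[p1 : p1 + L] == revcomp(g.seq[p2 : p2 + L])


def test_degradation_expectations_follow_status_rules(degraded):
    _, man = degraded
    exp = man.expected_gene_status
    assert exp["ycf15"] == "lost"
    assert exp["ndhF"] == "lost"  # truncated below the 60% coverage rule
    assert exp["accD"] == "fragmented"  # 75% kept: above coverage, broken ORF
    assert exp["rps16"] == "fragmented"
    assert exp["infA"] == "duplicated"
    assert man.expected_introns["clpP"] == [True, False]


def test_premature_stop_preserves_identity_except_one_codon(template):
    g, _ = template
    cfg = SimulationConfig(
        seed=7, degradations=[GeneDegradation("rbcL", "premature_stop", fraction=0.4)]
    )
    g2, _ = simulate(cfg)
    f0 = g.genes("rbcL")[0]
    f1 = g2.genes("rbcL")[0]
    assert f1.pseudo
    a, b = f0.extract(g.seq), f1.extract(g2.seq)
    diff = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    assert diff and max(diff) - min(diff) < 3  # a single codon replaced
    aa = translate(b)
    assert "*" in aa[:-1]


def test_premature_stop_on_trna_is_invalid(template):
    g, man = template
    import copy

    cfg_deg = [GeneDegradation("trnH-GUG", "premature_stop", fraction=0.5)]
    from plastarch.synthetic_plastomes import degrade_genes

    with pytest.raises(SimulationError, match="tRNA"):
        degrade_genes(g, cfg_deg, copy.deepcopy(man), np.random.default_rng(0))


def test_sizing_error_when_panel_does_not_fit():
    with pytest.raises(SimulationError, match="region"):
        build_template(SimulationConfig(seed=1, ssc_len=8000))


def test_config_yaml_round_trip(tmp_path):
    cfg = SimulationConfig(
        seed=13, gc_target=0.33,
        events=[StructuralEvent("insert_dr", {"length": 1650})],
        degradations=[GeneDegradation("ndhF", "truncate", fraction=0.5)],
    )
    path = tmp_path / "cfg.yaml"
    cfg.to_yaml(path)
    back = SimulationConfig.from_yaml(path)
    assert back.seed == 13 and back.gc_target == 0.33
    assert back.events[0].kind == "insert_dr"
    assert back.degradations[0].fraction == 0.5
    g1, _ = simulate(cfg)
    g2, _ = simulate(back)
    assert g1.seq == g2.seq
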