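"""Repeat census: oracle equivalence, planted recovery, symmetry properties."""

import numpy as np
import pytest

from plastarch._util import revcomp
from plastarch.repeat_census import (
    RepeatHit,
    brute_force_repeats,
    find_repeats,
    pigeonhole_seed,
    repeat_summary,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def test_minimal_forward_and_palindromic_examples():
    # two abutting copies of ACGT
    hits = find_repeats("ACGTACGT", min_len=4, max_mm=0, kinds=("forward",))
    assert hits == [RepeatHit(0, 4, "forward", 4, 0)]
    assert hits == brute_force_repeats("ACGTACGT", min_len=4, max_mm=0, kinds=("forward",))
    # AAAA / TTTT are reverse complements of each other
    hits = find_repeats("AAAATTTT", min_len=4, max_mm=0, kinds=("palindromic",))
    assert RepeatHit(0, 4, "palindromic", 4, 0) in hits
    assert hits == brute_force_repeats("AAAATTTT", min_len=4, max_mm=0, kinds=("palindromic",))


def test_short_or_empty_input_yields_nothing():
    assert brute_force_repeats("", min_len=12) == []
    rng = np.random.default_rng(0)
    seq = _random_seq(rng, 50)  # < 2*min_len, no wrap: nothing can repeat
    assert find_repeats(seq, min_len=30, max_mm=0) == []
    with pytest.raises(ValueError, match="oracle"):
        brute_force_repeats("A" * 6000)


def test_pigeonhole_seed_bound():
    # 3 mismatches split a 30 bp window into runs summing to 27: longest >= 6
    assert pigeonhole_seed(30, 3) == 6
    assert pigeonhole_seed(30, 0) == 30
    assert pigeonhole_seed(12, 2) == 4


@pytest.mark.parametrize("min_len,max_mm", [(12, 2), (30, 3)])
def test_oracle_equivalence_on_seeded_random_sequences(min_len, max_mm):
    rng = np.random.default_rng(5)
    for trial in range(15):
        n = int(rng.integers(100, 1500))
        seq = _random_seq(rng, n)
        if trial % 2:  # plant a duplication half the time
            L = int(rng.integers(min_len, min_len + 60))
            src = int(rng.integers(0, n - L))
            dst = int(rng.integers(0, n - L))
            seq = seq[:dst] + seq[src : src + L] + seq[dst + L :]
        found = find_repeats(seq, min_len=min_len, max_mm=max_mm)
        oracle = brute_force_repeats(seq, min_len=min_len, max_mm=max_mm)
        assert found == oracle
        for h in found:
            assert h.verify(seq)


def test_planted_duplication_recovered_in_random_background():
    rng = np.random.default_rng(9)
    seq = _random_seq(rng, 1000)
    seq = seq[:700] + seq[100:150] + seq[750:]  # 50 bp forward copy
    hits = brute_force_repeats(seq, min_len=30, max_mm=3, kinds=("forward",))
    assert len(hits) >= 1
    assert any(h.length >= 50 for h in hits)
    assert find_repeats(seq, min_len=30, max_mm=3, kinds=("forward",)) == hits


def test_strand_symmetry_of_totals():
    rng = np.random.default_rng(17)
    for _ in range(5):
        seq = _random_seq(rng, 800)
        L = int(rng.integers(25, 60))
        seq = seq + seq[10 : 10 + L] + revcomp(seq[100 : 100 + L])
        fwd = find_repeats(seq, min_len=20, max_mm=2)
        rev = find_repeats(revcomp(seq), min_len=20, max_mm=2)
        by_kind = lambda hits: {
            k: sum(1 for h in hits if h.kind == k)
            for k in ("forward", "reverse", "palindromic")
        }
        assert by_kind(fwd) == by_kind(rev)


def test_monotonicity_lowering_min_len_and_relaxing_budget():
    rng = np.random.default_rng(23)
    for _ in range(5):
        seq = _random_seq(rng, 600)
        seq = seq + seq[50:95]  # one planted 45 bp copy
        strict = find_repeats(seq, min_len=30, max_mm=1, max_len=10_000)
        fewer_len = find_repeats(seq, min_len=20, max_mm=1, max_len=10_000)
        assert len(fewer_len) >= len(strict)
        # relaxing the budget never loses a repeat region: every strict hit is
        # contained in some hit found under the larger budget
        relaxed = find_repeats(seq, min_len=30, max_mm=3, max_len=10_000)
        for h in strict:
            assert any(
                r.kind == h.kind
                and r.pos1 <= h.pos1
                and r.pos1 + r.length >= h.pos1 + h.length
                for r in relaxed
            )


def test_circular_scan_finds_origin_spanning_repeat():
    rng = np.random.default_rng(31)
    core = _random_seq(rng, 40)
    # copy 1 split across the origin, copy 2 internal
    seq = core[20:] + _random_seq(rng, 300) + core + _random_seq(rng, 300) + core[:20]
    hits = find_repeats(seq, circular=True, min_len=35, max_mm=0, kinds=("forward",))
    assert any(h.length >= 40 for h in hits)
    linear = find_repeats(seq, circular=False, min_len=35, max_mm=0, kinds=("forward",))
    assert not any(h.length >= 40 for h in linear)


def test_repeat_summary_partitions_hits():
    assert repeat_summary([]) == {
        "total": 0,
        "by_kind": {"forward": 0, "reverse": 0, "palindromic": 0},
        "by_length": {"30-99": 0, "100-999": 0, ">=1000": 0},
    }
    hits = [
        RepeatHit(0, 100, "forward", 40, 0),
        RepeatHit(0, 300, "reverse", 150, 1),
        RepeatHit(0, 2000, "palindromic", 1200, 3),
    ]
    s = repeat_summary(hits)
    assert s["total"] == 3
    assert s["by_length"] == {"30-99": 1, "100-999": 1, ">=1000": 1}
    assert sum(s["by_kind"].values()) == s["total"]


def test_planted_census_on_synthetic_genome():
    from plastarch.synthetic_plastomes import (
        SimulationConfig,
        StructuralEvent,
        _rng_streams,
        apply_events,
        build_template,
    )

    cfg = SimulationConfig(seed=15)
    g, man = build_template(cfg)
    rng = _rng_streams(cfg.seed)[1]
    events = [
        StructuralEvent("insert_repeat", {"length": 80, "kind": k})
        for k in ("forward", "palindromic", "reverse", "forward", "forward")
    ] * 4  # 20 planted pairs
    g, man = apply_events(g, events, man, rng)
    hits = find_repeats(g.seq, min_len=30, max_mm=3)
    assert len(hits) >= 20
    planted_kinds = {r["kind"] for r in man.planted_repeats}
    assert {h.kind for h in hits} >= planted_kinds
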