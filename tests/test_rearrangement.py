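"""Signed reversal distance (HP vs exact search) and LCB construction."""

import numpy as np
import pytest

from plastarch.rearrangement import (
    RearrangementError,
    SignedPermutation,
    _distance_table,
    apply_reversal,
    breakpoints,
    brute_force_distance,
    build_lcbs,
    call_inversions,
    collapse_signed_sequence,
    gene_anchors,
    reversal_distance,
)


def _random_perm(rng, n):
    vals = rng.permutation(n) + 1
    signs = rng.choice([-1, 1], n)
    return SignedPermutation(tuple(int(v * s) for v, s in zip(vals, signs)))


def test_validation_rejects_non_permutations():
    with pytest.raises(RearrangementError):
        SignedPermutation((1, 1))
    with pytest.raises(RearrangementError):
        SignedPermutation((0, 1))
    with pytest.raises(RearrangementError):
        SignedPermutation((2, 3))


@pytest.mark.parametrize(
    "elems,expected",
    [
        ((1, 2, 3), 0),
        ((1, -2, 3), 1),
        ((-1,), 1),
        ((2, 1), 3),  # the classic unoriented hurdle
        ((-3, -2, -1), 1),
        ((3, 2, 1), 3),  # nested unoriented hurdles
    ],
)
def test_known_distances(elems, expected):
    assert reversal_distance(SignedPermutation(elems)) == expected
    assert brute_force_distance(SignedPermutation(elems)) == expected


def test_distance_formula_matches_bfs_exhaustively_small_n():
    for n in range(1, 5):
        for elems, d in _distance_table(n).items():
            assert reversal_distance(SignedPermutation(elems)) == d


def test_fortress_cases_at_n6_match_bfs():
    # fortress structures (all hurdles protected, odd count) exist at n = 6;
    # pin a couple found by sweeping the BFS table
    from plastarch.rearrangement import _hurdles_fortress

    table = _distance_table(6)
    fortresses = [
        elems for elems in table if _hurdles_fortress(elems)[1] == 1
    ]
    assert len(fortresses) > 0
    for elems in fortresses:
        assert reversal_distance(SignedPermutation(elems)) == table[elems]


def test_distance_invariant_under_inversion_of_scenario():
    rng = np.random.default_rng(3)
    for _ in range(50):
        p = _random_perm(rng, int(rng.integers(2, 8)))
        assert reversal_distance(p) == reversal_distance(p.inverse())


def test_subadditivity_k_random_reversals():
    rng = np.random.default_rng(4)
    for _ in range(100):
        n = int(rng.integers(2, 11))
        k = int(rng.integers(0, 7))
        elems = tuple(range(1, n + 1))
        for _ in range(k):
            i = int(rng.integers(n))
            j = int(rng.integers(i, n))
            elems = apply_reversal(elems, i, j)
        p = SignedPermutation(elems)
        d = reversal_distance(p)
        assert d <= k
        assert d >= breakpoints(p) / 2


def test_exact_search_oracle_at_n7_8_spot_checks():
    rng = np.random.default_rng(11)
    for n in (7, 8):
        for _ in range(25):
            p = _random_perm(rng, n)
            assert reversal_distance(p) == brute_force_distance(p)
    with pytest.raises(RearrangementError, match="n <= 8"):
        brute_force_distance(_random_perm(rng, 9))


def test_grimm_style_round_trip():
    p = SignedPermutation((1, -3, 2))
    text = p.to_grimm("demo")
    assert SignedPermutation.from_grimm(text) == p


def test_collapse_signed_sequence():
    assert collapse_signed_sequence([1, 2, 3]) == [1]
    assert collapse_signed_sequence([1, -3, -2, 4]) == [1, -2, 3]
    assert collapse_signed_sequence([-3, -2, -1]) == [-1]
    assert collapse_signed_sequence([-2, -3]) == [-1, -2]  # not a collinear run


def test_anchors_identity_and_single_inversion(template_genome):
    anchors = gene_anchors(template_genome, template_genome)
    assert all(a.sign == 1 for a in anchors)
    lcbs, perm = build_lcbs(anchors)
    assert list(perm.elements) == [1]
    assert call_inversions(lcbs) == []


def test_closed_loop_planted_inversions_across_seeds():
    from plastarch.synthetic_plastomes import (
        SimulationConfig,
        _rng_streams,
        apply_events,
        build_template,
        expected_permutation,
        plan_inversions,
    )

    for seed, k in ((61, 1), (62, 2), (63, 4)):
        cfg = SimulationConfig(seed=seed, genome_id=f"q{seed}")
        tmpl, _ = build_template(cfg)
        g, man = build_template(cfg)
        rng = _rng_streams(seed)[1]
        events = plan_inversions(g, rng, k, region=(0, man.regions["LSC"][1]))
        g, man = apply_events(g, events, man, rng)
        man.expected_permutation = expected_permutation(man)
        anchors = gene_anchors(tmpl, g)
        lcbs, perm = build_lcbs(anchors)
        assert list(perm.elements) == man.expected_permutation
        assert reversal_distance(perm) == k
        calls = call_inversions(lcbs)
        assert len(calls) == k
        # anchors live in the normalized frame: shift planted coordinates by
        # the frame anchor's start before comparing
        off = g.genes("psbA")[0].start
        planted = sorted((r["start"] - off, r["end"] - off) for r in man.planted_inversions)
        called = sorted(c.query_interval for c in calls)
        for (ps, pe), (cs, ce) in zip(planted, called):
            # called interval within block granularity of the planted one
            assert ps <= cs < ce <= pe


def test_deleted_gene_absent_from_anchors(template_genome):
    from plastarch.synthetic_plastomes import GeneDegradation, SimulationConfig, simulate

    cfg = SimulationConfig(seed=7, degradations=[GeneDegradation("petA", "delete")])
    g, _ = simulate(cfg)
    anchors = gene_anchors(template_genome, g)
    names = {a.name for a in anchors}
    assert "petA" not in names
    assert "rbcL" in names
    _, perm = build_lcbs(anchors)
    assert list(perm.elements) == [1]


def test_insufficient_shared_genes_raises():
    from plastarch.plastome_io import AnnotatedPlastome, GeneFeature

    seq = "ATG" + "ACGTT" * 200 + "TAA"
    a = AnnotatedPlastome(
        id="a", seq=seq,
        features=[GeneFeature("psbA", "CDS", [(0, 90, "+")])],
    )
    with pytest.raises(RearrangementError, match="shared single-copy"):
        gene_anchors(a, a)
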