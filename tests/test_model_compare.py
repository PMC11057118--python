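"""LRT arithmetic, AICc ranking, selection rules, NG86 counting."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastarch._util import CODON_TABLE, STOP_CODONS
from plastarch.lrt_anchors import lrt_anchor_table
from plastarch.model_compare import (
    BranchRate,
    ModelCompareError,
    ModelFit,
    aicc,
    aicc_rank,
    chi2_sf,
    classify_positive_selection,
    lrt,
    lrt_from_stat,
    ng_dnds,
    summarize_dnds,
)

SENSE_CODONS = sorted(set(CODON_TABLE) - STOP_CODONS)


# ---------------------------------------------------------------------------
# chi-square / LRT


def _chi2_sf_even_df_closed_form(x, df):
    # survival for even df: exp(-x/2) * sum_{k<df/2} (x/2)^k / k!
    half = x / 2.0
    return math.exp(-half) * sum(half**k / math.factorial(k) for k in range(df // 2))


def _chi2_sf_series(x, df):
    """Independent survival function: series for the lower tail, Lentz
    continued fraction for the upper tail (avoids cancellation)."""
    a, z = df / 2.0, x / 2.0
    if z == 0:
        return 1.0
    log_pre = -z + a * math.log(z) - math.lgamma(a)
    if z < a + 1.0:  # series for P(a, z), then complement (no cancellation here)
        term = 1.0 / a
        total = term
        k = 0
        while abs(term) > abs(total) * 1e-18 and k < 10_000:
            k += 1
            term *= z / (a + k)
            total += term
        return 1.0 - total * math.exp(log_pre)
    # modified Lentz continued fraction for Q(a, z)
    tiny = 1e-300
    b = z + 1.0 - a
    c = 1.0 / tiny
    d = 1.0 / b
    h = d
    for i in range(1, 10_000):
        an = -i * (i - a)
        b += 2.0
        d = an * d + b
        if abs(d) < tiny:
            d = tiny
        c = b + an / c
        if abs(c) < tiny:
            c = tiny
        d = 1.0 / d
        delta = d * c
        h *= delta
        if abs(delta - 1.0) < 1e-16:
            break
    return math.exp(log_pre) * h


@pytest.mark.parametrize("df", [1, 2, 3, 4, 5, 6, 7, 8])
def test_chi2_survival_against_independent_series(df):
    for x in np.linspace(0.01, 100, 67):
        ours = chi2_sf(float(x), df)
        ref = _chi2_sf_series(float(x), df)
        assert ours == pytest.approx(ref, rel=1e-10, abs=1e-300)


@pytest.mark.parametrize("df", [2, 4, 6, 8])
def test_chi2_survival_even_df_closed_form(df):
    for x in (0.5, 3.0, 13.9514, 40.0, 73.2202):
        assert chi2_sf(x, df) == pytest.approx(
            _chi2_sf_even_df_closed_form(x, df), rel=1e-12
        )


def test_published_lrt_rows_reproduce_printed_p_values():
    rows = lrt_anchor_table()
    assert len(rows) == 24
    for row in rows:
        res = lrt_from_stat(row.two_delta_L, row.df)
        assert res.df == row.df == row.np_alt - row.np_null
        if row.p_printed == "0":
            assert res.p < 1e-15  # printed 0 means infinitesimally close to 0
        elif row.consistent:
            assert abs(res.p - row.p_value) <= row.p_tolerance(), (row.gene, row.comparison)
        else:
            assert res.p == pytest.approx(row.p_value, rel=0.2)


def test_lrt_from_fits_and_clamping():
    res = lrt(ModelFit("M1", -1969.1, 212), ModelFit("M2", -1962.1, 214))
    assert res.stat == pytest.approx(14.0)
    assert res.df == 2
    assert res.p == pytest.approx(chi2_sf(14.0, 2))
    # degenerate: equal likelihoods
    res0 = lrt(ModelFit("a", -10.0, 5), ModelFit("b", -10.0, 7))
    assert res0.stat == 0.0 and res0.p == 1.0
    # optimiser failure: alt worse than null beyond tolerance
    bad = lrt(ModelFit("a", -10.0, 5), ModelFit("b", -10.5, 7))
    assert bad.optimizer_warning and bad.stat == 0.0
    with pytest.raises(ModelCompareError):
        lrt(ModelFit("a", -10.0, 7), ModelFit("b", -9.0, 5))


# ---------------------------------------------------------------------------
# AICc


def test_aicc_closed_form_and_limits():
    assert aicc(-100.0, 5, 1000) == pytest.approx(210 + 60 / 994)
    # equal lnL: fewer parameters rank first
    ranked = aicc_rank([ModelFit("big", -50, 6), ModelFit("small", -50, 5)], n_obs=500)
    assert ranked[0].fit.model_name == "small"
    assert ranked[0].delta == 0.0
    # AICc -> AIC as n grows
    assert abs(aicc(-100, 5, 10**9) - (210.0)) < 1e-6
    with pytest.raises(ModelCompareError, match="n_obs"):
        aicc(-10, 5, 6)


def test_clock_model_ranking_prefers_best_fit():
    # constructed so the clockless model dominates despite its parameter cost
    fits = [
        ModelFit("global_clock", -5400.0, 100),
        ModelFit("local_clock", -5340.0, 103),
        ModelFit("clockless", -5200.0, 197),
    ]
    ranked = aicc_rank(fits, n_obs=20_000)
    assert [r.fit.model_name for r in ranked] == ["clockless", "local_clock", "global_clock"]
    assert ranked[1].delta > 0


# ---------------------------------------------------------------------------
# positive-selection decision rule


def test_selection_rule_and_sites():
    call = classify_positive_selection(
        lrt_from_stat(8.9, 1), omega=1.8, posteriors=[0.2, 0.97, 0.9]
    )
    assert call.positive  # p ~ 0.003 < 0.05 and omega > 1
    assert call.selected_sites == [2]
    assert not classify_positive_selection(lrt_from_stat(0.45, 1), omega=2.0).positive
    assert not classify_positive_selection(lrt_from_stat(8.9, 1), omega=0.5).positive


# ---------------------------------------------------------------------------
# NG86 dN/dS


def _ng86_oracle(seq_a, seq_b):
    """Independent site/pathway enumeration (no shared helpers)."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        for codon in (ca, cb):
            for pos in range(3):
                syn = 0
                for b in "ACGT":
                    if b == codon[pos]:
                        continue
                    alt = codon[:pos] + b + codon[pos + 1 :]
                    if alt not in STOP_CODONS and CODON_TABLE[alt] == CODON_TABLE[codon]:
                        syn += 1
                S += syn / 6.0  # averaged over the two codons
                N += (3 - syn) / 6.0
        diff = [k for k in range(3) if ca[k] != cb[k]]
        if diff:
            path_s, path_n, n_paths = 0.0, 0.0, 0
            for order in itertools.permutations(diff):
                cur, s, n, ok = ca, 0, 0, True
                for pos in order:
                    nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                    if nxt in STOP_CODONS:
                        ok = False
                        break
                    if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                        s += 1
                    else:
                        n += 1
                    cur = nxt
                if ok:
                    path_s += s
                    path_n += n
                    n_paths += 1
            Sd += path_s / n_paths
            Nd += path_n / n_paths
    ds = -0.75 * math.log(1 - 4 * (Sd / S) / 3) if Sd else 0.0
    dn = -0.75 * math.log(1 - 4 * (Nd / N) / 3) if Nd else 0.0
    return dn, ds


def test_ng86_identical_sequences():
    seq = "ATGGCTAAATTTGGG" * 4
    res = ng_dnds(seq, seq)
    assert res.dN == 0.0 and res.dS == 0.0
    assert res.undefined and res.omega is None


def test_ng86_single_synonymous_third_position_change():
    a = "TTT" * 30
    b = "TTT" * 29 + "TTC"  # Phe -> Phe
    res = ng_dnds(a, b)
    assert res.dN == 0.0
    assert res.dS > 0.0


def test_ng86_matches_independent_enumeration_oracle():
    rng = np.random.default_rng(8)
    for _ in range(25):
        n_cod = int(rng.integers(5, 40))
        a = "".join(rng.choice(SENSE_CODONS, n_cod))
        b_codons = []
        for c in [a[i : i + 3] for i in range(0, len(a), 3)]:
            if rng.random() < 0.3:
                c = str(rng.choice(SENSE_CODONS))
            b_codons.append(c)
        b = "".join(b_codons)
        res = ng_dnds(a, b)
        dn, ds = _ng86_oracle(a, b)
        assert res.dN == pytest.approx(dn, abs=1e-12)
        assert res.dS == pytest.approx(ds, abs=1e-12)


def test_ng86_matches_biopython_reference():
    # restrict to codons without a leading T: no mutational pathway can then
    # pass through a stop codon, where the two implementations' conventions
    # differ (pathways through stops are skipped here, counted by biopython)
    from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

    safe = [c for c in SENSE_CODONS if c[0] != "T"]
    rng = np.random.default_rng(12)
    for _ in range(5):
        a = "".join(rng.choice(safe, 30))
        b = "".join(
            str(rng.choice(safe)) if rng.random() < 0.2 else a[i : i + 3]
            for i in range(0, len(a), 3)
        )
        res = ng_dnds(a, b)
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
        assert res.dN == pytest.approx(dn, abs=1e-9)
        assert res.dS == pytest.approx(ds, abs=1e-9)


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=30, deadline=None)
def test_ng86_symmetric(seed):
    rng = np.random.default_rng(seed)
    a = "".join(rng.choice(SENSE_CODONS, 12))
    b = "".join(rng.choice(SENSE_CODONS, 12))
    try:
        r1, r2 = ng_dnds(a, b), ng_dnds(b, a)
    except ModelCompareError:
        return  # JC correction out of range for extreme divergence
    assert r1.dN == pytest.approx(r2.dN, abs=1e-12)
    assert r1.dS == pytest.approx(r2.dS, abs=1e-12)


def test_ng86_input_validation():
    with pytest.raises(ModelCompareError, match="length"):
        ng_dnds("ATGAAA", "ATGAAATTT")
    with pytest.raises(ModelCompareError, match="multiple of 3"):
        ng_dnds("ATGA", "ATGA")
    with pytest.raises(ModelCompareError, match="stop"):
        ng_dnds("ATGTAAAAA", "ATGAAAAAA")


# ---------------------------------------------------------------------------
# branch-rate summarisation


def test_summarize_dnds_exclusion_rule():
    rates = [
        BranchRate("focal", 0.02, 0.10),
        BranchRate("focal", 0.03, 0.05),
        BranchRate("comparator", 0.01, 0.10),
        BranchRate("comparator", 0.0005, 0.10),  # dN below 0.001: excluded
        BranchRate("comparator", 0.02, 0.0004),  # dS below 0.001: excluded
    ]
    summary = summarize_dnds(rates, {"focal"}, {"comparator"})
    assert len(summary.excluded) == 2
    assert summary.group_means["focal"] == pytest.approx((0.2 + 0.6) / 2)
    assert summary.group_means["comparator"] == pytest.approx(0.1)
    assert summary.larger_group == "focal"


def test_summarize_dnds_relaxed_vs_constrained_simulation():
    rng = np.random.default_rng(44)
    rates = []
    for _ in range(30):
        ds = float(rng.uniform(0.05, 0.2))
        rates.append(BranchRate("lost_sister", 0.6 * ds * float(rng.uniform(0.8, 1.2)), ds))
        ds = float(rng.uniform(0.05, 0.2))
        rates.append(BranchRate("intact_sister", 0.2 * ds * float(rng.uniform(0.8, 1.2)), ds))
    summary = summarize_dnds(rates, {"lost_sister"}, {"intact_sister"})
    assert summary.larger_group == "focal"
    assert summary.group_means["focal"] < 1.0  # still purifying on average


def test_summarize_dnds_all_excluded_raises():
    with pytest.raises(ModelCompareError, match="excluded"):
        summarize_dnds([BranchRate("x", 0.0001, 0.0001)], {"x"}, {"y"})
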