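"""Decision layer over molecular-evolution model fits.

Site/branch-site likelihood optimisation itself (codeml/HYPHY territory) is
out of scope; this module consumes fit summaries (lnL, parameter counts,
omega estimates, site posteriors) and implements the statistics around them:
likelihood-ratio tests against the chi-square distribution, AICc ranking of
clock models, the positive-selection decision rule (p < 0.05 and omega > 1;
site posterior > 0.95), a Nei-Gojobori (1986) counting dN/dS estimator as a
self-contained stand-in, and the dN/dS summarisation rule that excludes
branches with dN or dS below 0.001.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from scipy import stats as _sps

from ._util import CODON_TABLE, STOP_CODONS


class ModelCompareError(ValueError):
    pass


@dataclass
class ModelFit:
    model_name: str
    lnL: float
    np: int
    omega_estimates: dict | None = None
    site_posteriors: list | None = None

    def __post_init__(self):
        if self.np < 1:
            raise ModelCompareError(f"{self.model_name}: np must be >= 1")
        if not math.isfinite(self.lnL):
            raise ModelCompareError(f"{self.model_name}: non-finite lnL")


@dataclass
class LRTResult:
    stat: float  # 2 * (lnL_alt - lnL_null), clamped at 0
    df: int
    p: float
    optimizer_warning: bool = False


def chi2_sf(x: float, df: int) -> float:
    """Right-tail chi-square survival probability."""
    return float(_sps.chi2.sf(x, df))


def lrt(null: ModelFit, alt: ModelFit, tol: float = 1e-8) -> LRTResult:
    """Likelihood-ratio test of nested fits: 2(lnL1 - lnL0) ~ chi2(df).

    A negative statistic beyond ``tol`` signals an optimiser failure in the
    upstream fit; it is clamped to 0 (p = 1) and flagged.
    """
    if alt.np <= null.np:
        raise ModelCompareError(
            f"alternative ({alt.np} params) must have more parameters "
            f"than null ({null.np})"
        )
    stat = 2.0 * (alt.lnL - null.lnL)
    warning = stat < -tol
    stat = max(stat, 0.0)
    df = alt.np - null.np
    return LRTResult(stat=stat, df=df, p=chi2_sf(stat, df), optimizer_warning=warning)


def lrt_from_stat(stat: float, df: int) -> LRTResult:
    """LRT p-value from an already-computed statistic (e.g. a printed 2ΔL)."""
    if df < 1:
        raise ModelCompareError("df must be >= 1")
    stat = max(float(stat), 0.0)
    return LRTResult(stat=stat, df=df, p=chi2_sf(stat, df))


# ---------------------------------------------------------------------------
# AICc ranking


@dataclass
class RankedFit:
    fit: ModelFit
    aicc: float
    delta: float
    rank: int


def aicc(lnL: float, np: int, n_obs: int) -> float:
    if n_obs <= np + 1:
        raise ModelCompareError(
            f"AICc undefined: n_obs={n_obs} <= np+1={np + 1}"
        )
    return -2.0 * lnL + 2.0 * np + 2.0 * np * (np + 1) / (n_obs - np - 1)


def aicc_rank(fits: list[ModelFit], n_obs: int) -> list[RankedFit]:
    """Fits ranked by corrected Akaike information criterion (ascending)."""
    scored = sorted(
        ((aicc(f.lnL, f.np, n_obs), f) for f in fits), key=lambda t: t[0]
    )
    best = scored[0][0]
    return [
        RankedFit(fit=f, aicc=a, delta=a - best, rank=i)
        for i, (a, f) in enumerate(scored, start=1)
    ]


# ---------------------------------------------------------------------------
# positive-selection decision rule


@dataclass
class SelectionCall:
    positive: bool
    selected_sites: list[int] = field(default_factory=list)


def classify_positive_selection(
    test: LRTResult,
    omega: float,
    posteriors: list[float] | None = None,
    p_thresh: float = 0.05,
    omega_thresh: float = 1.0,
    posterior_thresh: float = 0.95,
) -> SelectionCall:
    """Gene positive iff p < 0.05 and omega > 1; sites iff posterior > 0.95."""
    if not (math.isfinite(test.p) and math.isfinite(omega)):
        raise ModelCompareError("non-finite inputs")
    positive = test.p < p_thresh and omega > omega_thresh
    sites = [
        i for i, pp in enumerate(posteriors or [], start=1) if pp > posterior_thresh
    ]
    return SelectionCall(positive=positive, selected_sites=sites)


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) counting dN/dS


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon."""
    s = 0.0
    for pos in range(3):
        aa = CODON_TABLE[codon]
        syn = 0
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TABLE[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    All orderings of the differing positions are averaged; paths passing
    through a stop codon are discarded (if every path is blocked, the block
    constraint is ignored, which cannot happen for sense-codon pairs under the
    standard code).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        s = n = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                s += 1
            else:
                n += 1
            cur = nxt
        if ok:
            paths.append((s, n))
    if not paths:  # all paths blocked: fall back to counting through stops
        for order in itertools.permutations(diff):
            cur = c1
            s = n = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if CODON_TABLE[cur] == CODON_TABLE[nxt]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            paths.append((s, n))
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


@dataclass
class DnDsResult:
    dN: float
    dS: float
    omega: float | None
    undefined: bool = False  # omega undefined (dS == 0)


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise ModelCompareError(f"proportion {p:.3f} too large for JC correction")
    return 0.0 if p == 0 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng_dnds(seq_a: str, seq_b: str) -> DnDsResult:
    """Nei-Gojobori (1986) dN/dS with Jukes-Cantor correction.

    Both sequences must be equal-length in-frame codon sequences without
    internal stop codons (a trailing stop codon is tolerated and skipped).
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ModelCompareError("sequences differ in length")
    if len(seq_a) % 3:
        raise ModelCompareError("length not a multiple of 3")
    codons = [
        (seq_a[i : i + 3], seq_b[i : i + 3]) for i in range(0, len(seq_a), 3)
    ]
    if codons and codons[-1][0] in STOP_CODONS and codons[-1][1] in STOP_CODONS:
        codons = codons[:-1]
    for ca, cb in codons:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ModelCompareError("internal stop codon")
        if set(ca + cb) - set("ACGT"):
            raise ModelCompareError("ambiguous bases not supported")
    S = N = Sd = Nd = 0.0
    for ca, cb in codons:
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds, dn = _pathway_diffs(ca, cb)
        Sd += ds
        Nd += dn
    pS = Sd / S if S else 0.0
    pN = Nd / N if N else 0.0
    dS = _jc_correct(pS)
    dN = _jc_correct(pN)
    if dS == 0.0:
        return DnDsResult(dN=dN, dS=0.0, omega=None, undefined=True)
    return DnDsResult(dN=dN, dS=dS, omega=dN / dS)


# ---------------------------------------------------------------------------
# dN/dS summarisation across branches


@dataclass
class BranchRate:
    lineage: str
    dN: float
    dS: float

    @property
    def omega(self) -> float | None:
        return self.dN / self.dS if self.dS > 0 else None


@dataclass
class DnDsSummary:
    group_means: dict
    excluded: list
    larger_group: str | None


def summarize_dnds(
    rates: list[BranchRate],
    focal_lineages: set[str],
    comparator_lineages: set[str],
    min_rate: float = 0.001,
) -> DnDsSummary:
    """Mean omega per lineage group, excluding near-zero-rate branches.

    Branches with dN or dS below ``min_rate`` are excluded (a tiny denominator
    would inflate omega arbitrarily) and logged.
    """
    if not rates:
        raise ModelCompareError("no branch rates")
    excluded = [r for r in rates if r.dN < min_rate or r.dS < min_rate]
    usable = [r for r in rates if r not in excluded]
    means = {}
    for name, members in (("focal", focal_lineages), ("comparator", comparator_lineages)):
        vals = [r.omega for r in usable if r.lineage in members and r.omega is not None]
        means[name] = sum(vals) / len(vals) if vals else float("nan")
    if all(math.isnan(v) for v in means.values()):
        raise ModelCompareError("all branches excluded; nothing to summarise")
    larger = None
    if not any(math.isnan(v) for v in means.values()):
        larger = "focal" if means["focal"] > means["comparator"] else "comparator"
    return DnDsSummary(group_means=means, excluded=excluded, larger_group=larger)


# ---------------------------------------------------------------------------
# tabular I/O


def read_fits_tsv(path) -> list[ModelFit]:
    """Model fits from a TSV with columns model, lnL, np[, omega]."""
    fits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            omega = row.get("omega")
            fits.append(
                ModelFit(
                    model_name=row["model"],
                    lnL=float(row["lnL"]),
                    np=int(row["np"]),
                    omega_estimates={"omega": float(omega)} if omega else None,
                )
            )
    return fits
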