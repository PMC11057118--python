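"""Quadripartite architecture: IR detection, region partition, class assignment.

The canonical plastome carries two large inverted-repeat copies (IRa/IRb)
separating a large and a small single-copy region (LSC/SSC).  Observed
departures handled here: boundary expansion/contraction (genes relocated
into or out of the IR), a third near-identical copy (IRc, oriented like IRa),
and complete loss of one copy leaving only a short inverted (sIR) or direct
(DR) remnant pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._util import gc_fraction, revcomp, seq_to_array
from .plastome_io import AnnotatedPlastome
from .reference import reference_regions

ARCH_CLASSES = (
    "canonical", "expanded", "contracted", "triple_IR",
    "ir_loss_sIR", "ir_loss_DR", "unresolved",
)


@dataclass
class IRSet:
    """Large repeat copies (0-3) plus an optional sIR/DR remnant."""

    copies: list[tuple[int, int, str]] = field(default_factory=list)
    copy_identity: float = 1.0
    remnant: tuple[str, int, int, int] | None = None  # (kind, start1, start2, length)

    def intervals(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, _ in self.copies]


@dataclass
class ArchitectureReport:
    genome_id: str
    genome_len: int
    lsc_len: int = 0
    ssc_len: int = 0
    ir_len: int = 0
    irc_len: int = 0
    gc_total: float = float("nan")
    gc_lsc: float = float("nan")
    gc_ssc: float = float("nan")
    gc_ir: float = float("nan")
    arch_class: str = "unresolved"
    junction_genes: list[str] = field(default_factory=list)
    relocated_genes: list[str] = field(default_factory=list)
    diagnostic: str = ""

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1)


# ---------------------------------------------------------------------------
# block matching between two strings (seed + diagonal chaining)


def _matched_blocks(seq_a: str, seq_b: str, k: int, min_block: int, max_gap: int = 200,
                    skip_diag0: bool = False):
    """Near-identical blocks between two strings along gap-free diagonals.

    Exact k-mer seeds are chained per diagonal when separated by at most
    ``max_gap``; each chained block is reported as
    ``(a_start, a_end, b_start, b_end, identity)``.  Boundaries are maximal
    exact-identity extensions of the chained block.  ``skip_diag0`` drops the
    trivial identity diagonal of a self-comparison.
    """
    na, nb = len(seq_a), len(seq_b)
    if na < k or nb < k:
        return []
    index: dict[str, list[int]] = {}
    for i in range(nb - k + 1):
        index.setdefault(seq_b[i : i + k], []).append(i)
    by_diag: dict[int, list[int]] = {}
    step = max(1, k // 2)
    for i in range(0, na - k + 1, step):
        for j in index.get(seq_a[i : i + k], ()):
            if skip_diag0 and j == i:
                continue
            by_diag.setdefault(j - i, []).append(i)
    aa, bb = seq_to_array(seq_a), seq_to_array(seq_b)
    blocks = []
    for diag, starts in by_diag.items():
        starts.sort()
        runs: list[list[int]] = []
        for i in starts:
            if runs and i - runs[-1][1] <= max_gap:
                runs[-1][1] = i + k
            else:
                runs.append([i, i + k])
        for a0, a1 in runs:
            if a1 - a0 < min_block:
                continue
            b0 = a0 + diag
            # maximal exact extension of both block edges
            while a0 > 0 and b0 > 0 and seq_a[a0 - 1] == seq_b[b0 - 1] != "N":
                a0 -= 1
                b0 -= 1
            while a1 < na and a1 + diag < nb and seq_a[a1] == seq_b[a1 + diag] != "N":
                a1 += 1
            b1 = a1 + diag
            mism = int(np.count_nonzero(aa[a0:a1] != bb[b0:b1]))
            ident = 1.0 - mism / (a1 - a0)
            blocks.append((a0, a1, b0, b1, ident))
    # drop blocks contained in a longer one on a different diagonal
    blocks.sort(key=lambda b: (-(b[1] - b[0]), b[0]))
    kept = []
    for b in blocks:
        if not any(b[0] >= o[0] and b[1] <= o[1] and b[2] >= o[2] and b[3] <= o[3] for o in kept):
            kept.append(b)
    return kept


def _inverted_pairs(seq: str, k: int, min_block: int):
    """Inverted-copy pairs ((s1,e1),(s2,e2),identity) with s1 < s2, disjoint."""
    n = len(seq)
    pairs = []
    for a0, a1, b0, b1, ident in _matched_blocks(seq, revcomp(seq), k, min_block):
        s2, e2 = n - b1, n - b0
        (x0, x1), (y0, y1) = sorted([(a0, a1), (s2, e2)])
        if x1 <= y0:  # disjoint copies only (an IR is not a local palindrome)
            pairs.append(((x0, x1), (y0, y1), ident))
    # symmetric duplicates collapse
    out, seen = [], set()
    for p in pairs:
        key = (p[0], p[1])
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out


def _direct_pairs(seq: str, k: int, min_block: int):
    n = len(seq)
    pairs, seen = [], set()
    for a0, a1, b0, b1, ident in _matched_blocks(seq, seq, k, min_block, skip_diag0=True):
        if a0 == b0:
            continue
        (x0, x1), (y0, y1) = sorted([(a0, a1), (b0, b1)])
        if x1 <= y0 and ((x0, x1), (y0, y1)) not in seen:
            seen.add(((x0, x1), (y0, y1)))
            pairs.append(((x0, x1), (y0, y1), ident))
    return pairs


# ---------------------------------------------------------------------------
# operations


def detect_irs(
    g: AnnotatedPlastome,
    min_ir: int = 1000,
    min_remnant: int = 50,
    max_copy_divergence: float = 0.02,
) -> IRSet:
    """Find large inverted-repeat copies, a possible third copy, or remnants.

    The primary IR is the longest disjoint inverted pair >= ``min_ir`` with
    copy identity >= ``1 - max_copy_divergence`` (ties: higher identity, then
    smaller start).  A third copy (IRc) is admitted in direct orientation
    relative to one of the pair.  With fewer than two large copies, the
    longest inverted (sIR) and direct (DR) pair in ``[min_remnant, min_ir)``
    is reported as a remnant.
    """
    seq = g.seq
    inv = [
        p for p in _inverted_pairs(seq, k=21, min_block=min_ir)
        if min(p[0][1] - p[0][0], p[1][1] - p[1][0]) >= min_ir
        and p[2] >= 1 - max_copy_divergence
    ]
    if inv:
        best = max(inv, key=lambda p: (min(p[0][1] - p[0][0], p[1][1] - p[1][0]), p[2], -p[0][0]))
        (s1, e1), (s2, e2), ident = best
        copies = [(s1, e1, "+"), (s2, e2, "-")]
        irc = _find_third_copy(seq, (s1, e1), (s2, e2), min_ir, max_copy_divergence)
        if irc is not None:
            copies.append(irc)
        return IRSet(copies=copies, copy_identity=ident)
    # remnant search
    sirs = [
        p for p in _inverted_pairs(seq, k=15, min_block=min_remnant)
        if min_remnant <= min(p[0][1] - p[0][0], p[1][1] - p[1][0]) < min_ir
    ]
    # a direct pair can never be mistaken for an IR, so the DR remnant search
    # has no upper length cap (observed DRs exceed 1 kb)
    drs = [
        p for p in _direct_pairs(seq, k=15, min_block=min_remnant)
        if min(p[0][1] - p[0][0], p[1][1] - p[1][0]) >= min_remnant
    ]
    best_sir = max(sirs, key=lambda p: p[0][1] - p[0][0], default=None)
    best_dr = max(drs, key=lambda p: p[0][1] - p[0][0], default=None)
    remnant = None
    cand = []
    if best_sir:
        cand.append(("sIR", best_sir))
    if best_dr:
        cand.append(("DR", best_dr))
    if cand:
        kind, p = max(cand, key=lambda kp: kp[1][0][1] - kp[1][0][0])
        remnant = (kind, p[0][0], p[1][0], p[0][1] - p[0][0])
    return IRSet(copies=[], remnant=remnant)


def _find_third_copy(seq, c1, c2, min_ir, max_div):
    """A direct-orientation match of either large copy, outside both."""
    s1, e1 = c1
    s2, e2 = c2

    def outside(x0, x1):
        return (x1 <= s1 or x0 >= e1) and (x1 <= s2 or x0 >= e2)

    def mostly_inside(x0, x1, s, e):
        ov = max(0, min(x1, e) - max(x0, s))
        return ov >= 0.8 * (x1 - x0)

    candidates = []
    for a0, a1, b0, b1, ident in _matched_blocks(seq, seq, k=21, min_block=min_ir,
                                                 skip_diag0=True):
        if a0 == b0 or ident < 1 - max_div:
            continue
        for (x0, x1), (y0, y1) in (((a0, a1), (b0, b1)), ((b0, b1), (a0, a1))):
            if outside(x0, x1) and (
                mostly_inside(y0, y1, s1, e1) or mostly_inside(y0, y1, s2, e2)
            ):
                # direct match of IRa (the '-' copy) keeps IRa's orientation
                orient = "-" if mostly_inside(y0, y1, s2, e2) else "+"
                candidates.append((x0, x1, orient))
    if not candidates:
        return None
    return max(candidates, key=lambda c: (c[1] - c[0], -c[0]))


def partition_regions(g: AnnotatedPlastome, irset: IRSet) -> ArchitectureReport:
    """Partition the circle into LSC/SSC/IR arcs and compute per-region GC."""
    n = len(g.seq)
    rep = ArchitectureReport(genome_id=g.id, genome_len=n, gc_total=gc_fraction(g.seq))
    copies = sorted(irset.copies)
    for (s1, e1, _), (s2, e2, _) in zip(copies, copies[1:]):
        if e1 > s2:
            rep.arch_class = "unresolved"
            rep.diagnostic = f"overlapping IR copies at {e1}>{s2}"
            return rep
    if len(copies) >= 2:
        arcs = []
        for (s, e, _), (s_next, _, _) in zip(copies, copies[1:] + [(
            copies[0][0] + n, 0, "")]):
            arcs.append((e, s_next))  # half-open arc, may wrap via +n
        arc_seqs = [(b - a, g.seq[a % n : b % n] if b <= n else g.seq[a:] + g.seq[: b % n])
                    for a, b in arcs]
        arc_seqs.sort(key=lambda t: -t[0])
        lsc_len, lsc_seq = arc_seqs[0]
        rep.lsc_len, rep.gc_lsc = lsc_len, gc_fraction(lsc_seq)
        ssc_len = sum(L for L, _ in arc_seqs[1:])
        rep.ssc_len = ssc_len
        rep.gc_ssc = gc_fraction("".join(s for _, s in arc_seqs[1:]))
        pair = copies[:2] if len(copies) == 2 else _primary_pair(copies)
        rep.ir_len = pair[0][1] - pair[0][0]
        ir_seq = "".join(g.seq[s:e] for s, e, _ in pair)
        rep.gc_ir = gc_fraction(ir_seq)
        if len(copies) == 3:
            third = next(c for c in copies if c not in pair)
            rep.irc_len = third[1] - third[0]
        # single-copy space tiles whatever the repeat copies do not cover
        rep.ssc_len = n - rep.lsc_len - sum(e - s for s, e, _ in copies)
        rep.arch_class = "canonical"
        rep.junction_genes = sorted(
            {f.name for f in g.features
             for s, e, _ in copies if f.start < s < f.end or f.start < e < f.end}
        )
    else:
        if irset.remnant:
            rep.arch_class = "ir_loss_sIR" if irset.remnant[0] == "sIR" else "ir_loss_DR"
        else:
            rep.diagnostic = "no IR copies and no remnant"
    return rep


def _primary_pair(copies):
    """The two most similar-length copies form the primary IRa/IRb pair."""
    best = None
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            li, lj = copies[i][1] - copies[i][0], copies[j][1] - copies[j][0]
            key = abs(li - lj)
            if best is None or key < best[0]:
                best = (key, [copies[i], copies[j]])
    return best[1]


def classify_architecture(
    report: ArchitectureReport,
    irset: IRSet,
    g: AnnotatedPlastome,
    reference_panel: dict[str, str] | None = None,
) -> ArchitectureReport:
    """Assign the architecture class and list boundary-shift relocated genes.

    *expanded*: a gene whose canonical home is single-copy lies wholly inside
    an IR copy.  *contracted*: a canonical IR resident lies in single-copy
    space.  Three copies type as triple_IR; missing copies type from the
    remnant.  Precedence: triple_IR > ir_loss > expanded > contracted.
    """
    if reference_panel is None:
        reference_panel = reference_regions()
    if not reference_panel:
        raise ValueError("empty reference panel")
    ivs = irset.intervals()

    def wholly_inside(f):
        return any(f.start >= s and f.end <= e for s, e in ivs)

    if len(irset.copies) >= 3:
        report.arch_class = "triple_IR"
        return report
    if len(irset.copies) < 2:
        # class already assigned from the remnant by partition_regions
        return report
    relocated, expelled = [], []
    by_name: dict[str, list] = {}
    for f in g.features:
        by_name.setdefault(f.name, []).append(f)
    for name, feats in by_name.items():
        ref_region = reference_panel.get(name)
        if ref_region in ("LSC", "SSC") and any(wholly_inside(f) for f in feats):
            relocated.append(name)
        if ref_region == "IR" and all(not wholly_inside(f) for f in feats):
            expelled.append(name)
    if relocated:
        report.arch_class = "expanded"
        report.relocated_genes = sorted(relocated)
    elif expelled:
        report.arch_class = "contracted"
        report.relocated_genes = sorted(expelled)
    else:
        report.arch_class = "canonical"
    return report


def regions_bed(g: AnnotatedPlastome, irset: IRSet) -> str:
    """Region intervals as BED rows (0-based half-open)."""
    n = len(g.seq)
    rows = []
    copies = sorted(irset.copies)
    if len(copies) >= 2:
        names = ["IRb", "IRa", "IRc"][: len(copies)]
        for (s, e, _), nm in zip(copies, names):
            rows.append((s, e, nm))
        arcs = []
        for (s, e, _), (s_next, _, _) in zip(copies, copies[1:] + [(copies[0][0] + n, 0, "")]):
            arcs.append((e, s_next))
        arcs.sort(key=lambda a: -(a[1] - a[0]))
        for (a, b), nm in zip(arcs, ["LSC", "SSC", "SSC2"]):
            rows.append((a % n, b % n if b != n else n, nm))
    elif irset.remnant:
        kind, s1, s2, L = irset.remnant
        rows += [(s1, s1 + L, f"{kind}_1"), (s2, s2 + L, f"{kind}_2")]
    rows.sort()
    return "\n".join(f"{g.id}\t{s}\t{e}\t{nm}" for s, e, nm in rows) + "\n"
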