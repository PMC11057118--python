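"""Gene presence/duplication/fragmentation/loss calls and loss-event counting.

A panel gene is *lost* when no locus in the whole genome reaches 60%
nucleotide identity and 60% reference coverage; *fragmented* when a
qualifying locus exists but its in-frame translation carries a premature stop
(or the open reading frame is otherwise incomplete); *duplicated* when extra
qualifying loci occur outside the detected IR copies (IR-driven duplication
is tracked separately as ``ir_copies``).  Calls are sequence-based, not
annotation-based, so unannotated but present genes still classify correctly.

Loss events are counted on a rooted phylogeny by uniform-cost small parsimony
with the root fixed to "present" (plastome panel genes are ancestrally
present); the reported number is the minimum count of presence->loss
transitions among minimum-change reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import revcomp, seq_to_array, translate
from .architecture import detect_irs
from .plastome_io import AnnotatedPlastome
from .reference import default_panel

TRANS_SPLICED_UNSUPPORTED = "unsupported"
_SEED_K = 17


class InventoryError(ValueError):
    pass


@dataclass(frozen=True)
class ReferenceGene:
    """Reference coding sequence plus intron model (exon sequences, 5'->3')."""

    name: str
    kind: str
    exons: tuple[str, ...]
    trans_spliced: bool = False

    @property
    def spliced(self) -> str:
        return "".join(self.exons)

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1


def reference_from_template(template: AnnotatedPlastome, panel=None) -> dict[str, ReferenceGene]:
    """Build the reference panel from an undisturbed template genome."""
    panel = panel or default_panel()
    refs = {}
    for spec in panel:
        feats = template.genes(spec.name)
        if not feats:
            raise InventoryError(f"template lacks panel gene {spec.name}")
        f = feats[0]
        parts = f.parts if f.strand == "+" else f.parts[::-1]
        exons = tuple(
            template.seq[s:e] if st == "+" else revcomp(template.seq[s:e])
            for s, e, st in parts
        )
        refs[spec.name] = ReferenceGene(spec.name, spec.kind, exons, spec.trans_spliced)
    return refs


@dataclass
class GeneStatus:
    gene: str
    status: str  # present | duplicated | fragmented | lost
    copies: int = 0
    ir_copies: int = 0
    best_identity: float = 0.0
    best_coverage: float = 0.0
    introns_present: list = field(default_factory=list)

    def code(self) -> str:
        if self.status == "present":
            c = "P"
        elif self.status == "duplicated":
            c = f"D{self.copies}"
        elif self.status == "fragmented":
            c = "F"
        else:
            c = "L"
        if self.introns_present:
            marks = "".join(
                "i" if x else ("?" if x is None else "o") for x in self.introns_present
            )
            c += f":{marks}"
        return c


# ---------------------------------------------------------------------------
# per-genome search context


class GenomeContext:
    """Cached search state for one genome: strands, k-mer indexes, IR intervals."""

    def __init__(self, genome: AnnotatedPlastome, ir_intervals=None):
        self.genome = genome
        self.strands = {"+": genome.seq, "-": revcomp(genome.seq)}
        self._index: dict[str, dict] = {}
        if ir_intervals is None:
            ir_intervals = detect_irs(genome).intervals()
        self.ir_intervals = ir_intervals

    def index(self, strand: str) -> dict:
        if strand not in self._index:
            seq = self.strands[strand]
            idx: dict[str, list[int]] = {}
            for i in range(len(seq) - _SEED_K + 1):
                idx.setdefault(seq[i : i + _SEED_K], []).append(i)
            self._index[strand] = idx
        return self._index[strand]

    def genome_interval(self, strand: str, s: int, e: int) -> tuple[int, int]:
        n = len(self.genome.seq)
        return (s, e) if strand == "+" else (n - e, n - s)


def _find_all(hay: str, needle: str) -> list[int]:
    out, i = [], hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return out


def _best_segment(exon: str, window: str):
    """Best gap-free local segment (match +1 / mismatch -1) of exon vs window.

    Returns (ref_lo, ref_hi, matches) for the maximal-scoring run; the
    Kadane-style scan mirrors what a local aligner does when indels are absent.
    """
    L = min(len(exon), len(window))
    if L == 0:
        return 0, 0, 0
    a = seq_to_array(exon[:L])
    b = seq_to_array(window[:L])
    score = np.where((a == b) & (a != ord("N")), 1, -1)
    best = (0, 0, 0)  # (score, lo, hi)
    cur, lo = 0, 0
    for i, s in enumerate(score):
        cur += int(s)
        if cur <= 0:
            cur, lo = 0, i + 1
        elif cur > best[0]:
            best = (cur, lo, i + 1)
    sc, lo, hi = best
    matches = (hi - lo + sc) // 2
    return lo, hi, matches


@dataclass
class _ExonHit:
    exon_idx: int
    strand: str
    start: int  # strand-space start of the full expected exon placement
    ref_lo: int
    ref_hi: int
    matches: int

    @property
    def aligned(self) -> int:
        return self.ref_hi - self.ref_lo


def _exon_hits(ctx: GenomeContext, exon: str, exon_idx: int) -> list[_ExonHit]:
    hits = []
    for strand, seq in ctx.strands.items():
        starts = _find_all(seq, exon)
        if starts:
            for s in starts:
                hits.append(_ExonHit(exon_idx, strand, s, 0, len(exon), len(exon)))
            continue
        # seed-based candidates
        if len(exon) < _SEED_K:
            continue
        votes: dict[int, int] = {}
        offs = list(range(0, len(exon) - _SEED_K + 1, 8))
        for off in offs:
            for pos in ctx.index(strand).get(exon[off : off + _SEED_K], ()):
                votes[pos - off] = votes.get(pos - off, 0) + 1
        merged: dict[int, int] = {}
        for cand in sorted(votes):
            near = next((k for k in merged if abs(k - cand) <= 3), None)
            merged[near if near is not None else cand] = votes[cand]
        for cand in sorted(merged, key=lambda c: -merged[c])[:8]:
            w0 = max(0, cand)
            window = seq[w0 : cand + len(exon)]
            pad = w0 - cand  # >0 when candidate start clipped at origin
            lo, hi, matches = _best_segment(exon[pad:] if pad > 0 else exon, window)
            if matches >= _SEED_K:
                hits.append(
                    _ExonHit(exon_idx, strand, cand, lo + max(0, pad), hi + max(0, pad), matches)
                )
    return hits


@dataclass
class _Locus:
    strand: str
    exon_hits: dict[int, _ExonHit]
    span: tuple[int, int]  # strand-space

    def identity(self) -> float:
        aligned = sum(h.aligned for h in self.exon_hits.values())
        return sum(h.matches for h in self.exon_hits.values()) / aligned if aligned else 0.0

    def coverage(self, ref_len: int) -> float:
        return sum(h.aligned for h in self.exon_hits.values()) / ref_len


def _cluster_loci(ref: ReferenceGene, hits: list[_ExonHit], max_span: int = 8000):
    """Group exon hits into candidate loci by strand and genomic proximity."""
    loci = []
    for strand in ("+", "-"):
        sh = sorted((h for h in hits if h.strand == strand), key=lambda h: h.start)
        cluster: list[_ExonHit] = []
        for h in sh + [None]:
            if h is not None and (not cluster or h.start - cluster[-1].start <= max_span):
                cluster.append(h)
                continue
            if cluster:
                by_exon: dict[int, _ExonHit] = {}
                for x in cluster:
                    if x.exon_idx not in by_exon or x.matches > by_exon[x.exon_idx].matches:
                        by_exon[x.exon_idx] = x
                span = (
                    min(x.start for x in by_exon.values()),
                    max(x.start + len(ref.exons[x.exon_idx]) for x in by_exon.values()),
                )
                loci.append(_Locus(strand, by_exon, span))
            cluster = [h] if h is not None else []
    return loci


def _orf_intact(ctx: GenomeContext, ref: ReferenceGene, locus: _Locus, coverage: float) -> bool:
    """Premature-stop / completeness check on the best locus of a CDS."""
    if coverage < 0.95:
        return False
    seq = ctx.strands[locus.strand]
    pieces = []
    for i, exon in enumerate(ref.exons):
        h = locus.exon_hits.get(i)
        if h is None:
            return False
        pieces.append(seq[h.start : h.start + len(exon)])
    spliced = "".join(pieces)
    aa = translate(spliced)
    return "*" not in aa[:-1]


def classify_gene(
    g: AnnotatedPlastome | GenomeContext,
    ref_gene: ReferenceGene,
    id_thresh: float = 0.60,
    cov_thresh: float = 0.60,
) -> GeneStatus:
    """Classify one panel gene from sequence similarity over the whole genome."""
    if not ref_gene.exons or not ref_gene.spliced:
        raise InventoryError(f"empty reference for {ref_gene.name}")
    ctx = g if isinstance(g, GenomeContext) else GenomeContext(g)
    ref_len = len(ref_gene.spliced)
    hits: list[_ExonHit] = []
    for i, exon in enumerate(ref_gene.exons):
        hits.extend(_exon_hits(ctx, exon, i))
    loci = _cluster_loci(ref_gene, hits)
    scored = sorted(
        ((loc.identity(), loc.coverage(ref_len), loc) for loc in loci),
        key=lambda t: (t[1] * t[0]), reverse=True,
    )
    qualifying = []
    taken: list[tuple[int, int]] = []
    for ident, cov, loc in scored:
        if ident < id_thresh or cov < cov_thresh:
            continue
        gi = ctx.genome_interval(loc.strand, *loc.span)
        if any(_overlap(gi, t) > 0.5 * (gi[1] - gi[0]) for t in taken):
            continue
        taken.append(gi)
        qualifying.append((ident, cov, loc, gi))
    best_ident = max((t[0] for t in scored), default=0.0)
    best_cov = max((t[1] for t in scored), default=0.0)
    status = GeneStatus(ref_gene.name, "lost", copies=0,
                        best_identity=best_ident, best_coverage=best_cov)
    if not qualifying:
        return status
    ir = ctx.ir_intervals
    ir_copies = sum(
        1 for _, _, _, gi in qualifying
        if any(_overlap(gi, iv) > 0.5 * (gi[1] - gi[0]) for iv in ir)
    )
    copies = len(qualifying)
    ident, cov, best_locus, _ = qualifying[0]
    status.copies, status.ir_copies = copies, ir_copies
    status.best_identity, status.best_coverage = ident, cov
    non_ir = copies - ir_copies
    if ref_gene.kind == "CDS" and not _orf_intact(ctx, ref_gene, best_locus, cov):
        status.status = "fragmented"
    elif non_ir >= 2 or (ir_copies >= 2 and non_ir >= 1):
        status.status = "duplicated"
    else:
        status.status = "present"
    return status


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def intron_status(
    g: AnnotatedPlastome | GenomeContext,
    ref_gene: ReferenceGene,
    min_intron: int = 200,
    contig_slack: int = 20,
):
    """Per-intron presence from exon-junction spacing in the best locus.

    Intron *i* is present when exon *i* and exon *i+1* land >= ``min_intron``
    apart, absent when they are contiguous within ``contig_slack``.  Lost
    genes yield ``None`` per intron (not counted as intron loss); trans-spliced
    genes are explicitly unsupported.
    """
    if ref_gene.trans_spliced:
        return TRANS_SPLICED_UNSUPPORTED
    if ref_gene.n_introns < 1:
        raise InventoryError(f"{ref_gene.name} has no introns in the model")
    ctx = g if isinstance(g, GenomeContext) else GenomeContext(g)
    hits = []
    for i, exon in enumerate(ref_gene.exons):
        hits.extend(_exon_hits(ctx, exon, i))
    loci = _cluster_loci(ref_gene, hits)
    ref_len = len(ref_gene.spliced)
    best = max(
        (loc for loc in loci),
        key=lambda loc: loc.coverage(ref_len) * loc.identity(),
        default=None,
    )
    if best is None or best.coverage(ref_len) < 0.6 or best.identity() < 0.6:
        return [None] * ref_gene.n_introns
    out = []
    for i in range(ref_gene.n_introns):
        h1, h2 = best.exon_hits.get(i), best.exon_hits.get(i + 1)
        if h1 is None or h2 is None:
            out.append(None)
            continue
        gap = h2.start - (h1.start + len(ref_gene.exons[i]))
        out.append(True if gap >= min_intron else (False if abs(gap) <= contig_slack else None))
    return out


# ---------------------------------------------------------------------------
# the genome x gene matrix


@dataclass
class GeneStatusMatrix:
    """Complete genomes x panel grid of :class:`GeneStatus`."""

    genomes: list[str]
    genes: list[str]
    cells: dict  # (genome_id, gene) -> GeneStatus

    def status(self, genome_id: str, gene: str) -> GeneStatus:
        return self.cells[(genome_id, gene)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {g: [self.cells[(gid, g)].code() for gid in self.genomes] for g in self.genes},
            index=self.genomes,
        )

    def lost_tips(self, gene: str) -> dict[str, bool]:
        return {gid: self.cells[(gid, gene)].status == "lost" for gid in self.genomes}

    def encoded_gene_count(self, genome_id: str) -> int:
        return sum(
            1 for g in self.genes
            if self.cells[(genome_id, g)].status in ("present", "duplicated")
        )

    def cds_count(self, genome_id: str, panel=None) -> int:
        kinds = {s.name: s.kind for s in (panel or default_panel())}
        return sum(
            1 for g in self.genes
            if kinds.get(g) == "CDS"
            and self.cells[(genome_id, g)].status in ("present", "duplicated")
        )

    def to_tsv(self) -> str:
        frame = self.to_frame()
        return frame.to_csv(sep="\t", index_label="genome")


def inventory_matrix(genomes, panel: dict[str, ReferenceGene]) -> GeneStatusMatrix:
    """Classify every panel gene in every genome (complete grid)."""
    genomes = list(genomes)
    if not genomes:
        raise InventoryError("no genomes")
    cells = {}
    for g in genomes:
        ctx = GenomeContext(g)
        for name, ref in panel.items():
            st = classify_gene(ctx, ref)
            if ref.n_introns and not ref.trans_spliced:
                st.introns_present = intron_status(ctx, ref)
            cells[(g.id, name)] = st
    return GeneStatusMatrix([g.id for g in genomes], list(panel), cells)


# ---------------------------------------------------------------------------
# loss events on a phylogeny


def min_loss_events(tree, lost_tips: dict[str, bool]) -> int:
    """Minimum presence->loss transitions on a rooted tree (root = present).

    Uniform-cost small parsimony; among minimum-total-change reconstructions
    the one with fewest 1->0 transitions is reported (lexicographic Sankoff).
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        raise InventoryError("tree must be a dendropy.Tree")
    inf = (math.inf, math.inf)
    cost: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label not in lost_tips:
                raise InventoryError(f"tip {label!r} missing from the status matrix")
            observed = 0 if lost_tips[label] else 1
            cost[node] = {s: ((0, 0) if s == observed else inf) for s in (0, 1)}
        else:
            table = {}
            for s in (0, 1):
                changes, losses = 0, 0
                ok = True
                for child in node.child_nodes():
                    best = inf
                    for t in (0, 1):
                        c = cost[child][t]
                        cand = (c[0] + (s != t), c[1] + (s == 1 and t == 0))
                        if cand < best:
                            best = cand
                    if best == inf:
                        ok = False
                    changes += best[0]
                    losses += best[1]
                table[s] = (changes, losses) if ok else inf
            cost[node] = table
    root_cost = cost[tree.seed_node][1]
    if root_cost == inf:  # pragma: no cover - only if a tip state is impossible
        root_cost = min(cost[tree.seed_node].values())
    return int(root_cost[1])


def count_loss_events(matrix: GeneStatusMatrix, tree) -> dict[str, int]:
    """Per-gene minimum independent loss counts over the tree."""
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(matrix.genomes)
    if missing:
        raise InventoryError(f"tips missing from matrix: {sorted(missing)}")
    return {gene: min_loss_events(tree, matrix.lost_tips(gene)) for gene in matrix.genes}
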