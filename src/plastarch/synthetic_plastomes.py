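"""Synthetic annotated plastomes with planted events and a ground-truth manifest.

The generator builds a canonical quadripartite template (LSC + IRb + SSC + IRa
on a circle, IRa the exact reverse complement of IRb, genes placed from the
packaged panel), then applies structural events (inversions, IR boundary
shifts, IR loss/triplication, planted repeats) and gene degradations
(deletion, truncation, premature stops, intron loss, duplication).  Every
planted event is recorded in a :class:`TruthManifest` whose expectations are
phrased in terms of downstream-module outputs, so recovery tests close the
loop without external data.

Everything is driven by a single seed: (config, seed) -> byte-identical
genome and manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from ._util import STOP_CODONS, gc_fraction, revcomp
from .plastome_io import AnnotatedPlastome, GeneFeature, PlastomeError
from .reference import GeneSpec, default_panel

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration and manifest types


@dataclass
class StructuralEvent:
    """A planted structural change; ``params`` are kind-specific."""

    kind: str
    params: dict = field(default_factory=dict)

    KINDS = (
        "inversion", "ir_expand", "ir_contract", "ir_loss",
        "ir_triplicate", "insert_sir", "insert_dr", "insert_repeat",
    )

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise SimulationError(f"unknown event kind {self.kind!r}")


@dataclass
class GeneDegradation:
    """A planted gene-level degradation."""

    gene: str
    mode: str  # delete | truncate | premature_stop | intron_delete | duplicate
    fraction: float | None = None
    index: int | None = None

    def __post_init__(self):
        if self.mode in ("truncate", "premature_stop"):
            if self.fraction is None or not 0 < self.fraction < 1:
                raise SimulationError(f"{self.mode} needs fraction in (0,1)")
        if self.mode == "intron_delete" and self.index is None:
            raise SimulationError("intron_delete needs an intron index")


@dataclass
class SimulationConfig:
    seed: int = 0
    lsc_len: int = 85_000
    ssc_len: int = 17_000
    ir_len: int = 25_000
    gc_target: float = 0.37
    gene_panel: tuple[GeneSpec, ...] | None = None
    events: list[StructuralEvent] = field(default_factory=list)
    degradations: list[GeneDegradation] = field(default_factory=list)
    genome_id: str = "synthetic"

    def __post_init__(self):
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise SimulationError("region lengths must be positive")
        if not 0.2 < self.gc_target < 0.6:
            raise SimulationError("gc_target outside (0.2, 0.6)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        raw = yaml.safe_load(open(path))
        events = [StructuralEvent(**e) for e in raw.pop("events", [])]
        degs = [GeneDegradation(**d) for d in raw.pop("degradations", [])]
        return cls(events=events, degradations=degs, **raw)

    def to_yaml(self, path) -> None:
        raw = {
            "seed": self.seed, "lsc_len": self.lsc_len, "ssc_len": self.ssc_len,
            "ir_len": self.ir_len, "gc_target": self.gc_target,
            "genome_id": self.genome_id,
            "events": [dataclasses.asdict(e) for e in self.events],
            "degradations": [
                {k: v for k, v in dataclasses.asdict(d).items() if v is not None}
                for d in self.degradations
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class TruthManifest:
    """Machine-readable record of every planted event and its expected effect."""

    genome_id: str
    regions: dict = field(default_factory=dict)  # name -> [start, end)
    events: list = field(default_factory=list)
    expected_arch_class: str = "canonical"
    expected_gene_status: dict = field(default_factory=dict)
    expected_introns: dict = field(default_factory=dict)
    gene_order: list = field(default_factory=list)  # [(name, sign)] outside IRb
    template_gene_order: list = field(default_factory=list)
    expected_permutation: list | None = None
    permutation_valid: bool = True
    planted_inversions: list = field(default_factory=list)
    planted_repeats: list = field(default_factory=list)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        d["gene_order"] = [tuple(x) for x in d["gene_order"]]
        d["template_gene_order"] = [tuple(x) for x in d["template_gene_order"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# random sequence primitives


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def _random_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    """A valid ORF: ATG start, TAA stop, no internal stop codons."""
    if length % 3 or length < 9:
        raise SimulationError(f"CDS length {length} not a multiple of 3 (>= 9)")
    body = _random_seq(rng, length - 6, gc)
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    for i, codon in enumerate(codons):
        while codon in STOP_CODONS:
            codon = _random_seq(rng, 3, gc)
        codons[i] = codon
    return "ATG" + "".join(codons) + "TAA"


def _split_exons(spliced: str, introns: tuple[int, ...]) -> list[str]:
    """Split a spliced sequence into len(introns)+1 near-even exons."""
    n_ex = len(introns) + 1
    cuts = [round(len(spliced) * i / n_ex) for i in range(n_ex + 1)]
    return [spliced[a:b] for a, b in zip(cuts, cuts[1:])]


def _gene_block(rng, spec: GeneSpec, gc: float):
    """Forward-strand genomic block and exon offsets for one gene.

    Returns (block_seq, parts_rel, spliced) where parts_rel are
    (start, end, strand) offsets inside the block.
    """
    spliced = (
        _random_cds(rng, spec.length, gc) if spec.kind == "CDS"
        else _random_seq(rng, spec.length, gc)
    )
    exons = _split_exons(spliced, spec.introns)
    intron_seqs = [_random_seq(rng, L, gc) for L in spec.introns]
    strand = "+" if spec.name == "psbA" else ("+", "-")[rng.integers(2)]
    pieces, offsets, off = [], [], 0
    for i, ex in enumerate(exons):
        offsets.append((off, off + len(ex)))
        pieces.append(ex)
        off += len(ex)
        if i < len(intron_seqs):
            pieces.append(intron_seqs[i])
            off += len(intron_seqs[i])
    fwd = "".join(pieces)
    if strand == "+":
        parts = [(s, e, "+") for s, e in offsets]
    else:
        fwd = revcomp(fwd)
        L = len(fwd)
        parts = sorted((L - e, L - s, "-") for s, e in offsets)
    return fwd, parts, spliced


def _assemble_region(rng, specs, region_len: int, gc: float, min_gap: int = 30):
    """Lay out genes with random intergenic gaps filling ``region_len`` exactly."""
    blocks = [_gene_block(rng, s, gc) for s in specs]
    used = sum(len(b[0]) for b in blocks)
    n_gaps = len(specs) + 1
    spare = region_len - used - min_gap * n_gaps
    if spare < 0:
        raise SimulationError(
            f"panel needs {used + min_gap * n_gaps} bp but region is {region_len} bp"
        )
    extra = rng.multinomial(spare, np.full(n_gaps, 1 / n_gaps))
    gaps = [min_gap + int(x) for x in extra]
    seq_parts, feats, pos = [], [], 0
    gap_ivs = []
    for gap, spec, (block, parts, _) in zip(gaps, specs, blocks):
        seq_parts.append(_random_seq(rng, gap, gc))
        gap_ivs.append((pos, pos + gap))
        pos += gap
        feats.append(
            GeneFeature(spec.name, spec.kind, [(pos + s, pos + e, st) for s, e, st in parts])
        )
        seq_parts.append(block)
        pos += len(block)
    seq_parts.append(_random_seq(rng, gaps[-1], gc))
    gap_ivs.append((pos, pos + gaps[-1]))
    return "".join(seq_parts), feats, gap_ivs


def _mirror_feature(f: GeneFeature, region_len: int, out_offset: int) -> GeneFeature:
    """Feature of the reverse-complemented copy of a region."""
    parts = sorted(
        (out_offset + region_len - e, out_offset + region_len - s, "-" if st == "+" else "+")
        for s, e, st in f.parts
    )
    return GeneFeature(f.name, f.kind, parts, f.pseudo)


def _tune_gc(seqs: dict[str, str], gap_ivs: dict[str, list], gc_target: float, rng):
    """Flip intergenic A/T <-> G/C bases so every region hits the GC target.

    Coding sequence runs slightly GC-rich (stop-codon avoidance), so the
    intergenic spacers are adjusted region by region — the real-plastome
    pattern of AT-rich intergenic DNA.  IRa mirrors IRb, so tuning IRb tunes
    both copies.
    """
    out = {}
    for k, s in seqs.items():
        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        current = s.count("G") + s.count("C")
        need = round(gc_target * len(s)) - current
        if need == 0:
            out[k] = s
            continue
        want_gc = need > 0
        source = BASES[[0, 3]] if want_gc else BASES[[1, 2]]
        candidates = []
        for a, b in gap_ivs[k]:
            window = arr[a:b]
            candidates.extend(a + int(off) for off in np.flatnonzero(np.isin(window, source)))
        rng.shuffle(candidates)
        flip_to = (ord("G"), ord("C")) if want_gc else (ord("A"), ord("T"))
        for pos in candidates[: abs(need)]:
            arr[pos] = flip_to[pos % 2]
        out[k] = arr.tobytes().decode()
    return out


# ---------------------------------------------------------------------------
# template construction


def _rng_streams(seed: int):
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(3)]


def build_template(cfg: SimulationConfig):
    """Canonical quadripartite template: LSC + IRb + SSC + IRa, IRa == revcomp(IRb)."""
    rng = _rng_streams(cfg.seed)[0]
    panel = cfg.gene_panel or default_panel()
    by_region = {r: [s for s in panel if s.region == r] for r in ("LSC", "IR", "SSC")}
    gc = cfg.gc_target
    lsc_seq, lsc_feats, lsc_gaps = _assemble_region(rng, by_region["LSC"], cfg.lsc_len, gc)
    irb_seq, irb_feats, irb_gaps = _assemble_region(rng, by_region["IR"], cfg.ir_len, gc)
    ssc_seq, ssc_feats, ssc_gaps = _assemble_region(rng, by_region["SSC"], cfg.ssc_len, gc)
    tuned = _tune_gc(
        {"LSC": lsc_seq, "IRb": irb_seq, "SSC": ssc_seq},
        {"LSC": lsc_gaps, "IRb": irb_gaps, "SSC": ssc_gaps},
        gc, rng,
    )
    lsc_seq, irb_seq, ssc_seq = tuned["LSC"], tuned["IRb"], tuned["SSC"]
    # pin the single-copy edge bases (all intergenic) so the exact IR copies
    # cannot extend by chance into the flanks, whatever the rotation frame:
    # extension across a junction needs the two flanking bases complementary
    ssc_seq = "A" + ssc_seq[1:-1] + "A"
    lsc_seq = "A" + lsc_seq[1:-1] + "A"
    ira_seq = revcomp(irb_seq)
    L, I, S = cfg.lsc_len, cfg.ir_len, cfg.ssc_len
    irb_off, ssc_off, ira_off = L, L + I, L + I + S
    feats: list[GeneFeature] = []
    for f in lsc_feats:
        feats.append(f)
    for f in irb_feats:
        feats.append(GeneFeature(f.name, f.kind,
                                 [(irb_off + s, irb_off + e, st) for s, e, st in f.parts]))
    for f in ssc_feats:
        feats.append(GeneFeature(f.name, f.kind,
                                 [(ssc_off + s, ssc_off + e, st) for s, e, st in f.parts]))
    for f in irb_feats:
        feats.append(_mirror_feature(f, I, ira_off))
    genome = AnnotatedPlastome(
        id=cfg.genome_id, seq=lsc_seq + irb_seq + ssc_seq + ira_seq,
        features=feats, circular=True, taxon=f"Synthetica {cfg.genome_id}",
        family="Synthetaceae", source="plastarch.synthetic_plastomes",
    )
    genome.validate()
    manifest = TruthManifest(
        genome_id=cfg.genome_id,
        regions={"LSC": [0, L], "IRb": [L, L + I], "SSC": [L + I, L + I + S],
                 "IRa": [L + I + S, L + 2 * I + S]},
        expected_gene_status={s.name: "present" for s in panel},
        expected_introns={s.name: [True] * len(s.introns) for s in panel if s.introns},
    )
    manifest.gene_order = _anchor_order(genome, manifest)
    manifest.template_gene_order = list(manifest.gene_order)
    return genome, manifest


def _anchor_order(g: AnnotatedPlastome, manifest: TruthManifest):
    """(gene, sign) for single-annotation genes outside IRb, in genomic order."""
    ib0, ib1 = manifest.regions.get("IRb", (0, 0))
    counts: dict[str, int] = {}
    kept = []
    for f in g.sorted_features():
        if f.start >= ib0 and f.end <= ib1:
            continue
        counts[f.name] = counts.get(f.name, 0) + 1
        kept.append(f)
    return [
        (f.name, 1 if f.strand == "+" else -1) for f in kept if counts[f.name] == 1
    ]


# ---------------------------------------------------------------------------
# sequence-edit helpers (feature-safe)


def _shifted(parts, pos, delta):
    out = []
    for s, e, st in parts:
        if s >= pos:
            out.append((s + delta, e + delta, st))
        elif e <= pos:
            out.append((s, e, st))
        else:
            raise SimulationError(f"edit at {pos} cuts a feature part ({s},{e})")
    return out


def _insert(g: AnnotatedPlastome, pos: int, ins: str, new_feats=()):
    feats = [GeneFeature(f.name, f.kind, _shifted(f.parts, pos, len(ins)), f.pseudo)
             for f in g.features]
    feats.extend(new_feats)
    return dataclasses.replace(g, seq=g.seq[:pos] + ins + g.seq[pos:], features=feats)


def _delete(g: AnnotatedPlastome, start: int, end: int):
    """Remove ``[start, end)``; parts wholly inside vanish, others shift.

    A part straddling a deletion edge is an error (the generator always cuts
    at feature-free or intron positions).
    """
    delta = end - start
    feats = []
    for f in g.features:
        parts = []
        for s, e, st in f.parts:
            if s >= start and e <= end:
                continue  # part removed with the segment
            if e <= start:
                parts.append((s, e, st))
            elif s >= end:
                parts.append((s - delta, e - delta, st))
            else:
                raise SimulationError(
                    f"deletion [{start},{end}) cuts a part of feature {f.name}"
                )
        if parts:
            feats.append(GeneFeature(f.name, f.kind, parts, f.pseudo))
    return dataclasses.replace(g, seq=g.seq[:start] + g.seq[end:], features=feats)


def _invert(g: AnnotatedPlastome, start: int, end: int, on_feature: str = "reject"):
    """Reverse-complement ``[start, end)``; inside features flip and mirror."""
    feats = []
    for f in g.features:
        if f.start >= end or f.end <= start:
            feats.append(f.copy())
        elif f.start >= start and f.end <= end:
            parts = sorted(
                (start + end - e, start + end - s, "-" if st == "+" else "+")
                for s, e, st in f.parts
            )
            feats.append(GeneFeature(f.name, f.kind, parts, f.pseudo))
        elif on_feature == "split":
            for piece, flag in _clip_parts(f, start, end):
                feats.append(piece)
        else:
            raise SimulationError(f"inversion [{start},{end}) cuts feature {f.name}")
    seq = g.seq[:start] + revcomp(g.seq[start:end]) + g.seq[end:]
    return dataclasses.replace(g, seq=seq, features=feats)


def _clip_parts(f: GeneFeature, start: int, end: int):
    """Split a boundary-straddling feature into flagged inside/outside fragments."""
    inside, outside = [], []
    for s, e, st in f.parts:
        if e <= start or s >= end:
            outside.append((s, e, st))
            continue
        if s < start:
            outside.append((s, start, st))
        if e > end:
            outside.append((end, e, st))
        a, b = max(s, start), min(e, end)
        inside.append((start + end - b, start + end - a, "-" if st == "+" else "+"))
    out = []
    if outside:
        out.append((GeneFeature(f.name, f.kind, outside, pseudo=True), True))
    if inside:
        out.append((GeneFeature(f.name, f.kind, sorted(inside), pseudo=True), True))
    return out


def intergenic_gaps(g: AnnotatedPlastome, within=None, min_len: int = 1):
    """Feature-free intervals, optionally restricted to ``within=(start, end)``."""
    lo, hi = within if within else (0, len(g.seq))
    edges = [(lo, lo)] + sorted(
        (max(f.start, lo), min(f.end, hi)) for f in g.features
        if f.start < hi and f.end > lo
    ) + [(hi, hi)]
    gaps = []
    cursor = lo
    for s, e in edges:
        if s - cursor >= min_len:
            gaps.append((cursor, s))
        cursor = max(cursor, e)
    return gaps


def _shift_regions(regions: dict, pos: int, delta: int):
    for name, (s, e) in list(regions.items()):
        regions[name] = [s + delta if s >= pos else s, e + delta if e > pos else e]


# ---------------------------------------------------------------------------
# structural events


def apply_events(g: AnnotatedPlastome, events, manifest: TruthManifest, rng=None):
    """Apply structural events in order, updating genome and manifest."""
    rng = rng or np.random.default_rng(0)
    for ev in events:
        handler = _EVENT_HANDLERS[ev.kind]
        g = handler(g, manifest, rng, **ev.params)
        manifest.events.append({"kind": ev.kind, **_jsonable(ev.params)})
    return g, manifest


def _jsonable(params):
    return {k: (int(v) if isinstance(v, (np.integer,)) else v) for k, v in params.items()}


def _ev_inversion(g, manifest, rng, start: int, end: int, on_feature: str = "reject"):
    inside = [f.name for f in g.features if f.start >= start and f.end <= end]
    g2 = _invert(g, start, end, on_feature=on_feature)
    manifest.planted_inversions.append(
        {"start": int(start), "end": int(end), "genes": inside}
    )
    names = set(inside)
    idxs = [i for i, (n, _) in enumerate(manifest.gene_order) if n in names]
    if idxs:
        if idxs != list(range(idxs[0], idxs[-1] + 1)):
            manifest.permutation_valid = False
        else:
            a, b = idxs[0], idxs[-1] + 1
            manifest.gene_order[a:b] = [
                (n, -s) for n, s in reversed(manifest.gene_order[a:b])
            ]
    return g2


def _ev_ir_expand(g, manifest, rng, shift: int, into: str = "ssc"):
    """Extend both IR copies by duplicating ``shift`` bp of the donor region."""
    (ib0, ib1), (ia0, ia1) = manifest.regions["IRb"], manifest.regions["IRa"]
    if into == "ssc":
        donor = (ib1, ib1 + shift)
        mirror_at = ia0
    else:
        donor = (ib0 - shift, ib0)
        mirror_at = ia1
    for f in g.features:
        if f.start < donor[0] < f.end or f.start < donor[1] < f.end:
            raise SimulationError(f"ir_expand boundary cuts feature {f.name}")
    # pin the bases flanking the new IR junctions (both intergenic) so the
    # enlarged exact copies stop exactly at the planted boundaries
    if into == "ssc":
        g = _set_base(g, donor[1], "A")
        g = _set_base(g, ia0 - 1, "A")
    else:
        g = _set_base(g, donor[0] - 1, "A")
        g = _set_base(g, manifest.regions["LSC"][0], "A")
    dseq = g.seq[donor[0] : donor[1]]
    absorbed = [f for f in g.features if f.start >= donor[0] and f.end <= donor[1]]
    new_feats = [
        GeneFeature(
            f.name, f.kind,
            sorted((mirror_at + donor[1] - e, mirror_at + donor[1] - s,
                    "-" if st == "+" else "+") for s, e, st in f.parts),
            f.pseudo,
        )
        for f in absorbed
    ]
    g2 = _insert(g, mirror_at, revcomp(dseq), new_feats)
    _shift_regions(manifest.regions, mirror_at, shift)
    if into == "ssc":
        manifest.regions["IRb"][1] += shift
        manifest.regions["SSC"][0] += shift
        manifest.regions["IRa"][0] -= shift
    else:
        manifest.regions["IRb"][0] -= shift
        manifest.regions["LSC"][1] -= shift
        manifest.regions["IRa"][1] += shift
    relocated = [f.name for f in absorbed]
    if relocated and manifest.expected_arch_class == "canonical":
        manifest.expected_arch_class = "expanded"
    manifest.permutation_valid = False
    manifest.events.append({"kind": "_relocated", "genes": relocated})
    return g2


def _set_base(g: AnnotatedPlastome, pos: int, base: str) -> AnnotatedPlastome:
    return _replace_span(g, pos, pos + 1, base)


def _ev_ir_contract(g, manifest, rng, shift: int):
    """Retract the IR boundary on the SSC side: IRb tail becomes single-copy."""
    (ib0, ib1), (ia0, ia1) = manifest.regions["IRb"], manifest.regions["IRa"]
    zone = (ib1 - shift, ib1)
    for f in g.features:
        if f.start < zone[0] < f.end:
            raise SimulationError(f"ir_contract boundary cuts feature {f.name}")
    expelled = [f.name for f in g.features if f.start >= zone[0] and f.end <= zone[1]]
    # pin the new junction flanks (intergenic) so the shortened exact copies
    # stop exactly at the planted boundary
    g = _set_base(g, zone[0], "A")
    g = _set_base(g, ia0 - 1, "A")
    # the IRa mirror of the retracted tail is its first `shift` bases
    g2 = _delete(g, ia0, ia0 + shift)
    manifest.regions["IRb"] = [ib0, ib1 - shift]
    manifest.regions["SSC"] = [ib1 - shift, ia0]
    manifest.regions["IRa"] = [ia0, ia1 - shift]
    if expelled and manifest.expected_arch_class == "canonical":
        manifest.expected_arch_class = "contracted"
    manifest.permutation_valid = False
    manifest.events.append({"kind": "_expelled", "genes": expelled})
    return g2


def _ev_ir_loss(g, manifest, rng, copy: str = "IRa"):
    s, e = manifest.regions[copy]
    lost = sorted({f.name for f in g.features if f.start >= s and f.end <= e})
    g2 = _delete(g, s, e)
    _shift_regions(manifest.regions, e, -(e - s))
    del manifest.regions[copy]
    manifest.regions["IRb_relic"] = manifest.regions.pop("IRb")
    manifest.expected_arch_class = "unresolved"
    manifest.permutation_valid = False
    manifest.events.append({"kind": "_ir_lost_copies", "genes": lost})
    return g2


def _ev_ir_triplicate(g, manifest, rng, length: int, at: int | None = None):
    """Insert a third IR copy (IRc): a prefix of IRa, same orientation as IRa."""
    ia0, ia1 = manifest.regions["IRa"]
    length = min(length, ia1 - ia0)
    # trim the copy end to the nearest feature-free point
    while any(f.start < ia0 + length < f.end for f in g.features):
        length += 1
        if ia0 + length > ia1:
            raise SimulationError("cannot place IRc boundary outside a feature")
    cseq = g.seq[ia0 : ia0 + length]
    inside = [f for f in g.features if f.start >= ia0 and f.end <= ia0 + length]
    if at is None:
        lsc = manifest.regions["LSC"]
        gaps = intergenic_gaps(g, within=tuple(lsc), min_len=60)
        s, e = gaps[rng.integers(len(gaps))]
        at = (s + e) // 2
    new_feats = [
        GeneFeature(f.name, f.kind,
                    [(at + s - ia0, at + e - ia0, st) for s, e, st in f.parts], f.pseudo)
        for f in inside
    ]
    g2 = _insert(g, at, cseq, new_feats)
    _shift_regions(manifest.regions, at, length)
    manifest.regions["IRc"] = [at, at + length]
    manifest.expected_arch_class = "triple_IR"
    manifest.permutation_valid = False
    return g2


def _insert_pair(g, manifest, rng, length: int, inverted: bool, label: str,
                 identity: float = 1.0, kind_out: str | None = None):
    gc = gc_fraction(g.seq)
    seg = _random_seq(rng, length, gc)
    partner = np.frombuffer(seg.encode(), dtype=np.uint8).copy()
    n_mut = round((1 - identity) * length)
    if n_mut:
        sites = rng.choice(length, size=n_mut, replace=False)
        for pos in sites:
            alt = partner[pos]
            while alt == partner[pos]:
                alt = BASES[rng.integers(4)]
            partner[pos] = alt
    partner = partner.tobytes().decode()
    if inverted:
        partner = revcomp(partner)
    # place copies in single-copy space only, so the exact IR stays exact
    allowed = [tuple(manifest.regions[r]) for r in ("LSC", "SSC") if r in manifest.regions]
    gaps = [
        gv for gv in intergenic_gaps(g, min_len=60)
        if any(gv[0] >= a and gv[1] <= b for a, b in allowed)
    ] or list(intergenic_gaps(g, min_len=60))
    if len(gaps) < 2:
        raise SimulationError("not enough intergenic space for a repeat pair")
    i1, i2 = sorted(rng.choice(len(gaps), size=2, replace=False))
    p1 = sum(gaps[i1]) // 2
    p2 = sum(gaps[i2]) // 2
    g2 = _insert(g, p2, partner)
    _shift_regions(manifest.regions, p2, length)
    g2 = _insert(g2, p1, seg)
    _shift_regions(manifest.regions, p1, length)
    manifest.planted_repeats.append(
        {"label": label, "kind": kind_out or ("palindromic" if inverted else "forward"),
         "pos1": int(p1), "pos2": int(p2 + length), "length": int(length),
         "mismatches": int(n_mut)}
    )
    return g2


def _ev_insert_sir(g, manifest, rng, length: int = 600):
    g2 = _insert_pair(g, manifest, rng, length, inverted=True, label="sIR")
    if manifest.expected_arch_class == "unresolved":
        manifest.expected_arch_class = "ir_loss_sIR"
    return g2


def _ev_insert_dr(g, manifest, rng, length: int = 1650):
    g2 = _insert_pair(g, manifest, rng, length, inverted=False, label="DR")
    if manifest.expected_arch_class == "unresolved":
        manifest.expected_arch_class = "ir_loss_DR"
    return g2


def _ev_insert_repeat(g, manifest, rng, length: int = 100, kind: str = "forward",
                      identity: float = 1.0):
    if kind == "reverse":
        # reversed-only partner: build inverted then complement back
        g2 = _insert_pair(g, manifest, rng, length, inverted=False, label="repeat",
                          identity=identity, kind_out="reverse")
        rec = manifest.planted_repeats[-1]
        p2, L = rec["pos2"], rec["length"]
        seq = g2.seq
        seg = seq[p2 : p2 + L][::-1]
        g2 = dataclasses.replace(g2, seq=seq[:p2] + seg + seq[p2 + L :])
        return g2
    return _insert_pair(g, manifest, rng, length, inverted=(kind == "palindromic"),
                        label="repeat", identity=identity, kind_out=kind)


_EVENT_HANDLERS = {
    "inversion": _ev_inversion,
    "ir_expand": _ev_ir_expand,
    "ir_contract": _ev_ir_contract,
    "ir_loss": _ev_ir_loss,
    "ir_triplicate": _ev_ir_triplicate,
    "insert_sir": _ev_insert_sir,
    "insert_dr": _ev_insert_dr,
    "insert_repeat": _ev_insert_repeat,
}


# ---------------------------------------------------------------------------
# gene degradations


def degrade_genes(g: AnnotatedPlastome, degradations, manifest: TruthManifest, rng=None):
    """Apply gene degradations; manifest expectations follow the 60% status rules."""
    rng = rng or np.random.default_rng(0)
    for d in degradations:
        feats = g.genes(d.gene)
        if not feats:
            raise SimulationError(f"degradation targets unknown gene {d.gene}")
        handler = _DEG_HANDLERS[d.mode]
        g = handler(g, manifest, rng, d, feats)
        manifest.events.append({"kind": f"degrade_{d.mode}", "gene": d.gene})
    return g, manifest


def _replace_span(g, start, end, replacement):
    assert len(replacement) == end - start
    return dataclasses.replace(
        g, seq=g.seq[:start] + replacement + g.seq[end:], features=list(g.features)
    )


def _deg_delete(g, manifest, rng, d, feats):
    gc = gc_fraction(g.seq)
    for f in feats:
        g = _replace_span(g, f.start, f.end, _random_seq(rng, f.end - f.start, gc))
    g = dataclasses.replace(g, features=[f for f in g.features if f.name != d.gene])
    manifest.expected_gene_status[d.gene] = "lost"
    manifest.expected_introns.pop(d.gene, None)
    manifest.gene_order = [(n, s) for n, s in manifest.gene_order if n != d.gene]
    return g


def _deg_truncate(g, manifest, rng, d, feats):
    f = feats[0]
    if len(feats) > 1 or f.n_introns:
        raise SimulationError("truncate supports single-copy intronless genes")
    if f.kind == "CDS":
        keep = (int((f.end - f.start) * d.fraction) // 3) * 3
    else:
        keep = int((f.end - f.start) * d.fraction)
    gc = gc_fraction(g.seq)
    s, e, st = f.parts[0]
    if st == "+":
        cut = (s + keep, e)
        new_part = (s, s + keep, st)
    else:
        cut = (s, e - keep)
        new_part = (e - keep, e, st)
    g = _replace_span(g, cut[0], cut[1], _random_seq(rng, cut[1] - cut[0], gc))
    feats_new = [x for x in g.features if x is not f and x.name != d.gene]
    feats_new.append(GeneFeature(f.name, f.kind, [new_part], pseudo=True))
    g = dataclasses.replace(g, features=feats_new)
    realized = keep / (f.end - f.start)
    manifest.expected_gene_status[d.gene] = "fragmented" if realized >= 0.6 else "lost"
    return g


def _deg_premature_stop(g, manifest, rng, d, feats):
    f = feats[0]
    if f.kind != "CDS":
        raise SimulationError(f"premature_stop invalid for {f.kind} gene {d.gene}")
    spliced_len = sum(e - s for s, e, _ in f.parts)
    n_cod = spliced_len // 3
    c = min(max(1, int(n_cod * d.fraction)), n_cod - 2)
    # map spliced codon offset to a genomic interval within one exon
    model_parts = f.parts if f.strand == "+" else f.parts[::-1]
    target = None
    while target is None:
        off = 3 * c
        walked = 0
        for s, e, st in model_parts:
            if walked <= off and off + 3 <= walked + (e - s):
                rel = off - walked
                target = (s + rel, s + rel + 3) if st == "+" else (e - rel - 3, e - rel)
                break
            walked += e - s
        else:  # codon straddles an exon junction; nudge one codon downstream
            c += 1
            if c >= n_cod - 1:
                raise SimulationError("no in-frame position available")
    stop = "TAA" if f.strand == "+" else revcomp("TAA")
    g = _replace_span(g, target[0], target[1], stop)
    g.features[g.features.index(f)] = GeneFeature(f.name, f.kind, f.parts, pseudo=True)
    manifest.expected_gene_status[d.gene] = "fragmented"
    return g


def _deg_intron_delete(g, manifest, rng, d, feats):
    f = feats[0]
    if f.n_introns == 0:
        raise SimulationError(f"{d.gene} has no introns")
    gap_idx = d.index if f.strand == "+" else f.n_introns - 1 - d.index
    start, end = f.parts[gap_idx][1], f.parts[gap_idx + 1][0]
    g = _delete(g, start, end)
    _shift_regions(manifest.regions, end, -(end - start))
    # the two exons are now adjacent; merge them into one part
    feats = []
    for x in g.features:
        if x.name != d.gene:
            feats.append(x)
            continue
        merged: list[tuple[int, int, str]] = []
        for p in x.parts:
            if merged and merged[-1][1] == p[0] and merged[-1][2] == p[2]:
                merged[-1] = (merged[-1][0], p[1], p[2])
            else:
                merged.append(p)
        feats.append(GeneFeature(x.name, x.kind, merged, x.pseudo))
    g = dataclasses.replace(g, features=feats)
    manifest.expected_introns[d.gene][d.index] = False
    return g


def _deg_duplicate(g, manifest, rng, d, feats):
    f = feats[0]
    if len(feats) > 1:
        raise SimulationError("duplicate expects a single-copy gene")
    span = g.seq[f.start : f.end]
    # the new copy goes into single-copy space (an IR insertion would break
    # copy symmetry) and well away from the original so the loci are distinct
    allowed = [tuple(manifest.regions[r]) for r in ("LSC", "SSC") if r in manifest.regions]
    gaps = [
        gv for gv in intergenic_gaps(g, min_len=len(span) // 20 + 60)
        if abs((gv[0] + gv[1]) // 2 - f.start) > 10_000
        and any(gv[0] >= a and gv[1] <= b for a, b in allowed)
    ]
    if not gaps:
        raise SimulationError(f"no distant gap available to duplicate {d.gene}")
    s, e = gaps[rng.integers(len(gaps))]
    at = (s + e) // 2
    copy_feat = GeneFeature(
        f.name, f.kind, [(at + ps - f.start, at + pe - f.start, st) for ps, pe, st in f.parts]
    )
    g = _insert(g, at, span, [copy_feat])
    _shift_regions(manifest.regions, at, len(span))
    manifest.expected_gene_status[d.gene] = "duplicated"
    manifest.gene_order = [(n, s) for n, s in manifest.gene_order if n != d.gene]
    return g


_DEG_HANDLERS = {
    "delete": _deg_delete,
    "truncate": _deg_truncate,
    "premature_stop": _deg_premature_stop,
    "intron_delete": _deg_intron_delete,
    "duplicate": _deg_duplicate,
}


# ---------------------------------------------------------------------------
# top-level drivers


def simulate(cfg: SimulationConfig):
    """Template + events + degradations, fully determined by ``cfg.seed``."""
    _, rng_ev, rng_deg = _rng_streams(cfg.seed)
    g, manifest = build_template(cfg)
    g, manifest = apply_events(g, cfg.events, manifest, rng_ev)
    g, manifest = degrade_genes(g, cfg.degradations, manifest, rng_deg)
    if manifest.permutation_valid:
        manifest.expected_permutation = expected_permutation(manifest)
    else:
        manifest.expected_permutation = None
    g.validate()
    return g, manifest


def expected_permutation(manifest: TruthManifest) -> list[int]:
    """Signed block permutation implied by the manifest's gene bookkeeping."""
    from .rearrangement import collapse_signed_sequence

    template = [n for n, _ in manifest.template_gene_order]
    tsign = dict(manifest.template_gene_order)
    present = {n for n, _ in manifest.gene_order}
    ranked = [n for n in template if n in present]
    rank = {n: i + 1 for i, n in enumerate(ranked)}
    seq = [
        (1 if s == tsign[n] else -1) * rank[n]
        for n, s in manifest.gene_order
        if n in rank
    ]
    return collapse_signed_sequence(seq)


def save_simulation(g: AnnotatedPlastome, manifest: TruthManifest, outdir) -> None:
    from pathlib import Path

    from .plastome_io import write_genome

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(g, outdir / f"{g.id}.gb", "genbank")
    write_genome(g, outdir / f"{g.id}.fasta", "fasta+table")
    (outdir / f"{g.id}.manifest.json").write_text(manifest.to_json())


# ---------------------------------------------------------------------------
# planners used by recovery tests and the acceptance script


def plan_inversions(g: AnnotatedPlastome, rng, k: int, region=(None, None)):
    """``k`` non-interleaving gene-bearing inversion intervals inside the LSC.

    Intervals are separated by at least one untouched gene, so the expected
    reversal distance equals ``k``.
    """
    lo = region[0] if region[0] is not None else 0
    hi = region[1] if region[1] is not None else len(g.seq)
    feats = [f for f in g.sorted_features() if f.start >= lo and f.end <= hi]
    if feats:  # keep the frame anchor out of any interval
        lo = max(lo, feats[0].end)
        feats = feats[1:]
    if k == 0:
        return []
    if 3 * k + 1 > len(feats):
        raise SimulationError(f"not enough genes for {k} separated inversions")
    # choose k disjoint gene runs separated by >= 1 gene
    cuts = sorted(rng.choice(len(feats) - 2 * k, size=2 * k, replace=False))
    bounds = [c + i for i, c in enumerate(cuts)]  # enforce separation
    events = []
    for a, b in zip(bounds[::2], bounds[1::2]):
        first, last = feats[a], feats[b]
        prev_end = feats[a - 1].end if a > 0 else lo
        next_start = feats[b + 1].start if b + 1 < len(feats) else hi
        start = (prev_end + first.start) // 2
        end = (last.end + next_start) // 2
        events.append(StructuralEvent("inversion", {"start": int(start), "end": int(end)}))
    return events


def architecture_scenario(arch_class: str, seed: int, genome_id: str | None = None):
    """A SimulationConfig planting exactly one architecture class."""
    cfg = SimulationConfig(seed=seed, genome_id=genome_id or f"{arch_class}_{seed}")
    if arch_class == "canonical":
        events = []
    elif arch_class == "expanded":
        events = [StructuralEvent("ir_expand", {"shift": None, "into": "ssc"})]
    elif arch_class == "contracted":
        events = [StructuralEvent("ir_contract", {"shift": None})]
    elif arch_class == "triple_IR":
        events = [StructuralEvent("ir_triplicate", {"length": 8000})]
    elif arch_class == "ir_loss_sIR":
        events = [StructuralEvent("ir_loss", {}), StructuralEvent("insert_sir", {"length": 600})]
    elif arch_class == "ir_loss_DR":
        events = [StructuralEvent("ir_loss", {}), StructuralEvent("insert_dr", {"length": 1650})]
    else:
        raise SimulationError(f"unknown architecture class {arch_class!r}")
    cfg.events = events
    return cfg


def simulate_architecture(arch_class: str, seed: int, genome_id: str | None = None):
    """Simulate one genome of the requested class, resolving boundary shifts."""
    cfg = architecture_scenario(arch_class, seed, genome_id)
    _, rng_ev, rng_deg = _rng_streams(cfg.seed)
    g, manifest = build_template(cfg)
    for ev in cfg.events:
        if ev.kind == "ir_expand" and ev.params.get("shift") is None:
            ev.params["shift"] = _shift_absorbing_first_gene(g, manifest)
        if ev.kind == "ir_contract" and ev.params.get("shift") is None:
            ev.params["shift"] = _shift_expelling_last_gene(g, manifest)
    g, manifest = apply_events(g, cfg.events, manifest, rng_ev)
    g, manifest = degrade_genes(g, cfg.degradations, manifest, rng_deg)
    manifest.expected_permutation = None
    g.validate()
    return g, manifest


def _shift_absorbing_first_gene(g, manifest):
    """Expansion shift reaching the gap just past the first SSC gene."""
    ss0, ss1 = manifest.regions["SSC"]
    first = min((f for f in g.features if f.start >= ss0 and f.end <= ss1),
                key=lambda f: f.start)
    nxt = min((f.start for f in g.features if f.start >= first.end), default=ss1)
    return (first.end + min(nxt, ss1)) // 2 - ss0


def _shift_expelling_last_gene(g, manifest):
    """Contraction shift expelling the IR gene nearest the SSC boundary."""
    ib0, ib1 = manifest.regions["IRb"]
    inside = [f for f in g.features if f.start >= ib0 and f.end <= ib1]
    last = max(inside, key=lambda f: f.end)
    prev_end = max((f.end for f in inside if f.end < last.start), default=ib0)
    return ib1 - (prev_end + last.start) // 2


def plan_degradations(rng, n: int = 9, panel=None) -> list[GeneDegradation]:
    """``n`` degradations over distinct genes, cycling through every mode.

    Truncations alternate between a fraction below the 60% coverage rule
    (expected lost) and one above it (expected fragmented); premature stops
    land at varied in-frame positions.  Intron deletions target single-copy
    intron-bearing genes; duplications and truncations target single-copy
    intronless genes.
    """
    panel = panel or default_panel()
    single = [s for s in panel if s.region != "IR"]
    cds_plain = [s.name for s in single if s.kind == "CDS" and not s.introns
                 and s.length >= 150]
    intronful = [s.name for s in single if s.introns and not s.trans_spliced]
    deletable = [s.name for s in single if s.length >= 60]
    rng.shuffle(cds_plain)
    rng.shuffle(intronful)
    rng.shuffle(deletable)
    used: set[str] = set()

    def take(pool):
        for name in pool:
            if name not in used:
                used.add(name)
                return name
        raise SimulationError("degradation pool exhausted")

    out = []
    modes = ["delete", "truncate_lost", "truncate_frag", "premature_stop",
             "intron_delete", "duplicate"]
    for i in range(n):
        mode = modes[i % len(modes)]
        if mode == "delete":
            out.append(GeneDegradation(take(deletable), "delete"))
        elif mode == "truncate_lost":
            out.append(GeneDegradation(take(cds_plain), "truncate",
                                       fraction=float(rng.uniform(0.3, 0.5))))
        elif mode == "truncate_frag":
            out.append(GeneDegradation(take(cds_plain), "truncate",
                                       fraction=float(rng.uniform(0.7, 0.9))))
        elif mode == "premature_stop":
            out.append(GeneDegradation(take(cds_plain), "premature_stop",
                                       fraction=float(rng.uniform(0.2, 0.7))))
        elif mode == "intron_delete":
            gene = take(intronful)
            spec = next(s for s in panel if s.name == gene)
            out.append(GeneDegradation(gene, "intron_delete",
                                       index=int(rng.integers(len(spec.introns)))))
        else:
            out.append(GeneDegradation(take(cds_plain), "duplicate"))
    return out


def simulate_cohort(n: int, seed: int, link_strength: float = 3.0):
    """A cohort where planted repeat load drives planted inversion count.

    Genome sizes, GC, repeat pair counts and inversion counts all vary; the
    number of inversions tracks repeats / ``link_strength`` plus noise,
    emulating repeat-mediated rearrangement.  Returns
    ``(template, genome, manifest)`` triples — rearrangement truth is defined
    against each genome's own undisturbed template.
    """
    master = np.random.default_rng(seed)
    out = []
    for i in range(n):
        sub = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub)
        n_rep = int(rng.integers(0, 25))
        n_inv = int(np.clip(round(n_rep / link_strength + rng.normal(0, 1)), 0, 12))
        cfg = SimulationConfig(
            seed=sub,
            lsc_len=int(rng.integers(78_000, 100_001)),
            ssc_len=int(rng.integers(16_500, 21_001)),
            ir_len=int(rng.integers(21_000, 30_001)),
            gc_target=float(rng.uniform(0.31, 0.39)),
            genome_id=f"cohort_{i:02d}",
        )
        _, rng_ev, rng_deg = _rng_streams(cfg.seed)
        g, manifest = build_template(cfg)
        template = g
        rep_events = [
            StructuralEvent("insert_repeat", {
                "length": int(rng.integers(40, 400)),
                "kind": ("forward", "palindromic", "reverse")[int(rng.integers(3))],
            })
            for _ in range(n_rep)
        ]
        g, manifest = apply_events(g, rep_events, manifest, rng_ev)
        inv_events = plan_inversions(g, rng_ev, n_inv, region=(0, manifest.regions["LSC"][1]))
        g, manifest = apply_events(g, inv_events, manifest, rng_ev)
        if manifest.permutation_valid:
            manifest.expected_permutation = expected_permutation(manifest)
        out.append((template, g, manifest))
    return out
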