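"""Data model and I/O for annotated circular plastid genomes.

Internal convention: all coordinates are 0-based half-open on the forward
strand; GenBank's 1-based inclusive coordinates are converted at the I/O
boundary only.  Circular genomes are stored rotated so that no feature part
spans the origin; :func:`rotate` splits and re-merges parts when a rotation
cut falls inside a feature, so rotation is a bijection on positions.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from ._util import gc_fraction, revcomp

VALID_KINDS = ("CDS", "tRNA", "rRNA")


class PlastomeError(ValueError):
    """Malformed genome, feature, or file."""


# ---------------------------------------------------------------------------
# gene-name canonicalisation


def _load_name_table() -> dict[str, str]:
    table = {}
    path = importlib.resources.files("plastarch.data") / "gene_names.tsv"
    for line in path.read_text().splitlines()[1:]:
        if line.strip():
            variant, canonical = line.split("\t")
            table[variant.strip().casefold()] = canonical.strip()
    return table


_NAME_TABLE = _load_name_table()
_TRNA_RE = re.compile(r"^trn\s*-?\s*(f?[A-Za-z])\s*[-(]\s*([ACGUTacgut]{3})\s*\)?$")
_RRNA_RE = re.compile(r"^(?:rrn)?\s*(\d+(?:\.\d+)?)\s*s?(?:\s*(?:ribosomal\s+rna|rrna))?$", re.I)


def canonical_gene_name(name: str) -> str:
    """Normalise a gene symbol: case, italics markers, tRNA anticodon styles.

    Unknown names are returned stripped but otherwise unchanged.
    """
    raw = name.strip().strip("*_ ")
    key = raw.casefold()
    if key in _NAME_TABLE:
        return _NAME_TABLE[key]
    m = _TRNA_RE.match(raw)
    if m:
        letter, anticodon = m.group(1), m.group(2).upper().replace("T", "U")
        letter = "fM" if letter.lower() == "fm" else letter.upper()
        return f"trn{letter}-{anticodon}"
    if key.startswith("rrn") or "ribosomal" in key or "rrna" in key:
        m = _RRNA_RE.match(raw)
        if m:
            return f"rrn{m.group(1)}"
    # gene symbols are lower-case with a capital locus suffix (rbcL, ndhA ...)
    m = re.match(r"^([a-z]{3,4})([A-Z0-9.]*)$", raw, re.I)
    if m and raw.lower() != raw and raw.upper() != raw:
        return raw  # already mixed-case, trust it
    return raw


# ---------------------------------------------------------------------------
# domain types


@dataclass
class GeneFeature:
    """A gene with one or more exon parts on the forward-strand coordinate frame.

    ``parts`` are ``(start, end, strand)`` tuples, 0-based half-open, stored in
    forward-strand adjacency order: ascending genomic positions, except that a
    feature transiently split across the circle origin (only ever produced by
    :meth:`AnnotatedPlastome.rotate`) may wrap once.  Intron count is
    ``len(parts) - 1``.
    """

    name: str
    kind: str
    parts: list[tuple[int, int, str]]
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.parts:
            raise PlastomeError(f"feature {self.name}: empty parts")
        if self.kind not in VALID_KINDS:
            raise PlastomeError(f"feature {self.name}: kind {self.kind!r}")
        self.parts = list(self.parts)
        descents = sum(
            1 for (s1, e1, _), (s2, _, _) in zip(self.parts, self.parts[1:]) if s2 < e1
        )
        if descents > 1:
            raise PlastomeError(f"feature {self.name}: parts out of order or overlapping")
        if descents == 1:  # wrapped: the pieces must still be disjoint
            spans = sorted((s, e) for s, e, _ in self.parts)
            if any(b[0] < a[1] for a, b in zip(spans, spans[1:])):
                raise PlastomeError(f"feature {self.name}: overlapping parts")
        for s, e, st in self.parts:
            if s >= e or st not in "+-":
                raise PlastomeError(f"feature {self.name}: bad part ({s},{e},{st})")

    @property
    def start(self) -> int:
        return self.parts[0][0]

    @property
    def end(self) -> int:
        return self.parts[-1][1]

    @property
    def strand(self) -> str:
        return self.parts[0][2]

    @property
    def n_introns(self) -> int:
        return len(self.parts) - 1

    def span(self) -> tuple[int, int]:
        return self.start, self.end

    def extract(self, seq: str) -> str:
        """Spliced 5'->3' sequence of the feature."""
        joined = "".join(seq[s:e] for s, e, _ in self.parts)
        return revcomp(joined) if self.strand == "-" else joined

    def copy(self) -> "GeneFeature":
        return GeneFeature(self.name, self.kind, list(self.parts), self.pseudo)


@dataclass
class AnnotatedPlastome:
    """Circular (or linear) plastid genome with gene features and metadata."""

    id: str
    seq: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    taxon: str = ""
    family: str = ""
    source: str = ""

    def __len__(self) -> int:
        return len(self.seq)

    def validate(self) -> None:
        if not self.seq:
            raise PlastomeError(f"{self.id}: empty sequence")
        if set(self.seq) - set("ACGTN"):
            raise PlastomeError(f"{self.id}: non-ACGTN characters in sequence")
        n = len(self.seq)
        for f in self.features:
            if f.start < 0 or f.end > n:
                raise PlastomeError(f"{self.id}: feature {f.name} outside [0,{n})")

    def gc(self) -> float:
        return gc_fraction(self.seq)

    def genes(self, name: str) -> list[GeneFeature]:
        name = canonical_gene_name(name)
        return [f for f in self.features if f.name == name]

    def gene_names(self) -> list[str]:
        return sorted({f.name for f in self.features})

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: f.start)

    # -- geometry ----------------------------------------------------------

    def rotate(self, offset: int) -> "AnnotatedPlastome":
        """Rotate the circle so position ``offset`` becomes 0.

        Feature parts crossing the cut are split, then re-merged once the
        rotation brings them back into adjacency, so the operation is a
        bijection on positions.
        """
        n = len(self.seq)
        offset %= n
        if offset == 0:
            return replace(self, features=[f.copy() for f in self.features])
        if not self.circular:
            raise PlastomeError(f"{self.id}: cannot rotate a linear genome")
        new_seq = self.seq[offset:] + self.seq[:offset]
        new_feats = []
        for f in self.features:
            parts = []
            for s, e, st in f.parts:
                if s < offset < e:  # cut inside part: split, adjacency order kept
                    parts.append(((s - offset) % n, n, st))
                    parts.append((0, e - offset, st))
                else:
                    ns = (s - offset) % n
                    parts.append((ns, ns + (e - s), st))
            merged: list[tuple[int, int, str]] = []
            for p in parts:
                if merged and merged[-1][1] == p[0] and merged[-1][2] == p[2]:
                    merged[-1] = (merged[-1][0], p[1], p[2])
                else:
                    merged.append(p)
            # a previously split feature may re-join across the old seam
            if len(merged) > 1 and merged[-1][1] == merged[0][0] and merged[-1][2] == merged[0][2]:
                merged[0] = (merged[-1][0], merged[0][1], merged[0][2])
                merged.pop()
            new_feats.append(GeneFeature(f.name, f.kind, merged, f.pseudo))
        return replace(self, seq=new_seq, features=new_feats)

    def reverse_complement(self) -> "AnnotatedPlastome":
        n = len(self.seq)
        feats = []
        for f in self.features:
            parts = [
                (n - e, n - s, "-" if st == "+" else "+") for s, e, st in reversed(f.parts)
            ]
            feats.append(GeneFeature(f.name, f.kind, parts, f.pseudo))
        return replace(self, seq=revcomp(self.seq), features=feats)


def _spans_origin(f: GeneFeature, n: int) -> bool:
    return any(e == n for _, e, _ in f.parts) and any(s == 0 for s, _, _ in f.parts)


# ---------------------------------------------------------------------------
# readers / writers


def read_genome(path, format: str = "auto", table=None) -> AnnotatedPlastome:
    """Read an annotated plastome from GenBank or FASTA + feature table.

    ``format`` is ``genbank``, ``fasta+table`` or ``auto`` (by extension).
    For ``fasta+table``, ``table`` is the feature-table path (defaults to the
    FASTA path with a ``.features.tsv`` suffix).
    """
    path = Path(path)
    if format == "auto":
        format = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta+table"
    if format == "genbank":
        return _read_genbank(path)
    if format == "fasta+table":
        table = Path(table) if table else path.with_suffix(".features.tsv")
        return _read_fasta_table(path, table)
    raise PlastomeError(f"unknown format {format!r}")


def _read_genbank(path: Path) -> AnnotatedPlastome:
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise PlastomeError(f"{path}: cannot parse GenBank record: {exc}") from exc
    feats = []
    taxon = record.annotations.get("organism", "")
    family = ""
    for f in record.features:
        if f.type == "source":
            for note in f.qualifiers.get("note", []):
                if note.startswith("family:"):
                    family = note.split(":", 1)[1].strip()
            continue
        if f.type not in VALID_KINDS:
            continue
        name = canonical_gene_name(
            (f.qualifiers.get("gene") or f.qualifiers.get("locus_tag") or ["?"])[0]
        )
        parts = []
        for loc in f.location.parts:
            strand = "-" if loc.strand == -1 else "+"
            parts.append((int(loc.start), int(loc.end), strand))
        # GenBank join() lists exons in transcription order; store ascending
        # (written records never span the origin)
        parts.sort()
        feats.append(GeneFeature(name, f.type, parts, pseudo="pseudo" in f.qualifiers))
    g = AnnotatedPlastome(
        id=record.id,
        seq=str(record.seq).upper(),
        features=feats,
        circular=record.annotations.get("topology", "linear") == "circular",
        taxon=taxon,
        family=family,
        source=str(path),
    )
    g.validate()
    return g


def _read_fasta_table(fasta: Path, table: Path) -> AnnotatedPlastome:
    record = next(SeqIO.parse(str(fasta), "fasta"))
    features: list[GeneFeature] = []
    pending: dict | None = None
    if table.exists():
        lines = table.read_text().splitlines()
        header = lines[0].split("\t")
        expect = ["genome_id", "gene", "kind", "part_index", "start", "end", "strand"]
        if header != expect:
            raise PlastomeError(f"{table}: bad header {header}")
        for ln, line in enumerate(lines[1:], start=2):
            if not line.strip():
                continue
            try:
                gid, gene, kind, idx, start, end, strand = line.split("\t")
                idx = int(idx)
                part = (int(start), int(end), strand)
            except ValueError as exc:
                raise PlastomeError(f"{table}:{ln}: malformed row") from exc
            name = canonical_gene_name(gene)
            if idx == 0:  # each feature's rows start at part_index 0
                if pending:
                    features.append(GeneFeature(**pending))
                pending = {"name": name, "kind": kind, "parts": []}
            elif pending is None or pending["name"] != name:
                raise PlastomeError(f"{table}:{ln}: part_index {idx} without part 0")
            pending["parts"].append(part)
        if pending:
            features.append(GeneFeature(**pending))
    desc = record.description.split()
    circular = "circular" in record.description.lower()
    g = AnnotatedPlastome(
        id=record.id, seq=str(record.seq).upper(), features=features,
        circular=circular, taxon=" ".join(desc[1:3]) if len(desc) > 2 else "",
        source=str(fasta),
    )
    g.validate()
    return g


def write_genome(g: AnnotatedPlastome, path, format: str = "auto", table=None) -> None:
    """Write GenBank or FASTA(+table); rotates first if a feature spans the origin."""
    g.validate()
    n = len(g.seq)
    for f in g.features:
        if _spans_origin(f, n):
            # rotate so the wrapped feature becomes contiguous
            cut = min(s for s, e, _ in f.parts if e == n)
            g = g.rotate(cut)
            break
    path = Path(path)
    if format == "auto":
        format = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".genbank") else "fasta+table"
    if format == "genbank":
        _write_genbank(g, path)
    elif format == "fasta+table":
        table = Path(table) if table else path.with_suffix(".features.tsv")
        _write_fasta_table(g, path, table)
    else:
        raise PlastomeError(f"unknown format {format!r}")


def _write_genbank(g: AnnotatedPlastome, path: Path) -> None:
    record = SeqRecord(Seq(g.seq), id=g.id, name=g.id[:16], description=g.taxon)
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if g.circular else "linear"
    record.annotations["organism"] = g.taxon
    src = SeqFeature(SimpleLocation(0, len(g.seq), 1), type="source")
    src.qualifiers["organism"] = [g.taxon]
    if g.family:
        src.qualifiers["note"] = [f"family:{g.family}"]
    record.features.append(src)
    for f in g.sorted_features():
        locs = [SimpleLocation(s, e, 1 if st == "+" else -1) for s, e, st in f.parts]
        if f.strand == "-":
            locs = locs[::-1]
        loc = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        sf = SeqFeature(loc, type=f.kind)
        sf.qualifiers["gene"] = [f.name]
        if f.pseudo:
            sf.qualifiers["pseudo"] = [""]
        record.features.append(sf)
    SeqIO.write([record], str(path), "genbank")


def _write_fasta_table(g: AnnotatedPlastome, fasta: Path, table: Path) -> None:
    topo = "circular" if g.circular else "linear"
    fasta.write_text(f">{g.id} {g.taxon} [{topo}]\n" + _wrap(g.seq) + "\n")
    rows = ["genome_id\tgene\tkind\tpart_index\tstart\tend\tstrand"]
    for f in g.sorted_features():
        for i, (s, e, st) in enumerate(f.parts):
            rows.append(f"{g.id}\t{f.name}\t{f.kind}\t{i}\t{s}\t{e}\t{st}")
    table.write_text("\n".join(rows) + "\n")


def _wrap(seq: str, width: int = 70) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


# ---------------------------------------------------------------------------
# frame normalisation

ANCHOR_ORDER = ("psbA", "rbcL", "rrn16")


def normalize_frame(g: AnnotatedPlastome, anchor_gene: str = "psbA") -> AnnotatedPlastome:
    """Rotate/flip so the anchor gene starts at position 0 on the plus strand.

    Falls back through :data:`ANCHOR_ORDER` when the requested anchor is
    missing.  Normalisation makes LCB signs comparable across genomes and is
    idempotent.
    """
    candidates = [anchor_gene] + [a for a in ANCHOR_ORDER if a != anchor_gene]
    feat = None
    for name in candidates:
        hits = g.genes(name)
        if hits:
            feat = min(hits, key=lambda f: f.start)
            break
    if feat is None:
        raise PlastomeError(
            f"{g.id}: no anchor gene among {candidates}; genes present: {g.gene_names()}"
        )
    if feat.strand == "-":
        g = g.reverse_complement()
        feat = min(g.genes(feat.name), key=lambda f: f.start)
    if feat.start == 0:
        return g
    return g.rotate(feat.start)
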