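"""Shared low-level helpers: alphabets, complement tables, GC, codon translation."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Standard nuclear/plastid genetic code, DNA alphabet, '*' marks stops.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases; N excluded from numerator and denominator."""
    gc = seq.count("G") + seq.count("C") + seq.count("g") + seq.count("c")
    at = seq.count("A") + seq.count("T") + seq.count("a") + seq.count("t")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def translate(seq: str) -> str:
    """Translate an in-frame DNA string; trailing partial codon ignored."""
    return "".join(
        CODON_TABLE.get(seq[i : i + 3].upper(), "X") for i in range(0, len(seq) - 2, 3)
    )


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a DNA string for vectorised comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def spawn_seed(rng: np.random.Generator) -> int:
    """A fresh sub-seed below 2**31 drawn from an existing generator."""
    return int(rng.integers(0, 2**31 - 1))
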