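"""Packaged reference gene panel: the canonical angiosperm-style plastome set.

One table drives both the synthetic generator (what to place where) and the
architecture classifier (each gene's canonical home region).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache


@dataclass(frozen=True)
class GeneSpec:
    """Panel entry: spliced length, canonical region, intron model."""

    name: str
    kind: str  # CDS | tRNA | rRNA
    length: int  # spliced (exonic) length in bp
    region: str  # LSC | SSC | IR
    introns: tuple[int, ...] = field(default_factory=tuple)
    trans_spliced: bool = False

    @property
    def genomic_length(self) -> int:
        return self.length + sum(self.introns)


@lru_cache(maxsize=1)
def default_panel() -> tuple[GeneSpec, ...]:
    """The packaged ~113-gene panel in canonical genomic order."""
    path = importlib.resources.files("plastarch.data") / "gene_panel.tsv"
    specs = []
    for line in path.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        name, kind, length, region, introns, trans = line.split("\t")
        intron_lens = tuple(int(x) for x in introns.split(",")) if introns != "-" else ()
        specs.append(
            GeneSpec(name, kind, int(length), region, intron_lens, trans == "1")
        )
    return tuple(specs)


@lru_cache(maxsize=1)
def reference_regions() -> dict[str, str]:
    """Gene -> canonical region (LSC/SSC/IR) from the packaged panel."""
    return {spec.name: spec.region for spec in default_panel()}


def panel_by_name() -> dict[str, GeneSpec]:
    return {spec.name: spec for spec in default_panel()}
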