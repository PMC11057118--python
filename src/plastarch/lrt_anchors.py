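"""Packaged site-model LRT summaries for the 8 positively selected genes.

These are published likelihood-ratio summaries (lnL, parameter counts, the
2ΔL statistic, degrees of freedom and the printed p-value) for the three
standard site-model comparisons (M0 vs M3, M1 vs M2, M7 vs M8) on eight
plastid genes.  They serve as worked-arithmetic anchors: recomputing the
right-tail chi-square p-value from (2ΔL, df) must reproduce the printed value
to its displayed precision.  One row (atpA, M7 vs M8) is flagged
``consistent = False``: its printed p disagrees with chi-square of its printed
statistic by far more than rounding can explain, so it is compared only
loosely.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from functools import lru_cache


def _ulp(text: str) -> float:
    """Half-interval of the last printed significant digit."""
    t = text.upper()
    mantissa = t.split("E")[0].replace("-", "").replace(".", "").lstrip("0")
    value = float(t)
    if value == 0 or not mantissa:
        return 0.0
    exponent = math.floor(math.log10(abs(value)))
    return 10.0 ** (exponent - len(mantissa) + 1)


@dataclass(frozen=True)
class LRTAnchor:
    gene: str
    comparison: str
    lnL_null: float
    lnL_alt: float
    np_null: int
    np_alt: int
    stat_text: str  # 2ΔL as printed
    df: int
    p_printed: str  # as printed; "0" means "infinitesimally close to 0"
    consistent: bool = True

    @property
    def two_delta_L(self) -> float:
        return float(self.stat_text)

    @property
    def p_value(self) -> float:
        return float(self.p_printed)

    def p_tolerance(self) -> float:
        """Printed-precision band for the p-value, widened by the uncertainty
        the rounded statistic itself propagates through the chi-square tail."""
        from scipy.stats import chi2

        half_stat = _ulp(self.stat_text) / 2.0
        propagated = abs(
            chi2.sf(self.two_delta_L - half_stat, self.df)
            - chi2.sf(self.two_delta_L + half_stat, self.df)
        )
        return 0.51 * _ulp(self.p_printed) + propagated


@lru_cache(maxsize=1)
def lrt_anchor_table() -> tuple[LRTAnchor, ...]:
    path = importlib.resources.files("plastarch.data") / "poales_site_model_lrt.tsv"
    rows = []
    for line in path.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        gene, comp, l0, l1, n0, n1, stat, df, p, ok = line.split("\t")
        rows.append(
            LRTAnchor(gene, comp, float(l0), float(l1), int(n0), int(n1),
                      stat, int(df), p, ok == "1")
        )
    return tuple(rows)
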