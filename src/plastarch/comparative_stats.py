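"""Cross-genome feature table, Pearson correlations, root-to-tip distances.

The eight standard per-genome variables are GC content, repeat number, genome
length, LSC length, SSC length, IR length (one copy), rearrangement distance
and protein-coding gene count.  Correlation strength follows the |r|
thresholds used in comparative plastome work: strong >= 0.8, moderate in
[0.5, 0.8), weak < 0.5.  P-values are two-sided from the t distribution and
reported raw (no multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

FEATURE_COLUMNS = (
    "gc_content", "repeat_number", "genome_length", "lsc_length",
    "ssc_length", "ir_length", "rearrangement_distance", "cds_number",
)


class StatsError(ValueError):
    pass


def feature_table(
    genomes,
    reports: dict,
    repeat_summaries: dict,
    distances: dict,
    cds_numbers: dict | None = None,
    families: dict | None = None,
    include_incomplete: bool = False,
) -> pd.DataFrame:
    """One row per genome with the eight comparative variables.

    ``reports`` maps genome_id -> ArchitectureReport, ``repeat_summaries`` ->
    repeat_summary dict, ``distances`` -> reversal distance,
    ``cds_numbers`` -> protein-coding genes with status present/duplicated.
    Genomes missing any component are flagged incomplete and excluded unless
    ``include_incomplete`` is set (IR-less genomes report ir_length 0; remnant
    lengths are never counted as IR).
    """
    rows = []
    for g in genomes:
        gid = g.id if hasattr(g, "id") else str(g)
        rep = reports.get(gid)
        summ = repeat_summaries.get(gid)
        complete = rep is not None and summ is not None and gid in distances
        row = {
            "genome_id": gid,
            "family": (families or {}).get(gid, getattr(g, "family", "")),
            "gc_content": rep.gc_total if rep else np.nan,
            "repeat_number": summ["total"] if summ else np.nan,
            "genome_length": rep.genome_len if rep else len(getattr(g, "seq", "")),
            "lsc_length": rep.lsc_len if rep else np.nan,
            "ssc_length": rep.ssc_len if rep else np.nan,
            "ir_length": rep.ir_len if rep else np.nan,
            "rearrangement_distance": distances.get(gid, np.nan),
            "cds_number": (cds_numbers or {}).get(gid, np.nan),
            "complete": complete,
        }
        rows.append(row)
    df = pd.DataFrame(rows).set_index("genome_id")
    if not include_incomplete:
        df = df[df["complete"]]
    return df


def classify_strength(r: float) -> str:
    """Correlation strength from |r|: >=0.8 strong, [0.5, 0.8) moderate, else weak."""
    if np.isnan(r):
        return "undefined"
    a = abs(r)
    if a >= 0.8:
        return "strong"
    if a >= 0.5:
        return "moderate"
    return "weak"


@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    strength: pd.DataFrame

    def pair(self, a: str, b: str) -> tuple[float, float, str]:
        return self.r.loc[a, b], self.p.loc[a, b], self.strength.loc[a, b]

    def to_tsv(self) -> str:
        rows = ["var_a\tvar_b\tr\tp\tstrength"]
        for i, a in enumerate(self.variables):
            for b in self.variables[i + 1:]:
                r, p, s = self.pair(a, b)
                rows.append(f"{a}\t{b}\t{r:.4f}\t{p:.3e}\t{s}")
        return "\n".join(rows) + "\n"


def pairwise_correlations(table: pd.DataFrame, variables=None) -> CorrelationMatrix:
    """Pearson r (two-sided t-test p) for every variable pair.

    Zero-variance columns yield NaN r with strength "undefined" rather than
    an error.
    """
    variables = list(variables or [c for c in FEATURE_COLUMNS if c in table.columns])
    data = table[variables].astype(float).dropna()
    if len(data) < 4:
        raise StatsError(f"need >= 4 complete rows, have {len(data)}")
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = data.iloc[:, i], data.iloc[:, j]
            if x.std() == 0 or y.std() == 0:
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    rdf = pd.DataFrame(r, index=variables, columns=variables)
    pdf = pd.DataFrame(p, index=variables, columns=variables)
    sdf = rdf.map(classify_strength)
    return CorrelationMatrix(variables, rdf, pdf, sdf)


def root_to_tip(tree, groups: dict[str, str] | None = None):
    """Per-tip patristic distance from the root, with per-group summaries.

    ``tree`` is a rooted dendropy tree with branch lengths; ``groups`` maps
    tip label -> family/clade.  Returns (per_tip: Series, per_group: DataFrame).
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        raise StatsError("tree must be a dendropy.Tree")
    if not tree.is_rooted:
        raise StatsError("tree is unrooted: root it first (e.g. with an outgroup)")
    dist = {}
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        edge = node.edge.length or 0.0
        if edge < 0:
            raise StatsError("negative branch length")
        depth[node] = depth[node.parent_node] + edge
        if node.is_leaf():
            dist[node.taxon.label] = depth[node]
    per_tip = pd.Series(dist, name="root_to_tip").sort_index()
    if groups:
        df = per_tip.to_frame()
        df["group"] = [groups.get(t, "?") for t in df.index]
        per_group = df.groupby("group")["root_to_tip"].agg(["mean", "min", "max", "count"])
    else:
        per_group = pd.DataFrame(columns=["mean", "min", "max", "count"])
    return per_tip, per_group
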