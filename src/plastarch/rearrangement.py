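"""Gene-order rearrangement: anchors, collinear blocks, signed reversal distance.

Two annotated plastomes are compared through their shared single-copy gene
anchors (one IR copy is masked first, as rearrangement analyses of
quadripartite genomes conventionally do).  Maximal runs of anchors collinear
in both genomes collapse into locally collinear blocks (LCBs) carrying a
(+/-) orientation sign; a negative sign marks an inversion.  The minimum
number of reversals sorting the signed block permutation is computed with
Hannenhalli-Pevzner theory on the capped breakpoint graph:

    d(pi) = (n + 1) - c(pi) + h(pi) + f(pi)

with c = cycles, h = hurdles, f = 1 for a fortress.  An exact search oracle
(pure BFS for n <= 6, iterative deepening with the classical cycle lower
bound for n = 7, 8) backs the formula in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from .architecture import detect_irs
from .plastome_io import AnnotatedPlastome, normalize_frame


class RearrangementError(ValueError):
    pass


# ---------------------------------------------------------------------------
# signed permutations


@dataclass(frozen=True)
class SignedPermutation:
    """Non-zero signed integers whose absolute values form 1..n."""

    elements: tuple[int, ...]

    def __post_init__(self):
        elems = tuple(int(x) for x in self.elements)
        object.__setattr__(self, "elements", elems)
        n = len(elems)
        if sorted(abs(x) for x in elems) != list(range(1, n + 1)) or 0 in elems:
            raise RearrangementError(f"not a signed permutation: {elems}")

    def __len__(self) -> int:
        return len(self.elements)

    def is_identity(self) -> bool:
        return all(x == i + 1 for i, x in enumerate(self.elements))

    def inverse(self) -> "SignedPermutation":
        out = [0] * len(self.elements)
        for i, x in enumerate(self.elements, start=1):
            out[abs(x) - 1] = i if x > 0 else -i
        return SignedPermutation(tuple(out))

    def to_grimm(self, name: str = "genome") -> str:
        return f">{name}\n{' '.join(str(x) for x in self.elements)}\n"

    @classmethod
    def from_grimm(cls, text: str) -> "SignedPermutation":
        nums = [int(tok) for line in text.splitlines()
                if line.strip() and not line.startswith(">")
                for tok in line.split()]
        return cls(tuple(nums))


def apply_reversal(p: tuple[int, ...], i: int, j: int) -> tuple[int, ...]:
    """Reverse segment [i, j] (inclusive) and flip its signs."""
    return p[:i] + tuple(-x for x in reversed(p[i : j + 1])) + p[j + 1 :]


# ---------------------------------------------------------------------------
# Hannenhalli-Pevzner distance


def _breakpoint_graph(elems: tuple[int, ...]):
    """Capped unsigned doubling; returns (u, pos) for the 2n+2 point sequence."""
    u = [0]
    for x in elems:
        u.extend((2 * x - 1, 2 * x) if x > 0 else (-2 * x, -2 * x - 1))
    u.append(2 * len(elems) + 1)
    pos = {v: i for i, v in enumerate(u)}
    return u, pos


def _gray_partner(v: int, n: int) -> int:
    # gray edges join 2i <-> 2i+1 for i = 0..n
    return v + 1 if v % 2 == 0 else v - 1


def _cycles(elems: tuple[int, ...]):
    """Alternating cycles of the breakpoint graph.

    Returns a list of cycles, each a list of gray edges (value_even, value_odd).
    """
    n = len(elems)
    u, pos = _breakpoint_graph(elems)
    seen = [False] * (n + 1)  # per black edge k spanning positions (2k, 2k+1)
    cycles = []
    for k in range(n + 1):
        if seen[k]:
            continue
        grays = []
        p = 2 * k
        while True:
            seen[p // 2] = True
            q = p ^ 1  # cross the black edge
            w = _gray_partner(u[q], n)
            grays.append((min(u[q], w), max(u[q], w)))
            p = pos[w]  # cross the gray edge
            if p == 2 * k:
                break
        cycles.append(grays)
    return cycles, pos


def cycle_count(elems: tuple[int, ...]) -> int:
    if not elems:
        return 1
    return len(_cycles(elems)[0])


def _components(elems: tuple[int, ...]):
    """Interleaving components of non-trivial cycles.

    Each component records its gray-edge position intervals and whether it is
    oriented (contains a gray edge whose endpoints share position parity).
    """
    cycles, pos = _cycles(elems)
    items = []  # (edges_positions, oriented) per non-trivial cycle
    for grays in cycles:
        if len(grays) == 1:  # adjacency: trivial cycle, never in a component
            continue
        edges = []
        oriented = False
        for v, w in grays:
            a, b = pos[v], pos[w]
            if a > b:
                a, b = b, a
            if a % 2 == b % 2:
                oriented = True
            edges.append((a, b))
        items.append((edges, oriented))
    # union-find over cycles via crossing gray edges
    parent = list(range(len(items)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if any(
                a1 < a2 < b1 < b2 or a2 < a1 < b2 < b1
                for a1, b1 in items[i][0]
                for a2, b2 in items[j][0]
            ):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, dict] = {}
    for i, (edges, oriented) in enumerate(items):
        r = find(i)
        c = comps.setdefault(r, {"positions": set(), "oriented": False})
        for a, b in edges:
            c["positions"].update((a, b))
        c["oriented"] |= oriented
    return list(comps.values())


def _hurdles_among(position_sets: list[frozenset]) -> list[int]:
    """Indices of hurdles: components whose positions are consecutive when
    only positions of unoriented components are scanned left to right."""
    owner = {}
    for idx, ps in enumerate(position_sets):
        for p in ps:
            owner[p] = idx
    order = [owner[p] for p in sorted(owner)]
    hurdles = []
    for idx in range(len(position_sets)):
        occ = [i for i, o in enumerate(order) if o == idx]
        if occ and occ[-1] - occ[0] + 1 == len(occ):
            hurdles.append(idx)
    return hurdles


def _hurdles_fortress(elems: tuple[int, ...]) -> tuple[int, int]:
    comps = _components(elems)
    unoriented = [frozenset(c["positions"]) for c in comps if not c["oriented"]]
    if not unoriented:
        return 0, 0
    hurdles = _hurdles_among(unoriented)
    h = len(hurdles)
    if h == 0:
        return 0, 0
    # a superhurdle protects a non-hurdle that would become one if it vanished
    super_flags = []
    base = set(hurdles)
    for hu in hurdles:
        rest = [ps for i, ps in enumerate(unoriented) if i != hu]
        if not rest:
            super_flags.append(False)
            continue
        new_h = _hurdles_among(rest)
        # map rest indices back to original indices
        remap = [i for i in range(len(unoriented)) if i != hu]
        new_ids = {remap[i] for i in new_h}
        super_flags.append(bool(new_ids - base))
    f = 1 if h % 2 == 1 and all(super_flags) else 0
    return h, f


def reversal_distance(p: SignedPermutation) -> int:
    """Minimum reversals sorting ``p`` to identity (Hannenhalli-Pevzner)."""
    elems = p.elements
    n = len(elems)
    if n == 0 or p.is_identity():
        return 0
    c = cycle_count(elems)
    h, f = _hurdles_fortress(elems)
    return n + 1 - c + h + f


def breakpoints(p: SignedPermutation) -> int:
    """Breakpoints of the capped permutation (adjacencies missing)."""
    ext = (0,) + p.elements + (len(p) + 1,)
    return sum(1 for a, b in zip(ext, ext[1:]) if b - a != 1)


# ---------------------------------------------------------------------------
# exact-search oracle


@lru_cache(maxsize=4)
def _distance_table(n: int) -> dict:
    """BFS over the whole reversal graph from the identity (n <= 6)."""
    if n > 6:
        raise RearrangementError("full BFS table limited to n <= 6")
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    frontier = [ident]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for p in frontier:
            for i in range(n):
                for j in range(i, n):
                    q = apply_reversal(p, i, j)
                    if q not in dist:
                        dist[q] = d
                        nxt.append(q)
        frontier = nxt
    return dist


def _cycle_lower_bound(elems: tuple[int, ...]) -> int:
    n = len(elems)
    return n + 1 - cycle_count(elems)


def brute_force_distance(p: SignedPermutation) -> int:
    """Exact minimum reversal count by search, independent of the HP formula.

    n <= 6: lookup in a breadth-first distance table over all signed
    permutations.  n = 7, 8: iterative-deepening depth-first search pruned by
    the classical cycle lower bound (each reversal changes the cycle count by
    at most one), which is admissible, so the first bound that succeeds is
    the exact distance.
    """
    n = len(p)
    if n > 8:
        raise RearrangementError("oracle limited to n <= 8")
    if n == 0 or p.is_identity():
        return 0
    if n <= 6:
        return _distance_table(n)[p.elements]
    start = p.elements
    bound = _cycle_lower_bound(start)
    ident = tuple(range(1, n + 1))

    def dfs(state, g, bound, seen):
        lb = _cycle_lower_bound(state)
        if g + lb > bound:
            return None
        if state == ident:
            return g
        best_next = None
        for i in range(n):
            for j in range(i, n):
                q = apply_reversal(state, i, j)
                if q in seen:
                    continue
                seen.add(q)
                r = dfs(q, g + 1, bound, seen)
                seen.discard(q)
                if r is not None:
                    return r
        return best_next

    while True:
        res = dfs(start, 0, bound, {start})
        if res is not None:
            return res
        bound += 1


# ---------------------------------------------------------------------------
# anchors and LCBs


@dataclass(frozen=True)
class Anchor:
    name: str
    ref_interval: tuple[int, int]
    query_interval: tuple[int, int]
    sign: int  # +1 same strand in both genomes, -1 otherwise


@dataclass
class LCB:
    ref_index: int  # signed block label (reference order 1..n)
    ref_interval: tuple[int, int]
    query_interval: tuple[int, int]
    genes: list[str]


@dataclass
class LCBSet:
    reference_id: str
    query_id: str
    blocks: list[LCB] = field(default_factory=list)  # in query order

    def permutation(self) -> SignedPermutation:
        return SignedPermutation(tuple(b.ref_index for b in self.blocks))


@dataclass
class InversionCall:
    query_interval: tuple[int, int]
    length: int
    genes: list[str]
    shared_with: set = field(default_factory=set)


def _masked_single_copy(g: AnnotatedPlastome) -> dict[str, object]:
    """Single-copy features after masking the earlier-start large IR copy."""
    irset = detect_irs(g)
    ivs = sorted(irset.intervals())
    mask = ivs[0] if len(ivs) >= 2 else None
    kept = [
        f for f in g.sorted_features()
        if mask is None or not (f.start < mask[1] and f.end > mask[0])
    ]
    counts: dict[str, int] = {}
    for f in kept:
        counts[f.name] = counts.get(f.name, 0) + 1
    return {f.name: f for f in kept if counts[f.name] == 1}


def gene_anchors(ref: AnnotatedPlastome, query: AnnotatedPlastome) -> list[Anchor]:
    """Shared single-copy genes (IRb masked) ordered by reference position."""
    ref = normalize_frame(ref)
    query = normalize_frame(query)
    ref_feats = _masked_single_copy(ref)
    qry_feats = _masked_single_copy(query)
    shared = sorted(
        set(ref_feats) & set(qry_feats), key=lambda name: ref_feats[name].start
    )
    if len(shared) < 3:
        raise RearrangementError(
            f"only {len(shared)} shared single-copy genes between "
            f"{ref.id} and {query.id}; need >= 3"
        )
    anchors = []
    for name in shared:
        rf, qf = ref_feats[name], qry_feats[name]
        anchors.append(
            Anchor(
                name,
                (rf.start, rf.end),
                (qf.start, qf.end),
                1 if rf.strand == qf.strand else -1,
            )
        )
    return anchors


def collapse_signed_sequence(values: list[int]) -> list[int]:
    """Collapse maximal collinear runs and relabel blocks 1..n in source order.

    A run extends while the next value equals the previous plus one and both
    share a sign (a reversed segment of source blocks k..m reads -m..-k, which
    also ascends by one).
    """
    if not values:
        return []
    runs: list[list[int]] = []
    for v in values:
        if runs and ((v > 0) == (runs[-1][-1] > 0)) and v == runs[-1][-1] + 1:
            runs[-1].append(v)
        else:
            runs.append([v])
    order = sorted(range(len(runs)), key=lambda i: min(abs(x) for x in runs[i]))
    label = {i: rank for rank, i in enumerate(order, start=1)}
    return [label[i] if runs[i][0] > 0 else -label[i] for i in range(len(runs))]


def build_lcbs(anchors: list[Anchor], min_block_genes: int = 1):
    """Collapse anchors into LCBs; return (LCBSet, SignedPermutation)."""
    if not anchors:
        raise RearrangementError("no anchors")
    rank = {a.name: i + 1 for i, a in enumerate(anchors)}
    in_query = sorted(anchors, key=lambda a: a.query_interval[0])
    values = [a.sign * rank[a.name] for a in in_query]
    runs: list[list[Anchor]] = []
    vals: list[list[int]] = []
    for a, v in zip(in_query, values):
        if vals and ((v > 0) == (vals[-1][-1] > 0)) and v == vals[-1][-1] + 1:
            vals[-1].append(v)
            runs[-1].append(a)
        else:
            vals.append([v])
            runs.append([a])
    keep = [i for i, r in enumerate(runs) if len(r) >= min_block_genes]
    runs = [runs[i] for i in keep]
    vals = [vals[i] for i in keep]
    order = sorted(range(len(runs)), key=lambda i: min(abs(x) for x in vals[i]))
    label = {i: rank_ for rank_, i in enumerate(order, start=1)}
    blocks = []
    for i, run in enumerate(runs):
        sign = 1 if vals[i][0] > 0 else -1
        by_ref = sorted(run, key=lambda a: a.ref_interval[0])
        blocks.append(
            LCB(
                ref_index=sign * label[i],
                ref_interval=(by_ref[0].ref_interval[0], by_ref[-1].ref_interval[1]),
                query_interval=(run[0].query_interval[0], run[-1].query_interval[1]),
                genes=[a.name for a in run],
            )
        )
    lcbs = LCBSet(reference_id="ref", query_id="query", blocks=blocks)
    return lcbs, lcbs.permutation()


def call_inversions(lcbs: LCBSet) -> list[InversionCall]:
    """Maximal runs of negative blocks, one inversion call each."""
    calls = []
    run: list[LCB] = []
    for b in lcbs.blocks + [None]:
        if b is not None and b.ref_index < 0:
            run.append(b)
            continue
        if run:
            start = run[0].query_interval[0]
            end = run[-1].query_interval[1]
            genes = [g for blk in run for g in blk.genes]
            calls.append(InversionCall((start, end), end - start, genes))
        run = []
    return calls


def rearrangement_report(ref: AnnotatedPlastome, query: AnnotatedPlastome) -> dict:
    """Anchors -> LCBs -> inversion calls -> reversal distance, end to end."""
    anchors = gene_anchors(ref, query)
    lcbs, perm = build_lcbs(anchors)
    calls = call_inversions(lcbs)
    return {
        "n_anchors": len(anchors),
        "n_blocks": len(lcbs.blocks),
        "permutation": list(perm.elements),
        "inversions": calls,
        "reversal_distance": reversal_distance(perm),
    }


def mark_shared(calls_by_genome: dict[str, list[InversionCall]]) -> None:
    """Annotate calls sharing an identical gene content across genomes."""
    index: dict[frozenset, list[tuple[str, InversionCall]]] = {}
    for gid, calls in calls_by_genome.items():
        for c in calls:
            index.setdefault(frozenset(c.genes), []).append((gid, c))
    for group in index.values():
        gids = {gid for gid, _ in group}
        if len(gids) > 1:
            for gid, c in group:
                c.shared_with = gids - {gid}
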