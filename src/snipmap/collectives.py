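"""Gene collectives: phase III of the mapping pipeline.

Near-identical genes — paralog families, multi-copy transposable elements —
share most of their snippets and can never be told apart by exact matching.
Rather than discarding their reads, the pipeline groups such genes into a
"collective" accounted for by one synthetic collective-gene entry: reads that
match the group but no single member are credited to the collective gene,
while reads unique to one member still go to that member.

A pair of genes is linked when it shares more than ``share_frac`` of the
smaller gene's (still-mappable) snippets AND the two lengths differ by at most
``max_len_ratio``; collectives are the connected components of the link graph,
so overlapping qualifying pairs merge into one collective.  The defaults
(0.5 and 2.0) are the thresholds the method was designed with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .index import SnippetIndex, Transcriptome, _void_view

DEFAULT_SHARE_FRAC = 0.5
DEFAULT_MAX_LEN_RATIO = 2.0


@dataclass
class CollectiveSet:
    """Partition fragments grouping near-identical genes.

    ``members`` maps collective ordinal -> sorted list of member gene
    ordinals; every collective has at least two members and no gene belongs
    to more than one.  ``names`` are the synthetic collective-gene labels
    appended after the real genes in every output table.
    """

    members: list[list[int]] = field(default_factory=list)
    names: list[str] = field(default_factory=list)
    gene_to_collective: dict[int, int] = field(default_factory=dict)

    @property
    def n_collectives(self) -> int:
        return len(self.members)

    def collective_of(self, g: int) -> int | None:
        return self.gene_to_collective.get(g)

    def same_collective(self, g1: int, g2: int) -> bool:
        c1 = self.gene_to_collective.get(g1)
        return c1 is not None and c1 == self.gene_to_collective.get(g2)


def tally_shared_snippets(
    idx: SnippetIndex, t: Transcriptome
) -> dict[tuple[int, int], int]:
    """Count identical still-mappable snippets for every gene pair.

    After phase II each L-mer occurs at most once per gene among mappable
    snippets, so the tally for a pair is the number of distinct L-mers both
    genes carry.  Returned sparse and symmetric-by-convention with keys
    (g1, g2), g1 < g2; absent key means zero.
    """
    ids = idx.mappable_ids()
    if ids.size == 0:
        return {}
    win = np.lib.stride_tricks.sliding_window_view(idx.seq_bytes, idx.L)[ids]
    keys = _void_view(win)
    genes = idx.snippet_to_gene[ids]
    order = np.argsort(keys, kind="stable")
    keys_s, genes_s = keys[order], genes[order]
    boundaries = np.flatnonzero(
        np.concatenate([[True], keys_s[1:] != keys_s[:-1], [True]])
    )
    tally: dict[tuple[int, int], int] = {}
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if b - a < 2:
            continue
        gs = sorted(set(int(g) for g in genes_s[a:b]))
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                pair = (gs[i], gs[j])
                tally[pair] = tally.get(pair, 0) + 1
    return tally


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_collectives(
    tally: dict[tuple[int, int], int],
    idx: SnippetIndex,
    t: Transcriptome,
    share_frac: float = DEFAULT_SHARE_FRAC,
    max_len_ratio: float = DEFAULT_MAX_LEN_RATIO,
    name_prefix: str = "COLL_",
) -> CollectiveSet:
    """Link qualifying gene pairs and emit connected components as collectives.

    The shared fraction uses the smaller gene's count of snippets still
    mappable at phase III entry as denominator, so an identical pair scores
    exactly 1.  Pairs with a zero denominator never link.
    """
    lengths = t.lengths
    # mappable snippet count per gene at phase III entry
    mappable_per_gene = np.bincount(
        idx.snippet_to_gene[idx.mappable_ids()], minlength=t.n_genes
    )
    uf = _UnionFind(t.n_genes)
    linked: set[int] = set()
    for (g1, g2), shared in tally.items():
        denom = min(mappable_per_gene[g1], mappable_per_gene[g2])
        if denom == 0:
            continue
        l1, l2 = int(lengths[g1]), int(lengths[g2])
        if max(l1, l2) > max_len_ratio * min(l1, l2):
            continue
        if shared / denom > share_frac:
            uf.union(g1, g2)
            linked.add(g1)
            linked.add(g2)

    components: dict[int, list[int]] = {}
    for g in sorted(linked):
        components.setdefault(uf.find(g), []).append(g)

    coll = CollectiveSet()
    # deterministic order: by smallest member gene ordinal
    for comp in sorted(components.values(), key=lambda m: m[0]):
        cid = len(coll.members)
        coll.members.append(sorted(comp))
        coll.names.append(f"{name_prefix}{cid + 1}")
        for g in comp:
            coll.gene_to_collective[g] = cid
    idx.log_phase("III:collectives")
    return coll
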