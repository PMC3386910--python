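"""Exact-match read assignment: phase V of the mapping pipeline.

Reads are matched, unmodified, against the snippets that survived the
robust-uniqueness phase.  Only exact matches count.  A surviving L-mer present
in exactly one gene credits that gene; a surviving L-mer present in two or
more genes necessarily lies within one collective (cross-collective
duplicates were masked in phase IV) and credits the collective gene instead.
Reads matching no surviving snippet stay unmapped; a read of the wrong length
is skipped and tallied, not fatal.  With ``orientation="both"`` the reverse
complement is tried when the forward sequence misses, so each read is counted
at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .collectives import CollectiveSet
from .index import SnippetIndex, Transcriptome

_RC = bytes.maketrans(b"ACGTN", b"TGCAN")


@dataclass
class CountTable:
    """Per-sample read counts and positional coverage per gene/collective gene.

    ``names`` lists real genes in input order followed by collective genes;
    ``profiles[i]`` counts matches per snippet start along entity i (for a
    collective gene, coordinates of its lowest-ordinal member).  The sum of
    ``counts`` equals ``total_mapped`` and each profile sums to its entity's
    count.
    """

    sample_id: str
    names: list[str]
    lengths: np.ndarray
    counts: np.ndarray
    profiles: list[np.ndarray]
    total_reads: int = 0
    total_mapped: int = 0
    n_length_mismatch: int = 0

    @property
    def n_entities(self) -> int:
        return len(self.names)


def collective_gene_lengths(coll: CollectiveSet, t: Transcriptome) -> np.ndarray:
    """Nominal length of each collective gene: rounded mean of member lengths.

    The collective gene is an accounting entity without a sequence; a nominal
    length is needed only so RPKM stays defined for it.
    """
    lens = t.lengths
    return np.array(
        [int(round(lens[m].mean())) for m in coll.members], dtype=np.int64
    )


def build_lookup(
    idx: SnippetIndex, coll: CollectiveSet
) -> dict[bytes, tuple[int, int, int]]:
    """Map each surviving L-mer to (entity ordinal, profile gene, gene-local start).

    Entity ordinals: 0..G-1 real genes, then G..G+C-1 collective genes.  A
    surviving L-mer occurring in >= 2 genes must lie within one collective;
    this is asserted rather than tie-broken, since phase IV guarantees it.
    """
    n_genes = idx.n_genes
    occurrences: dict[bytes, list[int]] = {}
    for s in idx.mappable_ids():
        occurrences.setdefault(idx.snippet_bytes(int(s)), []).append(int(s))

    lookup: dict[bytes, tuple[int, int, int]] = {}
    for lmer, sites in occurrences.items():
        genes = sorted({int(idx.snippet_to_gene[s]) for s in sites})
        if len(genes) == 1:
            g = genes[0]
            entity = g
        else:
            cids = {coll.collective_of(g) for g in genes}
            assert len(cids) == 1 and None not in cids, (
                "multi-gene snippet survived uniqueness masking outside a "
                "single collective"
            )
            entity = n_genes + cids.pop()
        # profile coordinate: occurrence in the lowest-ordinal gene
        g0 = genes[0]
        s0 = min(s for s in sites if int(idx.snippet_to_gene[s]) == g0)
        lookup[lmer] = (entity, g0, s0 - int(idx.gene_offsets[g0]))
    return lookup


def reverse_complement(seq: bytes) -> bytes:
    return seq.translate(_RC)[::-1]


def map_reads(
    reads: Iterable[tuple[str, str]],
    idx: SnippetIndex,
    coll: CollectiveSet,
    t: Transcriptome,
    orientation: str = "both",
    sample_id: str = "sample",
    truncate_to_L: bool = False,
) -> CountTable:
    """Assign a stream of (read id, sequence) pairs to genes/collective genes.

    Deterministic: identical inputs give identical tables.  ``truncate_to_L``
    optionally clips longer reads to their first L bases (off by default; the
    method is designed for read length equal to the snippet length).
    """
    if orientation not in ("forward", "both"):
        raise ValueError(f"orientation must be 'forward' or 'both', got {orientation!r}")
    L = idx.L
    lookup = build_lookup(idx, coll)
    n_genes = idx.n_genes
    names = list(t.ids) + list(coll.names)
    lengths = np.concatenate([t.lengths, collective_gene_lengths(coll, t)]).astype(
        np.int64
    )
    counts = np.zeros(len(names), dtype=np.int64)
    profiles = [
        np.zeros(max(0, int(lengths[i]) - L + 1) if i < n_genes else 0, dtype=np.int64)
        for i in range(len(names))
    ]
    # collective profiles live on the lowest-ordinal member's coordinates
    for cid, members in enumerate(coll.members):
        g0 = members[0]
        profiles[n_genes + cid] = np.zeros(
            max(0, int(t.lengths[g0]) - L + 1), dtype=np.int64
        )

    total_reads = total_mapped = n_badlen = 0
    for _rid, seq in reads:
        total_reads += 1
        b = seq.upper().encode("ascii")
        if len(b) != L:
            if truncate_to_L and len(b) > L:
                b = b[:L]
            else:
                n_badlen += 1
                continue
        hit = lookup.get(b)
        if hit is None and orientation == "both":
            hit = lookup.get(reverse_complement(b))
        if hit is None:
            continue
        entity, _g, pos = hit
        counts[entity] += 1
        profiles[entity][pos] += 1
        total_mapped += 1

    return CountTable(
        sample_id=sample_id,
        names=names,
        lengths=lengths,
        counts=counts,
        profiles=profiles,
        total_reads=total_reads,
        total_mapped=total_mapped,
        n_length_mismatch=n_badlen,
    )
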