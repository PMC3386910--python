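"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use plain Python strings / dense numpy comparisons,
a different algorithmic route from the hash-grouping implementation, so that
equivalence tests are meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from snipmap.collectives import CollectiveSet
from snipmap.index import SnippetIndex, Transcriptome

BASES = "ACGT"


def random_transcriptome(rng: np.random.Generator, n_genes: int,
                         min_len: int, max_len: int) -> Transcriptome:
    ids = [f"g{i}" for i in range(n_genes)]
    seqs = [
        "".join(rng.choice(list(BASES), size=rng.integers(min_len, max_len + 1)))
        for _ in range(n_genes)
    ]
    return Transcriptome(ids=ids, seqs=seqs)


# ------------------------------------------------------------------- oracles


def oracle_intragene_duplicates(t: Transcriptome, L: int) -> set[int]:
    """Concatenated offsets of snippets duplicated within their own gene."""
    masked: set[int] = set()
    offset = 0
    for seq in t.seqs:
        seen: dict[str, list[int]] = {}
        for i in range(len(seq) - L + 1):
            seen.setdefault(seq[i : i + L], []).append(offset + i)
        for positions in seen.values():
            if len(positions) >= 2:
                masked.update(positions)
        offset += len(seq)
    return masked


def oracle_shared_tally(t: Transcriptome, idx: SnippetIndex) -> dict[tuple[int, int], int]:
    """All-pairs count of L-mers mappable in both genes (string sets)."""
    L = idx.L
    per_gene: list[set[str]] = []
    for g in range(t.n_genes):
        lo = int(idx.gene_offsets[g])
        lmers = {
            t.seqs[g][i : i + L]
            for i in range(max(0, len(t.seqs[g]) - L + 1))
            if idx.status[lo + i]
        }
        per_gene.append(lmers)
    tally = {}
    for g1, g2 in itertools.combinations(range(t.n_genes), 2):
        n = len(per_gene[g1] & per_gene[g2])
        if n:
            tally[(g1, g2)] = n
    return tally


def oracle_hamming_census(idx: SnippetIndex, coll: CollectiveSet) -> set[int]:
    """Surviving snippet set by exhaustive pairwise Hamming comparison.

    Input: index state at phase IV entry (phases I-III applied).  A snippet
    survives iff no entry snippet of a gene outside its collective (and not
    its own gene) is within Hamming distance 1.
    """
    ids = idx.mappable_ids()
    if ids.size == 0:
        return set()
    win = np.ascontiguousarray(
        np.lib.stride_tricks.sliding_window_view(idx.seq_bytes, idx.L)[ids]
    )
    genes = idx.snippet_to_gene[ids]
    ckey = np.array(
        [
            coll.collective_of(int(g))
            if coll.collective_of(int(g)) is not None
            else -(int(g) + 1)
            for g in genes
        ]
    )
    n = ids.size
    doomed = np.zeros(n, dtype=bool)
    chunk = 512
    for a in range(0, n, chunk):
        block = win[a : a + chunk]
        dist = (block[:, None, :] != win[None, :, :]).sum(axis=2)
        close = dist <= 1
        conflict = close & (ckey[a : a + chunk, None] != ckey[None, :])
        doomed[a : a + chunk] |= conflict.any(axis=1)
        doomed |= conflict.any(axis=0)
    return set(int(s) for s in ids[~doomed])


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


@pytest.fixture
def rng():
    return np.random.default_rng(20120601)
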