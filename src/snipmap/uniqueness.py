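"""Robust-uniqueness masking: phase IV of the mapping pipeline.

A snippet is only a safe exact-match target if no snippet of another gene
(outside its own collective) is identical to it or differs from it at a single
base.  Otherwise a read carrying one sequencing error at that locus could be
exactly equal to the other gene's snippet and be silently miscounted; masking
the whole Hamming-distance-1 neighbourhood obviates mismapping from
single-base sequencing errors.

The contract is expressed as L+1 passes over the snippets that enter this
phase: pass 0 groups snippets by their full L-mer and marks cross-gene,
cross-collective groups; pass p (1..L) groups by the L-mer with position p
ignored, catching pairs that differ only at that position.  Every pass
compares the full phase-IV entry set, so the surviving set equals the
brute-force census {s : no entry snippet s' of a gene outside s's collective
has Hamming(s, s') <= 1}.  Identical snippets shared only within one
collective are deliberately left mappable: they are the collective gene's
counting territory.  Within-gene pairs at Hamming distance exactly 1 are not
masked (the cross-gene rule does not apply to them); exact within-gene
duplicates were already removed in phase II.
"""

from __future__ import annotations

import numpy as np

from .collectives import CollectiveSet
from .index import SnippetIndex, Transcriptome, _void_view


def _collective_keys(idx: SnippetIndex, coll: CollectiveSet) -> np.ndarray:
    """Per-gene grouping key: collective ordinal, or a unique key per singleton.

    Two snippets conflict iff their genes' keys differ, so genes in the same
    collective never mask each other while everything else does.
    """
    n = idx.n_genes
    keys = np.arange(n, dtype=np.int64) + coll.n_collectives  # unique per gene
    for cid, members in enumerate(coll.members):
        for g in members:
            keys[g] = cid
    return keys


def mark_cross_gene_collisions(
    idx: SnippetIndex, coll: CollectiveSet, t: Transcriptome
) -> SnippetIndex:
    """Mask every entry snippet with a cross-collective neighbour at Hamming <= 1.

    Runs L+1 grouping passes (recorded in ``idx.passes_run``); marks are
    collected against the full entry set and applied at the end, so the result
    is exactly the Hamming-<=1 census and is independent of pass order.
    """
    ids = idx.mappable_ids()
    L = idx.L
    idx.passes_run = 0
    if ids.size == 0:
        idx.passes_run = L + 1
        idx.log_phase("IV:uniqueness")
        return idx

    win = np.ascontiguousarray(
        np.lib.stride_tricks.sliding_window_view(idx.seq_bytes, L)[ids]
    )
    gene_keys = _collective_keys(idx, coll)[idx.snippet_to_gene[ids]]
    doomed = np.zeros(ids.size, dtype=bool)

    for p in range(L + 1):
        if p == 0:
            sub = win
        else:
            sub = np.delete(win, p - 1, axis=1)  # ignore base at position p
        keys = _void_view(sub)
        order = np.argsort(keys, kind="stable")
        ks = keys[order]
        bounds = np.flatnonzero(np.concatenate([[True], ks[1:] != ks[:-1], [True]]))
        gk = gene_keys[order]
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < 2:
                continue
            group_gk = gk[a:b]
            first = group_gk[0]
            if (group_gk != first).any():  # >= 2 distinct collective keys
                doomed[order[a:b]] = True
        idx.passes_run += 1

    idx.status[ids[doomed]] = False
    idx.log_phase("IV:uniqueness")
    return idx
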