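"""Snippet index over a transcriptome: phases I and II of the mapping pipeline.

The transcriptome (all predicted coding sequences, plus any appended auxiliary
sequences) is segmented into fixed-length windows ("snippets") of L nucleotides,
one per start position within each gene.  A snippet is addressed by a single
integer: its start offset in the gene-concatenated transcriptome, so snippet 0
begins at the first base of the first gene.  A status array records, for every
snippet, whether it is still a usable mapping target; later phases only ever
turn snippets off.

Phase I builds the index with every snippet MAPPABLE.  Phase II masks, within
each gene independently, every snippet whose L-mer occurs two or more times in
that gene (all copies are masked, which removes low-complexity sequence such as
extended trinucleotide repeats from the mapping-target set), and also masks any
snippet whose window overlaps an ambiguous (non-ACGT) base, since exact
matching cannot use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_ACGT = frozenset(b"ACGT")


@dataclass
class Transcriptome:
    """Ordered collection of named gene sequences.

    Gene order is the file order of the source FASTA and is preserved in every
    downstream table.  Sequences are uppercase; characters outside A/C/G/T are
    retained (the genes keep their true lengths) and handled by masking at the
    snippet level.
    """

    ids: list[str]
    seqs: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            for i in self.ids:
                if i in seen:
                    raise ValueError(f"duplicate gene identifier: {i!r}")
                seen.add(i)
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_genes(self) -> int:
        return len(self.ids)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.seqs], dtype=np.int64)

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def concatenated_bytes(self) -> np.ndarray:
        """The whole transcriptome as one uint8 array, genes back to back."""
        return np.frombuffer("".join(self.seqs).encode("ascii"), dtype=np.uint8).copy()


@dataclass
class SnippetIndex:
    """Integer-addressed snippet set with per-snippet mappability status.

    Attributes
    ----------
    L : snippet length in nucleotides.
    gene_offsets : start offset of each gene in the concatenated coordinate
        system; ``gene_offsets[-1]`` equals the total transcriptome length.
    valid : boolean per offset, True where a full L-window fits inside one gene.
    status : boolean per offset, True = MAPPABLE.  Meaningful only where
        ``valid``; kept False elsewhere so that ``valid & status`` is simply
        ``status``.
    snippet_to_gene : gene ordinal for every transcriptome offset.
    seq_bytes : the concatenated uppercase sequence as uint8.
    phase_log : (phase name, number of mappable snippets after it) pairs,
        appended by each phase for the CLI log.
    passes_run : number of hash/comparison passes executed by the robust-
        uniqueness phase (0 until that phase has run).
    """

    L: int
    gene_offsets: np.ndarray
    valid: np.ndarray
    status: np.ndarray
    snippet_to_gene: np.ndarray
    seq_bytes: np.ndarray
    phase_log: list[tuple[str, int]] = field(default_factory=list)
    passes_run: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.gene_offsets) - 1

    def gene_length(self, g: int) -> int:
        return int(self.gene_offsets[g + 1] - self.gene_offsets[g])

    def gene_window_count(self, g: int) -> int:
        """Number of valid snippets of gene g (zero if shorter than L)."""
        return max(0, self.gene_length(g) - self.L + 1)

    def mappable_ids(self) -> np.ndarray:
        """Sorted integer ids of snippets currently MAPPABLE."""
        return np.flatnonzero(self.status)

    def n_mappable(self) -> int:
        return int(self.status.sum())

    def snippet_bytes(self, s: int) -> bytes:
        return self.seq_bytes[s : s + self.L].tobytes()

    def windows_of_gene(self, g: int) -> np.ndarray:
        """(n_windows, L) uint8 view of gene g's snippets (may be empty)."""
        lo, hi = int(self.gene_offsets[g]), int(self.gene_offsets[g + 1])
        seg = self.seq_bytes[lo:hi]
        if seg.size < self.L:
            return np.empty((0, self.L), dtype=np.uint8)
        return np.lib.stride_tricks.sliding_window_view(seg, self.L)

    def log_phase(self, name: str) -> None:
        self.phase_log.append((name, self.n_mappable()))


def build_index(t: Transcriptome, L: int) -> SnippetIndex:
    """Phase I: segment the transcriptome into L-base snippets.

    One snippet per start position within each gene (sliding window, step 1 —
    forced by the integer-offset snippet addressing).  Genes shorter than L
    contribute no snippets.  All snippets start MAPPABLE.
    """
    if L < 1:
        raise ValueError(f"snippet length must be >= 1, got {L}")
    lengths = t.lengths
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(offsets[-1])

    valid = np.zeros(total, dtype=bool)
    for g in range(t.n_genes):
        lo, hi = int(offsets[g]), int(offsets[g + 1])
        if hi - lo >= L:
            valid[lo : hi - L + 1] = True

    snippet_to_gene = np.repeat(np.arange(t.n_genes, dtype=np.int64), lengths)
    idx = SnippetIndex(
        L=L,
        gene_offsets=offsets,
        valid=valid,
        status=valid.copy(),
        snippet_to_gene=snippet_to_gene,
        seq_bytes=t.concatenated_bytes(),
    )
    idx.log_phase("I:index")
    return idx


def _void_view(mat: np.ndarray) -> np.ndarray:
    """Row-wise hashable view of a 2-D uint8 array for np.unique grouping."""
    mat = np.ascontiguousarray(mat)
    return mat.view(np.dtype((np.void, mat.shape[1]))).ravel()


def mark_intragene_duplicates(idx: SnippetIndex, t: Transcriptome) -> SnippetIndex:
    """Phase II: mask intra-gene duplicate snippets and ambiguous-base windows.

    Genes are processed independently.  Every snippet whose L-mer occurs two or
    more times within its own gene is masked (all occurrences).  Snippets whose
    window overlaps a base outside A/C/G/T are masked here as well.  Idempotent;
    never un-masks a snippet.
    """
    ambiguous = ~np.isin(idx.seq_bytes, np.frombuffer(b"ACGT", dtype=np.uint8))
    if ambiguous.any():
        # a window [s, s+L) is bad if any ambiguous base falls inside it
        bad_cum = np.concatenate([[0], np.cumsum(ambiguous)])
        starts = np.flatnonzero(idx.valid)
        overlaps = bad_cum[starts + idx.L] - bad_cum[starts] > 0
        idx.status[starts[overlaps]] = False

    for g in range(idx.n_genes):
        win = idx.windows_of_gene(g)
        if win.shape[0] < 2:
            continue
        keys = _void_view(win)
        _, inverse, counts = np.unique(keys, return_inverse=True, return_counts=True)
        dup = counts[inverse] >= 2
        if dup.any():
            lo = int(idx.gene_offsets[g])
            idx.status[lo + np.flatnonzero(dup)] = False
    idx.log_phase("II:intragene")
    return idx
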