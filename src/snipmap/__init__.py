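"""snipmap: snippet-based exact-match mRNA-Seq read mapping and quantification.

The pipeline runs in five phases: (I) segment the transcriptome into
fixed-length integer-addressed snippets; (II) mask intra-gene duplicate
snippets; (III) group near-identical genes into collectives with synthetic
collective-gene entries; (IV) mask every snippet confusable across genes at
Hamming distance <= 1, leaving only robustly unique mapping targets; (V)
assign reads by exact match to genes or collective genes.  Downstream modules
compute normalized hits, RPKM, mutant/wild-type regulation factors, candidate
selection with a significance screen, and unit-sum time-course profiles.
"""

from .collectives import CollectiveSet, build_collectives, tally_shared_snippets
from .index import SnippetIndex, Transcriptome, build_index, mark_intragene_duplicates
from .io_formats import (
    SampleSheet,
    iter_reads,
    load_sample_sheet,
    load_transcriptome,
    read_count_table,
    write_count_table,
)
from .mapper import CountTable, map_reads
from .quantify import (
    ProfileSet,
    build_profile_set,
    build_regulation_table,
    group_average_profile,
    normalized_hits,
    profile_offset_test,
    regulation_factor,
    rpkm,
    unit_sum_profile,
)
from .select_genes import (
    call_candidates,
    classify_genes,
    conditional_binomial_test,
    scatter_coordinates,
    significance_filter,
)
from .synth import SimSpec, cell_cycle_profile, simulate_reads, simulate_transcriptome
from .uniqueness import mark_cross_gene_collisions

__version__ = "0.1.0"

__all__ = [
    "CollectiveSet",
    "CountTable",
    "ProfileSet",
    "SampleSheet",
    "SimSpec",
    "SnippetIndex",
    "Transcriptome",
    "build_collectives",
    "build_index",
    "build_profile_set",
    "build_regulation_table",
    "call_candidates",
    "cell_cycle_profile",
    "classify_genes",
    "conditional_binomial_test",
    "group_average_profile",
    "iter_reads",
    "load_sample_sheet",
    "load_transcriptome",
    "map_reads",
    "mark_cross_gene_collisions",
    "mark_intragene_duplicates",
    "normalized_hits",
    "profile_offset_test",
    "read_count_table",
    "regulation_factor",
    "rpkm",
    "scatter_coordinates",
    "significance_filter",
    "simulate_reads",
    "simulate_transcriptome",
    "tally_shared_snippets",
    "unit_sum_profile",
    "write_count_table",
]


def build_full_index(t: Transcriptome, L: int = 42):
    """Run phases I-IV and return (index, collectives)."""
    idx = build_index(t, L)
    mark_intragene_duplicates(idx, t)
    coll = build_collectives(tally_shared_snippets(idx, t), idx, t)
    mark_cross_gene_collisions(idx, coll, t)
    return idx, coll
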