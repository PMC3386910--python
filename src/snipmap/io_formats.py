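"""External formats: FASTA/FASTQ input, TSV tables, index serialization.

All coordinates written by this package are 0-based, half-open.  Row order in
every table is deterministic: real genes in input FASTA order, collective
genes appended.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from .collectives import CollectiveSet
from .index import SnippetIndex, Transcriptome
from .mapper import CountTable


def load_transcriptome(
    path: "str | Path",
    split_rules: "list[tuple[str, int]] | None" = None,
) -> Transcriptome:
    """Load gene sequences from FASTA, optionally splitting named records.

    A split rule (gene_id, cut) replaces the record by ``gene_id.part1`` (the
    first ``cut`` bases) and ``gene_id.part2`` (the rest), preventing one
    chimeric sequence from fusing two otherwise-separate gene collectives.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    ids = [r.id for r in records]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate gene identifier in {path}: {i!r}")
        seen.add(i)
    rules = dict(split_rules or [])
    unknown = set(rules) - set(ids)
    if unknown:
        raise ValueError(f"split rule names unknown gene(s): {sorted(unknown)}")
    out_ids: list[str] = []
    out_seqs: list[str] = []
    for r in records:
        seq = str(r.seq).upper()
        if r.id in rules:
            cut = rules[r.id]
            if not 0 < cut < len(seq):
                raise ValueError(
                    f"split position {cut} outside gene {r.id!r} (length {len(seq)})"
                )
            out_ids.extend([f"{r.id}.part1", f"{r.id}.part2"])
            out_seqs.extend([seq[:cut], seq[cut:]])
        else:
            out_ids.append(r.id)
            out_seqs.append(seq)
    return Transcriptome(ids=out_ids, seqs=out_seqs)


def write_transcriptome(t: Transcriptome, path: "str | Path") -> None:
    with open(path, "w") as fh:
        for gid, seq in zip(t.ids, t.seqs):
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def iter_reads(path: "str | Path") -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from FASTQ or FASTA; qualities are ignored.

    Format chosen by extension (.fastq/.fq -> FASTQ, else FASTA).
    """
    fmt = "fastq" if str(path).endswith((".fastq", ".fq")) else "fasta"
    for rec in SeqIO.parse(str(path), fmt):
        yield rec.id, str(rec.seq)


def write_reads(reads: Iterable[tuple[str, str]], path: "str | Path") -> None:
    """Write reads as FASTQ (constant quality) or FASTA by extension."""
    fastq = str(path).endswith((".fastq", ".fq"))
    with open(path, "w") as fh:
        for rid, seq in reads:
            if fastq:
                fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            else:
                fh.write(f">{rid}\n{seq}\n")


@dataclass
class SampleSheet:
    """Experimental design: which read file is which strain/stage/replicate."""

    table: pd.DataFrame  # columns: sample_id, read_file, strain, stage, replicate

    REQUIRED = ("sample_id", "read_file", "strain", "stage", "replicate")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        sids = self.table["sample_id"]
        if sids.duplicated().any():
            dup = sids[sids.duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        if (self.table["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be >= 1")

    def samples(self, strain: "str | None" = None, stage: "str | None" = None) -> list[str]:
        tbl = self.table
        if strain is not None:
            tbl = tbl[tbl["strain"] == strain]
        if stage is not None:
            tbl = tbl[tbl["stage"] == stage]
        return list(tbl["sample_id"])


def load_sample_sheet(path: "str | Path", check_files: bool = True) -> SampleSheet:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    sheet = SampleSheet(table=table)
    if check_files:
        base = Path(path).parent
        for f in table["read_file"]:
            p = Path(f)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"read file listed in sample sheet missing: {f}")
    return sheet


# ---------------------------------------------------------------- count tables

COUNT_COLUMNS = ["gene", "length", "count", "normalized_hits", "rpkm"]


def write_count_table(counts: CountTable, path: "str | Path") -> None:
    """One row per gene/collective gene: id, length, raw count, normalized
    hits, RPKM; gene order preserved, collectives last."""
    from .quantify import normalized_hits, rpkm_table  # local import: no cycle

    if counts.total_mapped > 0:
        nh = normalized_hits(counts)
        rp = rpkm_table(counts)
    else:
        nh = np.zeros(counts.n_entities)
        rp = np.zeros(counts.n_entities)
    df = pd.DataFrame(
        {
            "gene": counts.names,
            "length": counts.lengths,
            "count": counts.counts,
            "normalized_hits": nh,
            "rpkm": rp,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# sample={counts.sample_id}\ttotal_reads={counts.total_reads}\t"
                 f"total_mapped={counts.total_mapped}\t"
                 f"length_mismatch={counts.n_length_mismatch}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_count_table(path: "str | Path") -> CountTable:
    """Parse a written count table back (profiles are not round-tripped)."""
    with open(path) as fh:
        header = fh.readline()
        meta = dict(
            item.split("=", 1) for item in header.lstrip("# ").rstrip("\n").split("\t")
        )
        df = pd.read_csv(fh, sep="\t")
    counts = df["count"].to_numpy(dtype=np.int64)
    return CountTable(
        sample_id=meta["sample"],
        names=list(df["gene"]),
        lengths=df["length"].to_numpy(dtype=np.int64),
        counts=counts,
        profiles=[np.zeros(0, dtype=np.int64)] * len(df),
        total_reads=int(meta["total_reads"]),
        total_mapped=int(meta["total_mapped"]),
        n_length_mismatch=int(meta["length_mismatch"]),
    )


def write_profiles(counts: CountTable, path: "str | Path") -> None:
    """Positional match profiles, one row per (gene, snippet start)."""
    rows = []
    for name, prof in zip(counts.names, counts.profiles):
        for pos in np.flatnonzero(prof):
            rows.append((name, int(pos), int(prof[pos])))
    pd.DataFrame(rows, columns=["gene", "start", "count"]).to_csv(
        path, sep="\t", index=False
    )


# ------------------------------------------------------------- index on disk


def write_index(idx: SnippetIndex, t: Transcriptome, path: "str | Path") -> None:
    """Serialize the index as TSV: gene table then MAPPABLE status runs.

    Status runs are (start, end) half-open intervals over the concatenated
    transcriptome coordinate; everything outside a run is non-mappable.
    """
    with open(path, "w") as fh:
        fh.write(f"#L\t{idx.L}\n")
        fh.write(f"#passes_run\t{idx.passes_run}\n")
        for name, n in idx.phase_log:
            fh.write(f"#phase\t{name}\t{n}\n")
        for gid, length in zip(t.ids, t.lengths):
            fh.write(f"G\t{gid}\t{length}\n")
        status = idx.status
        edges = np.flatnonzero(np.diff(np.concatenate([[0], status.view(np.int8), [0]])))
        for a, b in zip(edges[::2], edges[1::2]):
            fh.write(f"R\t{a}\t{b}\n")


def read_index(path: "str | Path", t: Transcriptome) -> SnippetIndex:
    from .index import build_index

    L = None
    passes = 0
    phase_log: list[tuple[str, int]] = []
    runs: list[tuple[int, int]] = []
    genes: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#L":
                L = int(parts[1])
            elif parts[0] == "#passes_run":
                passes = int(parts[1])
            elif parts[0] == "#phase":
                phase_log.append((parts[1], int(parts[2])))
            elif parts[0] == "G":
                genes.append((parts[1], int(parts[2])))
            elif parts[0] == "R":
                runs.append((int(parts[1]), int(parts[2])))
    if L is None:
        raise ValueError(f"not an index file (no #L line): {path}")
    if genes != list(zip(t.ids, (len(s) for s in t.seqs))):
        raise ValueError("index was built from a different transcriptome")
    idx = build_index(t, L)
    idx.status[:] = False
    for a, b in runs:
        idx.status[a:b] = True
    idx.passes_run = passes
    idx.phase_log = phase_log
    return idx


def write_collectives(coll: CollectiveSet, t: Transcriptome, path: "str | Path") -> None:
    rows = [
        (coll.names[cid], t.ids[g])
        for cid, members in enumerate(coll.members)
        for g in members
    ]
    pd.DataFrame(rows, columns=["collective_id", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_collectives(path: "str | Path", t: Transcriptome) -> CollectiveSet:
    df = pd.read_csv(path, sep="\t")
    ordinal = {gid: i for i, gid in enumerate(t.ids)}
    coll = CollectiveSet()
    for name, grp in df.groupby("collective_id", sort=False):
        cid = len(coll.members)
        members = sorted(ordinal[g] for g in grp["gene_id"])
        coll.members.append(members)
        coll.names.append(str(name))
        for g in members:
            coll.gene_to_collective[g] = cid
    return coll


# ------------------------------------------------------------------ utilities


def file_checksum(path: "str | Path") -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def parse_config(path: "str | Path") -> dict[str, str]:
    """Plain-text ``key = value`` configuration; '#' starts a comment."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"malformed config line: {raw.rstrip()!r}")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out
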