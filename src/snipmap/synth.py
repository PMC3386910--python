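"""Synthetic fixtures with known ground truth for every pipeline stage.

Emulates the structure the method was designed for: a transcriptome of mostly
singleton coding sequences plus a few families of near-identical genes (the
multi-copy transposable-element case), and fixed-length reads sampled from
known genes at known abundances with independent per-base substitution errors.
Under an exact-match mapper an indel in a read guarantees a miss just like a
substitution does, so a substitution-only error model loses no generality for
testing.  Everything is deterministic under the spec's seed.

Two closed forms are useful for tests.  Each descendant mutates independently
from the ancestor at per-site rate d, so two family members agree at one site
with probability (1-d)**2 + (d**2)/3 (both unchanged, or both mutated to the
same of three alternatives) and share a whole L-mer window with that quantity
to the power L.  A read with per-base error rate e survives exact matching
only if all L bases are error-free, probability (1-e)**L.

A "cell-cycle mode" produces time-course expression shaped as a von Mises
density around a peak phase, averaged over a population phase dispersion;
increasing dispersion damps the observed modulation, mimicking incomplete
synchronization.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .index import Transcriptome

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimSpec:
    """Parameters of a synthetic experiment.

    ``divergence`` is substitutions per site applied independently to each
    family member relative to the common ancestor.  ``abundance`` maps gene id
    to relative expression weight (unset genes get weight 1).  ``fold_map``
    multiplies abundances in the "mutant" condition.
    """

    n_singletons: int = 20
    gene_length_mean: int = 1000
    gene_length_sd: int = 200
    min_gene_length: int = 200
    n_families: int = 2
    family_size: int = 3
    family_gene_length: int = 1000
    divergence: float = 0.005
    read_length: int = 42
    error_rate: float = 0.0
    n_reads: int = 10000
    abundance: dict[str, float] = field(default_factory=dict)
    fold_map: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (("divergence", self.divergence), ("error_rate", self.error_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def simulate_transcriptome(spec: SimSpec) -> tuple[Transcriptome, dict[str, list[str]]]:
    """Generate singletons plus mutated-ancestor families.

    Returns the transcriptome (families first, then singletons, ids
    ``FAM<k>_<m>`` and ``GENE<n>``) and the family truth table mapping family
    id to its member gene ids.
    """
    rng = np.random.default_rng(spec.seed)
    ids: list[str] = []
    seqs: list[str] = []
    families: dict[str, list[str]] = {}
    for f in range(spec.n_families):
        ancestor = _random_seq(rng, spec.family_gene_length)
        fam_id = f"FAM{f + 1}"
        families[fam_id] = []
        for m in range(spec.family_size):
            gid = f"{fam_id}_{m + 1}"
            seqs.append(_mutate(rng, ancestor, spec.divergence).tobytes().decode("ascii"))
            ids.append(gid)
            families[fam_id].append(gid)
    for n in range(spec.n_singletons):
        length = max(
            spec.min_gene_length,
            int(rng.normal(spec.gene_length_mean, spec.gene_length_sd)),
        )
        ids.append(f"GENE{n + 1}")
        seqs.append(_random_seq(rng, length).tobytes().decode("ascii"))
    return Transcriptome(ids=ids, seqs=seqs), families


def simulate_reads(
    t: Transcriptome,
    spec: SimSpec,
    condition: str = "wt",
    seed_offset: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, int]]:
    """Draw reads with uniform start positions and per-base substitution errors.

    Gene weights are ``abundance`` (default 1) scaled by the gene's number of
    read start positions, times ``fold_map`` when ``condition == "mutant"``;
    the realized per-gene read counts are returned as the truth table.
    ``seed_offset`` decouples replicates/conditions under one spec seed.
    """
    rng = np.random.default_rng(
        (spec.seed, seed_offset, zlib.crc32(condition.encode("utf-8")))
    )
    L = spec.read_length
    starts_per_gene = np.array([max(0, len(s) - L + 1) for s in t.seqs], dtype=float)
    weights = np.array([spec.abundance.get(g, 1.0) for g in t.ids]) * starts_per_gene
    if condition == "mutant":
        weights *= np.array([spec.fold_map.get(g, 1.0) for g in t.ids])
    if weights.sum() <= 0:
        raise ValueError("no gene can produce a read of this length")
    probs = weights / weights.sum()
    gene_draws = rng.multinomial(spec.n_reads, probs)
    reads: list[tuple[str, str]] = []
    truth: dict[str, int] = {g: int(c) for g, c in zip(t.ids, gene_draws)}
    k = 0
    for g, n_g in enumerate(gene_draws):
        if n_g == 0:
            continue
        seq = np.frombuffer(t.seqs[g].encode("ascii"), dtype=np.uint8)
        n_starts = len(t.seqs[g]) - L + 1
        for pos in rng.integers(0, n_starts, size=n_g):
            frag = seq[pos : pos + L]
            if spec.error_rate > 0:
                frag = _mutate(rng, frag, spec.error_rate)
            reads.append((f"read{k}_{t.ids[g]}", frag.tobytes().decode("ascii")))
            k += 1
    # deterministic shuffle so reads are not grouped by gene
    order = rng.permutation(len(reads))
    return [reads[i] for i in order], truth


def expected_regulation_factor(t: Transcriptome, spec: SimSpec, gene: str) -> float:
    """Closed-form value of the normalized-hits regulation factor the
    generator programs for ``gene``.

    The estimand is a ratio of within-sample fractions, so a fold change on
    one gene also shifts the mutant sample's total: the expected factor is
    fold(gene) * (sum of wild-type weights) / (sum of mutant weights), not the
    bare fold.  The discrepancy is negligible when regulated genes carry a
    small share of the library, as in real data.
    """
    L = spec.read_length
    starts = np.array([max(0, len(s) - L + 1) for s in t.seqs], dtype=float)
    w_wt = np.array([spec.abundance.get(g, 1.0) for g in t.ids]) * starts
    w_mut = w_wt * np.array([spec.fold_map.get(g, 1.0) for g in t.ids])
    return spec.fold_map.get(gene, 1.0) * w_wt.sum() / w_mut.sum()


def cell_cycle_profile(
    n_timepoints: int,
    peak_phase: float,
    concentration: float = 4.0,
    phase_dispersion: float = 0.0,
    n_cells: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Population-average cyclic expression over one cell-cycle period.

    Each cell expresses along the cycle as a von Mises bump of the given
    concentration around ``peak_phase`` (radians); cells' phases are offset by
    a wrapped-normal dispersion, emulating imperfect synchronization.  Returns
    a unit-sum profile; larger ``phase_dispersion`` flattens it.
    """
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, 2 * np.pi, n_timepoints, endpoint=False)
    if phase_dispersion > 0:
        offsets = rng.normal(0.0, phase_dispersion, size=n_cells)
    else:
        offsets = np.zeros(1)
    bump = np.exp(
        concentration * np.cos(theta[None, :] - peak_phase - offsets[:, None])
    ).mean(axis=0)
    return bump / bump.sum()
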