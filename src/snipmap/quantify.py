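"""Quantification: normalized hits, RPKM, regulation factors, time-course
profiles and the chi-squared profile-offset test.

Normalized hits express a gene's mapped-read count as a fraction of all reads
assigned to any gene or collective gene in the sample; they sum to one per
sample, and differ from RPKM per gene only by the factor 1e9/length(nt).
Mutant-specific regulation factors divide replicate-averaged normalized hits
in the disruptant by those in the wild type, computed separately for growing
and developing cells.  Time-course series are rescaled to unit sum so that
profile shapes can be averaged over gene groups and compared across genes of
very different absolute expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mapper import CountTable

DEFAULT_PSEUDOCOUNT = 0.5


def normalized_hits(counts: CountTable) -> np.ndarray:
    """Per-entity fraction of the sample's mapped reads; sums to 1."""
    if counts.total_mapped <= 0:
        raise ValueError("cannot normalize a sample with zero mapped reads")
    return counts.counts / counts.total_mapped


def rpkm(count: float, gene_length: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript model per million mapped reads."""
    if gene_length <= 0:
        raise ValueError(f"gene length must be positive, got {gene_length}")
    if total_mapped <= 0:
        raise ValueError(f"total mapped reads must be positive, got {total_mapped}")
    return count / (gene_length / 1e3) / (total_mapped / 1e6)


def rpkm_table(counts: CountTable) -> np.ndarray:
    return np.array(
        [
            rpkm(int(c), int(l), counts.total_mapped)
            for c, l in zip(counts.counts, counts.lengths)
        ]
    )


def regulation_factor(
    mutant: "np.ndarray | list[float]",
    wt: "np.ndarray | list[float]",
    *,
    mutant_totals: "np.ndarray | list[float] | None" = None,
    wt_totals: "np.ndarray | list[float] | None" = None,
    pseudocount_reads: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Ratio of replicate-averaged normalized hits, mutant over wild type.

    With ``*_totals`` given, ``mutant``/``wt`` are raw per-replicate counts and
    the pseudocount (in reads) is added to every count before normalization
    whenever either side's mean would otherwise be zero.  Without totals the
    inputs are taken as already-normalized fractions (no pseudocount possible).
    Returns NaN when the factor is undefined (both sides zero).
    """
    mutant = np.asarray(mutant, dtype=float)
    wt = np.asarray(wt, dtype=float)
    if mutant.size == 0 or wt.size == 0:
        raise ValueError("need at least one sample per side")
    if (mutant_totals is None) != (wt_totals is None):
        raise ValueError("give totals for both sides or neither")
    if mutant_totals is not None:
        mt = np.asarray(mutant_totals, dtype=float)
        wtot = np.asarray(wt_totals, dtype=float)
        if mutant.mean() == 0.0 or wt.mean() == 0.0:
            if mutant.sum() == 0.0 and wt.sum() == 0.0 and pseudocount_reads == 0.0:
                return float("nan")
            mutant = mutant + pseudocount_reads
            wt = wt + pseudocount_reads
        mutant = mutant / mt
        wt = wt / wtot
    m, w = mutant.mean(), wt.mean()
    if m == 0.0 and w == 0.0:
        return float("nan")
    if w == 0.0:
        return float("inf")
    return float(m / w)


def build_regulation_table(
    samples: dict[str, CountTable],
    contrasts: dict[str, tuple[list[str], list[str]]],
    pseudocount_reads: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Assemble per-gene normalized hits, RPKM and regulation factors.

    ``contrasts`` maps a contrast name (e.g. "growth", "development") to
    (mutant sample ids, wild-type sample ids).  Output columns: per-sample
    ``nh_<sample>`` and ``rpkm_<sample>``, then per-contrast
    ``factor_<contrast>`` and ``log2_<contrast>``.
    """
    first = next(iter(samples.values()))
    names = first.names
    for ct in samples.values():
        if ct.names != names:
            raise ValueError("count tables disagree on gene set or order")
    df = pd.DataFrame({"gene": names, "length": first.lengths})
    for sid, ct in samples.items():
        df[f"nh_{sid}"] = normalized_hits(ct)
        df[f"rpkm_{sid}"] = rpkm_table(ct)
    for cname, (mut_ids, wt_ids) in contrasts.items():
        mut_counts = np.stack([samples[s].counts for s in mut_ids], axis=1)
        wt_counts = np.stack([samples[s].counts for s in wt_ids], axis=1)
        mut_tot = np.array([samples[s].total_mapped for s in mut_ids], dtype=float)
        wt_tot = np.array([samples[s].total_mapped for s in wt_ids], dtype=float)
        factors = np.array(
            [
                regulation_factor(
                    mut_counts[i],
                    wt_counts[i],
                    mutant_totals=mut_tot,
                    wt_totals=wt_tot,
                    pseudocount_reads=pseudocount_reads,
                )
                for i in range(len(names))
            ]
        )
        df[f"factor_{cname}"] = factors
        with np.errstate(divide="ignore", invalid="ignore"):
            df[f"log2_{cname}"] = np.log2(factors)
    return df


def unit_sum_profile(series: "np.ndarray | list[float]") -> np.ndarray:
    """Rescale a time-course series to total 1, preserving its shape."""
    series = np.asarray(series, dtype=float)
    total = series.sum()
    if total <= 0:
        raise ValueError("cannot unit-normalize an all-zero (or negative) series")
    return series / total


def group_average_profile(profiles: list[np.ndarray]) -> np.ndarray:
    """Unweighted elementwise mean of unit-sum profiles (itself unit-sum)."""
    if len(profiles) == 0:
        raise ValueError("empty profile group")
    mat = np.stack([np.asarray(p, dtype=float) for p in profiles])
    return mat.mean(axis=0)


@dataclass
class ProfileSet:
    """Unit-sum time-course profiles per gene plus named group averages.

    Genes whose series is all zero over the course are excluded from group
    averages and listed in ``excluded``.
    """

    timepoints: list[str]
    profiles: pd.DataFrame  # index = gene, columns = timepoints
    group_profiles: pd.DataFrame
    excluded: list[str]


def build_profile_set(
    series: pd.DataFrame, groups: dict[str, list[str]] | None = None
) -> ProfileSet:
    """Unit-normalize per-gene count series (rows=genes, cols=time points)."""
    totals = series.sum(axis=1)
    excluded = list(series.index[totals <= 0])
    kept = series.loc[totals > 0]
    profiles = kept.div(kept.sum(axis=1), axis=0)
    group_rows = {}
    for gname, members in (groups or {}).items():
        present = [m for m in members if m in profiles.index]
        if not present:
            raise ValueError(f"group {gname!r} has no usable members")
        group_rows[gname] = group_average_profile(
            [profiles.loc[m].to_numpy() for m in present]
        )
    return ProfileSet(
        timepoints=list(series.columns),
        profiles=profiles,
        group_profiles=pd.DataFrame.from_dict(
            group_rows, orient="index", columns=series.columns
        ),
        excluded=excluded,
    )


def profile_offset_test(
    series_a: "np.ndarray | list[int]", series_b: "np.ndarray | list[int]"
) -> tuple[float, float, int]:
    """Pearson chi-squared homogeneity test of two count series over time.

    Tests whether the two series are proportional (same profile shape) against
    the 2xT contingency table of raw counts; T-1 degrees of freedom.  Time
    points where both series are zero are dropped (reducing the df).  Returns
    (statistic, p-value, df used).
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must cover the same time points")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    keep = (a + b) > 0
    a, b = a[keep], b[keep]
    if a.size < 2:
        raise ValueError("need at least two informative time points")
    table = np.stack([a, b])
    if table.sum(axis=1).min() == 0:
        # one series entirely zero: homogeneity is degenerate
        raise ValueError("one series has no counts at all")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)
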