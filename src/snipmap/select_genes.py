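"""Candidate selection for differential regulation.

Genes are placed on a log2 scatter of growth-phase versus development-phase
regulation factors (mutant/wild-type).  A Euclidean distance of 0.5 from the
origin on that plot corresponds to a combined linear change of 2**0.5 ~ 1.41,
i.e. roughly 40% up- or down-regulation; unregulated genes cluster near the
origin.  Genes or collectives with a linear factor of 2 or more in growth
and/or development become candidates, and candidates are then screened with a
two-condition count test (pluggable; the built-in default is the exact
conditional binomial test of equal proportions given library sizes) with
Benjamini-Hochberg adjustment across candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_MIN_FOLD = 2.0
DEFAULT_ALPHA = 0.05

# a two-condition count test: (counts_a, totals_a, counts_b, totals_b) -> p-value
CountTest = Callable[
    [Sequence[int], Sequence[int], Sequence[int], Sequence[int]], float
]


def scatter_coordinates(reg: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (x, y) = (log2 growth factor, log2 development factor).

    Genes whose factor is undefined (NaN) or zero/infinite in either contrast
    are excluded; the number excluded is available as ``df.attrs['n_excluded']``.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.log2(reg["factor_growth"].to_numpy(dtype=float))
        y = np.log2(reg["factor_development"].to_numpy(dtype=float))
    ok = np.isfinite(x) & np.isfinite(y)
    out = pd.DataFrame({"gene": reg["gene"][ok], "x": x[ok], "y": y[ok]})
    out.attrs["n_excluded"] = int((~ok).sum())
    return out.reset_index(drop=True)


def call_candidates(reg: pd.DataFrame, min_fold: float = DEFAULT_MIN_FOLD) -> pd.DataFrame:
    """Flag genes with linear induction factor >= min_fold (boundary inclusive)
    in growth and/or development."""
    g = reg["factor_growth"].to_numpy(dtype=float)
    d = reg["factor_development"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        flag = (g >= min_fold) | (d >= min_fold)
    out = reg.copy()
    out["candidate"] = flag
    return out


def conditional_binomial_test(
    counts_a: Sequence[int],
    totals_a: Sequence[int],
    counts_b: Sequence[int],
    totals_b: Sequence[int],
) -> float:
    """Exact two-sided test that a gene's reads split between two conditions in
    proportion to the library sizes.

    Replicates are pooled within each condition; given the gene's total reads
    k = k_a + k_b, k_a ~ Binomial(k, N_a/(N_a+N_b)) under the null of equal
    relative expression.  Deterministic and dispersion-free, so it is anti-
    conservative in the presence of biological overdispersion; any other
    two-condition count test can be plugged in instead.
    """
    ka, kb = int(np.sum(counts_a)), int(np.sum(counts_b))
    na, nb = float(np.sum(totals_a)), float(np.sum(totals_b))
    k = ka + kb
    if k == 0:
        return 1.0
    return float(stats.binomtest(ka, k, na / (na + nb)).pvalue)


@dataclass
class SelectionResult:
    """Outcome of the fold + significance screen."""

    table: pd.DataFrame  # candidates with p, p_adj, selected flag
    n_failed: int  # genes where the test errored (reported NA, excluded)


def significance_filter(
    candidates: pd.DataFrame,
    mutant_counts: pd.DataFrame,
    wt_counts: pd.DataFrame,
    mutant_totals: Sequence[int],
    wt_totals: Sequence[int],
    test: CountTest = conditional_binomial_test,
    alpha: float = DEFAULT_ALPHA,
) -> SelectionResult:
    """Test each candidate for differential counts; BH-adjust; keep p_adj < alpha.

    ``mutant_counts``/``wt_counts`` are gene x replicate count frames indexed by
    gene id; ``candidates`` is the output of :func:`call_candidates` (only rows
    with ``candidate`` True are tested).
    """
    cand = candidates[candidates["candidate"]].copy()
    pvals = np.full(len(cand), np.nan)
    n_failed = 0
    for i, gene in enumerate(cand["gene"]):
        try:
            pvals[i] = test(
                mutant_counts.loc[gene].to_numpy(),
                np.asarray(mutant_totals),
                wt_counts.loc[gene].to_numpy(),
                np.asarray(wt_totals),
            )
        except Exception:
            n_failed += 1
    cand["p"] = pvals
    ok = np.isfinite(pvals)
    padj = np.full(len(cand), np.nan)
    if ok.any():
        _, padj_ok, _, _ = multipletests(pvals[ok], alpha=alpha, method="fdr_bh")
        padj[ok] = padj_ok
    cand["p_adj"] = padj
    cand["selected"] = np.where(np.isfinite(padj), padj < alpha, False)
    return SelectionResult(table=cand.reset_index(drop=True), n_failed=n_failed)


def classify_genes(
    reg: pd.DataFrame,
    selected: "set[str] | Sequence[str]",
    dev_induction: "pd.Series | None" = None,
    min_fold: float = DEFAULT_MIN_FOLD,
) -> pd.Series:
    """Assign each gene to one of the scatter classes (or 'unclassified').

    - ``repressed_by_mutant_target``: significantly mutant-up (factor >=
      min_fold in growth and/or development) — genes the wild-type regulator
      represses.
    - ``activated_by_mutant_target``: significantly mutant-down (factor <=
      1/min_fold), mirroring the repressed rule.
    - ``dev_induced_independent``: developmentally induced in the wild type
      (``dev_induction`` >= min_fold, when provided) but within the
      (1/min_fold, min_fold) mutant/wild-type band in development.

    The three classes are disjoint by construction of the fold bands.
    """
    selected = set(selected)
    g = reg["factor_growth"].to_numpy(dtype=float)
    d = reg["factor_development"].to_numpy(dtype=float)
    out = []
    for i, gene in enumerate(reg["gene"]):
        up = (g[i] >= min_fold) or (d[i] >= min_fold)
        down = (g[i] <= 1.0 / min_fold) or (d[i] <= 1.0 / min_fold)
        if gene in selected and up:
            out.append("repressed_by_mutant_target")
        elif gene in selected and down and not up:
            out.append("activated_by_mutant_target")
        elif (
            dev_induction is not None
            and gene in dev_induction.index
            and dev_induction[gene] >= min_fold
            and 1.0 / min_fold < d[i] < min_fold
        ):
            out.append("dev_induced_independent")
        else:
            out.append("unclassified")
    return pd.Series(out, index=reg.index, name="class")
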