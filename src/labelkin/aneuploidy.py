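"""Whole-chromosome expression-shift (aneuploidy) calling from bulk expression.

Each gene's expression (log2 scale) is referenced to its median across all
samples; the per-gene log fold changes are then aggregated by chromosome.
A coherent positive (negative) median shift of one chromosome's genes in
one sample is the transcriptional signature of a chromosome gain (loss) —
full dosage for a trisomy is ``log2(3/2) ~ 0.585``.

Significance comes from a gene-membership permutation: the observed
chromosome median is compared with medians of size-matched random gene
sets from the same sample, which preserves the sample's gene-level logFC
distribution exactly.  Calls additionally require the median shift to
exceed a configurable dosage threshold, and permutation p-values are
Benjamini-Hochberg adjusted across chromosomes within each sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Expected log2 shift of a fully dosage-expressed trisomy (3 copies vs 2).
TRISOMY_LOG2_DOSAGE = float(np.log2(1.5))


def logfc_vs_median(expr: pd.DataFrame, center_samples: bool = False) -> pd.DataFrame:
    """Per-gene log fold change relative to the cross-sample median.

    ``expr`` is a genes x samples matrix on the log2 scale.
    ``logFC(g, s) = expr(g, s) - median_s' expr(g, s')`` (even sample counts
    use the mean of the two central values, the pandas default).  Genes with
    zero variance are retained with logFC 0 everywhere.  With
    ``center_samples=True`` each sample column is median-centered first, an
    optional normalization that removes global per-sample offsets.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if expr.isna().any().any():
        raise ValueError("expression matrix must not contain missing values")
    mat = expr
    if center_samples:
        mat = mat.sub(mat.median(axis=0), axis=1)
    return mat.sub(mat.median(axis=1), axis=0)


@dataclass
class ChromosomeShiftResult:
    """Per-(chromosome, sample) shift statistics with permutation p-values."""

    table: pd.DataFrame          # chromosome, sample, n_genes, median_logfc,
    #                              iqr, p_value, low_n
    n_perm: int
    min_genes: int
    seed: int
    n_unannotated: int


def _align_annotation(logfc: pd.DataFrame, annotation: pd.DataFrame,
                      ) -> tuple[pd.DataFrame, pd.Series, int]:
    ann = annotation.copy()
    if not {"gene", "chromosome"} <= set(ann.columns):
        raise ValueError("annotation needs columns 'gene' and 'chromosome'")
    ann = ann.drop_duplicates(subset="gene").set_index("gene")["chromosome"]
    keep = logfc.index.intersection(ann.index)
    n_dropped = len(logfc) - len(keep)
    if n_dropped:
        logger.warning("dropping %d gene(s) absent from the annotation",
                       n_dropped)
    return logfc.loc[keep], ann.loc[keep], n_dropped


def chromosome_shift(logfc: pd.DataFrame, annotation: pd.DataFrame,
                     n_perm: int = 1000, min_genes: int = 50, seed: int = 0,
                     groups: Mapping[str, str] | None = None,
                     ) -> ChromosomeShiftResult:
    """Chromosome-level median logFC with a gene-set permutation p-value.

    For each chromosome and sample (or group average when ``groups`` maps
    sample -> group) the statistic is the median logFC of the chromosome's
    genes; its two-sided p-value compares it with ``n_perm`` medians of
    random gene sets of the same size drawn from all annotated genes.
    Chromosomes with fewer than ``min_genes`` genes keep their statistics
    but are flagged so downstream calling forces them neutral.
    """
    logfc, chrom, n_unannotated = _align_annotation(logfc, annotation)
    if logfc.empty:
        raise ValueError("no annotated genes left")
    if groups is not None:
        cols = {}
        for sample, grp in groups.items():
            cols.setdefault(grp, []).append(sample)
        logfc = pd.DataFrame({g: logfc[s].mean(axis=1) for g, s in cols.items()})

    rng = np.random.default_rng(seed)
    values = logfc.to_numpy()
    n_genes_total = values.shape[0]
    chrom_arr = chrom.to_numpy()
    chromosomes = list(dict.fromkeys(chrom_arr))  # stable order

    # One gene permutation per replicate, shared across chromosomes: the
    # null set for a chromosome with m genes is the permutation's first m
    # entries, a uniform random gene set of matched size (sets for
    # different chromosomes within one replicate are nested, which leaves
    # each per-chromosome p-value marginally valid).
    idx_full = np.tile(np.arange(n_genes_total), (n_perm, 1))
    rng.permuted(idx_full, axis=1, out=idx_full)

    med_by_size: dict[int, np.ndarray] = {}
    rows = []
    for c in chromosomes:
        gmask = chrom_arr == c
        m = int(gmask.sum())
        if m not in med_by_size:                        # (n_perm, samples)
            med_by_size[m] = np.median(values[idx_full[:, :m], :], axis=1)
        perm_med = med_by_size[m]
        for j, sample in enumerate(logfc.columns):
            col = values[:, j]
            obs = float(np.median(col[gmask]))
            q75, q25 = np.percentile(col[gmask], [75, 25])
            perm = perm_med[:, j]
            p_lo = (1 + int((perm <= obs).sum())) / (n_perm + 1)
            p_hi = (1 + int((perm >= obs).sum())) / (n_perm + 1)
            rows.append({
                "chromosome": c, "sample": sample, "n_genes": m,
                "median_logfc": obs, "iqr": float(q75 - q25),
                "p_value": min(1.0, 2.0 * min(p_lo, p_hi)),
                "low_n": m < min_genes,
            })
    table = pd.DataFrame(rows)
    return ChromosomeShiftResult(table=table, n_perm=n_perm,
                                 min_genes=min_genes, seed=seed,
                                 n_unannotated=int(n_unannotated))


@dataclass
class AneuploidyCalls:
    """Gain/loss/neutral calls per (chromosome, sample) with the rule recorded."""

    table: pd.DataFrame
    call_threshold: float
    alpha: float
    adjust: str


def call_aneuploidy(result: ChromosomeShiftResult, call_threshold: float = 0.3,
                    alpha: float = 0.01, adjust: str = "fdr_bh",
                    ) -> AneuploidyCalls:
    """Turn shift statistics into gain/loss/neutral calls.

    A gain requires median logFC >= +``call_threshold`` and an adjusted
    p-value <= ``alpha``; a loss is symmetric; everything else — including
    chromosomes below the minimum gene count — is neutral.  P-values are
    adjusted across chromosomes within each sample (Benjamini-Hochberg by
    default; ``adjust="none"`` disables).
    """
    tab = result.table.copy()
    tab["q_value"] = np.nan
    for sample, sub in tab.groupby("sample", observed=True):
        usable = sub.index[~sub["low_n"]]
        if len(usable) == 0:
            continue
        if adjust == "none":
            tab.loc[usable, "q_value"] = tab.loc[usable, "p_value"]
        else:
            tab.loc[usable, "q_value"] = multipletests(
                tab.loc[usable, "p_value"].to_numpy(), method=adjust)[1]
    sig = (~tab["low_n"]) & (tab["q_value"] <= alpha)
    call = np.full(len(tab), "neutral", dtype=object)
    call[sig & (tab["median_logfc"] >= call_threshold)] = "gain"
    call[sig & (tab["median_logfc"] <= -call_threshold)] = "loss"
    tab["call"] = call
    return AneuploidyCalls(table=tab, call_threshold=call_threshold,
                           alpha=alpha, adjust=adjust)
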