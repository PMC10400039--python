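"""Genic methylation classification: gbM / teM / unM / unclassified / missing.

Per-gene cytosine calls within primary-transcript CDS are summarized per
context (CG, CHG, CHH and pooled non-CG), tested for enrichment against a
genome-wide background rate with a one-tailed binomial test, BH-corrected,
and pushed through the decision tree:

1. missing — no covered CDS cytosines in any context;
2. teM — enriched (q < alpha) for CHG, CHH or non-CG with >= 10 sites in
   that context;
3. gbM — enriched for CG with >= 10 CG sites and neither CHG nor CHH
   significant;
4. unM — at most 1 methylated site in total, or weighted methylation
   <= 2% in every individual context;
5. unclassified — anything else (intermediate methylation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc_stats import bh_adjust
from .core_io import GeneModel

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH", "nonCG")
LABELS = ("gbM", "teM", "unM", "unclassified", "missing")


@dataclass
class BackgroundRates:
    """Mean fraction of methylated sites per context over genes."""

    b_CG: float
    b_CHG: float
    b_CHH: float
    b_nonCG: float
    n_genes_used: int

    def rate(self, context: str) -> float:
        return getattr(self, f"b_{context}")


def weighted_methylation(sum_mc: float, sum_cov: float) -> float:
    """Weighted methylation level: methylated reads / total reads.

    Returns NaN (undefined) when there is no coverage.
    """
    if sum_cov < 0 or sum_mc < 0:
        raise ValueError("read sums must be nonnegative")
    if sum_mc > sum_cov:
        raise ValueError("methylated reads exceed total reads")
    if sum_cov == 0:
        return float("nan")
    return sum_mc / sum_cov


def _empty_summary(gene_id: str) -> dict:
    rec: dict = {"gene_id": gene_id}
    for ctx in CONTEXTS:
        rec[f"n_sites_{ctx}"] = 0
        rec[f"n_meth_{ctx}"] = 0
        rec[f"mc_{ctx}"] = 0
        rec[f"cov_{ctx}"] = 0
        rec[f"weighted_{ctx}"] = np.nan
    return rec


def summarize_genes(sites: pd.DataFrame, genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-gene per-context site counts and read sums within CDS intervals.

    Sites on both strands inside any CDS interval of the gene count toward
    it; uncovered sites (cov = 0) are excluded from site counts and sums.
    Pooled non-CG = CHG + CHH.
    """
    records = {g.gene_id: _empty_summary(g.gene_id) for g in genes}

    # flatten CDS intervals per chromosome for positional assignment
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        for s, e in g.cds_intervals:
            by_chrom.setdefault(g.chrom, []).append((s, e, g.gene_id))
    overlap_chroms = set()
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        if any(e1 > s2 for (_, e1, _), (s2, _, _) in zip(ivs, ivs[1:])):
            overlap_chroms.add(chrom)

    cov_sites = sites.loc[sites["cov"] > 0]
    for chrom, sub in cov_sites.groupby("chrom"):
        if chrom not in by_chrom:
            continue
        ivs = by_chrom[chrom]
        pos = sub["pos"].to_numpy()
        if chrom not in overlap_chroms:
            starts = np.array([iv[0] for iv in ivs])
            ends = np.array([iv[1] for iv in ivs])
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
            owners = [[ivs[i][2]] if k else [] for i, k in zip(idx, ok)]
        else:  # rare overlapping-CDS case: a site may belong to several genes
            owners = [
                [gid for s, e, gid in ivs if s <= p < e] for p in pos
            ]
        ctx = sub["context_class"].to_numpy()
        meth = sub["methylated"].to_numpy()
        mc = sub["mc"].to_numpy()
        cov = sub["cov"].to_numpy()
        for i in range(len(pos)):
            for gid in owners[i]:
                rec = records[gid]
                for c in (ctx[i], "nonCG") if ctx[i] != "CG" else (ctx[i],):
                    rec[f"n_sites_{c}"] += 1
                    rec[f"n_meth_{c}"] += int(meth[i])
                    rec[f"mc_{c}"] += int(mc[i])
                    rec[f"cov_{c}"] += int(cov[i])

    df = pd.DataFrame(list(records.values())).set_index("gene_id")
    for ctx in CONTEXTS:
        cov = df[f"cov_{ctx}"].to_numpy(float)
        mc = df[f"mc_{ctx}"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            df[f"weighted_{ctx}"] = np.where(cov > 0, mc / np.maximum(cov, 1), np.nan)
    return df


def summarize_gene(sites: pd.DataFrame, gene: GeneModel) -> pd.Series:
    """Counts-only summary for a single gene (see :func:`summarize_genes`)."""
    return summarize_genes(sites, [gene]).loc[gene.gene_id]


def compute_background(summaries: pd.DataFrame) -> BackgroundRates:
    """Background methylation rate per context.

    Unweighted mean over genes of (methylated sites / covered sites),
    excluding genes without covered sites in that context. By default this
    is run per species; a pooled multi-species run simply concatenates
    summaries first.
    """
    rates = {}
    used = 0
    for ctx in CONTEXTS:
        n = summaries[f"n_sites_{ctx}"].to_numpy(float)
        k = summaries[f"n_meth_{ctx}"].to_numpy(float)
        mask = n > 0
        if not mask.any():
            # context absent from the data: rate undefined, tests skip it
            rates[f"b_{ctx}"] = float("nan")
            continue
        rates[f"b_{ctx}"] = float(np.mean(k[mask] / n[mask]))
        used = max(used, int(mask.sum()))
    if all(np.isnan(v) for v in rates.values()):
        raise ValueError("no genes with covered sites in any context")
    return BackgroundRates(n_genes_used=used, **rates)


def test_enrichment(summaries: pd.DataFrame, background: BackgroundRates) -> pd.DataFrame:
    """One-tailed upper binomial enrichment p-value per gene and context.

    p = P(X >= n_methylated) with X ~ Binomial(n_sites, b_context);
    undefined (NaN) where a gene has no covered sites in the context.
    """
    out = summaries.copy()
    for ctx in CONTEXTS:
        n = summaries[f"n_sites_{ctx}"].to_numpy(np.int64)
        k = summaries[f"n_meth_{ctx}"].to_numpy(np.int64)
        b = background.rate(ctx)
        if np.isnan(b):
            out[f"p_{ctx}"] = np.nan
            continue
        p = stats.binom.sf(k - 1, np.maximum(n, 1), b)
        p = np.where(n > 0, p, np.nan)
        if b == 0 and (k > 0).any():
            logger.info("background rate 0 in %s with methylated sites: p = 0", ctx)
        out[f"p_{ctx}"] = p
    return out


def classify_genes(
    summaries: pd.DataFrame,
    background: BackgroundRates,
    alpha: float = 0.05,
    min_sites: int = 10,
    unm_weighted_max: float = 0.02,
    unm_max_methylated: int = 1,
    unm_rule: str = "total",
) -> pd.DataFrame:
    """Apply the enrichment tests, BH correction and the label decision tree.

    ``unm_rule`` controls the "<= 1 methylated site" criterion: ``total``
    (default) counts methylated sites across CG+CHG+CHH; ``per-context``
    requires <= 1 in each context separately.
    """
    df = test_enrichment(summaries, background)
    for ctx in CONTEXTS:
        df[f"q_{ctx}"] = bh_adjust(df[f"p_{ctx}"].to_numpy())

    def sig(ctx: str) -> np.ndarray:
        q = df[f"q_{ctx}"].to_numpy(float)
        return ~np.isnan(q) & (q < alpha)

    def enough(ctx: str) -> np.ndarray:
        return df[f"n_sites_{ctx}"].to_numpy() >= min_sites

    total_sites = sum(df[f"n_sites_{c}"].to_numpy() for c in ("CG", "CHG", "CHH"))
    missing = total_sites == 0

    tem = np.zeros(len(df), dtype=bool)
    for ctx in ("CHG", "CHH", "nonCG"):
        tem |= sig(ctx) & enough(ctx)

    gbm = sig("CG") & enough("CG") & ~sig("CHG") & ~sig("CHH")

    if unm_rule == "total":
        few_meth = (
            sum(df[f"n_meth_{c}"].to_numpy() for c in ("CG", "CHG", "CHH"))
            <= unm_max_methylated
        )
    elif unm_rule == "per-context":
        few_meth = np.all(
            [df[f"n_meth_{c}"].to_numpy() <= unm_max_methylated for c in ("CG", "CHG", "CHH")],
            axis=0,
        )
    else:
        raise ValueError(f"unknown unm_rule {unm_rule!r}")
    low_weight = np.ones(len(df), dtype=bool)
    for ctx in ("CG", "CHG", "CHH"):
        w = df[f"weighted_{ctx}"].to_numpy(float)
        # contexts without coverage carry no evidence against unM
        low_weight &= np.isnan(w) | (w <= unm_weighted_max)
    unm = few_meth | low_weight

    df["label"] = np.select(
        [missing, tem, gbm, unm],
        ["missing", "teM", "gbM", "unM"],
        default="unclassified",
    )
    return df


def recall_methylated(
    mc: np.ndarray, cov: np.ndarray, error_rate: float = 0.005, alpha: float = 0.01
) -> np.ndarray:
    """Per-site methylation re-caller for inputs lacking the call column.

    A site is called methylated when the one-tailed binomial p-value of its
    methylated read count against the sequencing/non-conversion error rate
    falls below ``alpha``.
    """
    mc = np.asarray(mc, dtype=np.int64)
    cov = np.asarray(cov, dtype=np.int64)
    p = stats.binom.sf(mc - 1, np.maximum(cov, 1), error_rate)
    return (cov > 0) & (mc > 0) & (p < alpha)
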