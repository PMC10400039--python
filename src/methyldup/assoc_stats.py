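"""Shared statistical layer.

Enrichment contingency tests (two-sided Fisher with BH FDR), two-proportion
Z contrasts, TE association within a 1-kb margin, 100-kb/50-kb sliding
window profiles with class-density correlations, PAV calling and
population epiallele frequency binning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import GeneModel, TEFeature

logger = logging.getLogger(__name__)

FREQUENCY_BINS = ["0%", "<25%", "25-50%", "50-75%", ">75%"]


@dataclass
class ContingencyResult:
    """A 2x2 test: a = in label & in category, b = label only, etc."""

    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    odds_ratio_haldane: float
    p: float
    direction: str
    q: float = float("nan")


def fisher_exact(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 table.

    Two-sided p sums hypergeometric probabilities of all tables with the
    same margins that are no more probable than the observed one (the
    minimum-likelihood convention). The odds ratio ad/bc is reported with
    +/-infinity sentinels for zero cells, plus a Haldane-Anscombe (+0.5)
    version for plotting.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("contingency cells must be nonnegative")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = math.inf
    else:
        odds = math.nan
    hald = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    if math.isnan(odds) or odds == 1.0:
        direction = "none"
    elif odds > 1:
        direction = "enriched"
    else:
        direction = "depleted"
    return ContingencyResult(a, b, c, d, odds, hald, float(p), direction)


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs excluded from the family."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    if mask.sum():
        _, qv, _, _ = multipletests(p[mask], method="fdr_bh")
        q[mask] = qv
    return q


def enrichment_scan(
    labels: Mapping[str, str] | pd.Series,
    categories: Mapping[str, str] | pd.Series,
    universe: Iterable[str] | None = None,
    exclude_labels: tuple[str, ...] = ("missing", "unclassified"),
) -> pd.DataFrame:
    """Fisher enrichment of every label within every category.

    Both partitions are taken over one gene universe; by default genes
    whose methylation label is missing/unclassified are dropped from the
    universe before testing. BH is applied across all tests in the scan.
    """
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    categories = (
        pd.Series(dict(categories)) if not isinstance(categories, pd.Series) else categories
    )
    genes = labels.index.intersection(categories.index)
    if universe is not None:
        genes = genes.intersection(pd.Index(universe))
    if exclude_labels:
        genes = genes[~labels.loc[genes].isin(exclude_labels)]
    lab = labels.loc[genes]
    cat = categories.loc[genes]
    n = len(genes)
    rows = []
    for L in sorted(lab.unique()):
        in_l = lab == L
        for C in sorted(cat.unique()):
            in_c = cat == C
            if not in_c.any():
                logger.warning("empty category %s skipped", C)
                continue
            a = int((in_l & in_c).sum())
            b = int(in_l.sum()) - a
            c = int(in_c.sum()) - a
            d = n - a - b - c
            res = fisher_exact(a, b, c, d)
            rows.append(
                {
                    "label": L,
                    "category": C,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": res.odds_ratio,
                    "odds_ratio_haldane": res.odds_ratio_haldane,
                    "p": res.p,
                    "direction": res.direction,
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-proportion Z-test with a pooled variance estimate.

    Degenerate pooled proportions (0 or 1) carry no information and
    return (0.0, 1.0).
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2) or n1 == 0 or n2 == 0:
        raise ValueError("need 0 <= x <= n with n > 0")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        logger.warning("degenerate pooled proportion; z set to 0")
        return 0.0, 1.0
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (x1 / n1 - x2 / n2) / se
    p = 2 * stats.norm.sf(abs(z))
    return z, float(p)


# ---------------------------------------------------------------------------
# TE association and genomic windows


def te_association(
    genes: Sequence[GeneModel],
    tes: Sequence[TEFeature],
    margin: int = 1000,
) -> pd.Series:
    """Flag each gene TE-associated if any TE overlaps the gene body
    extended by ``margin`` bp on both sides (default 1 kb)."""
    te_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for te in tes:
        te_by_chrom.setdefault(te.chrom, []).append((te.start, te.end))
    arrays = {
        chrom: (np.array([iv[0] for iv in ivs]), np.array([iv[1] for iv in ivs]))
        for chrom, ivs in te_by_chrom.items()
    }
    flags = {}
    for g in genes:
        if g.chrom not in arrays:
            flags[g.gene_id] = False
            continue
        starts, ends = arrays[g.chrom]
        lo, hi = g.start - margin, g.end + margin
        flags[g.gene_id] = bool(np.any((starts < hi) & (ends > lo)))
    return pd.Series(flags, name="te_associated")


def sliding_windows(
    genes: Sequence[GeneModel],
    labels: Mapping[str, str],
    tes: Sequence[TEFeature],
    chrom_lengths: Mapping[str, int],
    window: int = 100_000,
    step: int = 50_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowed gene/TE density profiles and class-density correlations.

    Windows tile each chromosome from 0 with the given step while the
    start is inside the chromosome (the last window is truncated). A gene
    is counted in every window containing its midpoint; te_bp is the total
    TE overlap with the window. Returns (profiles, correlations) where
    correlations holds Pearson r with t-based two-sided p and BH q between
    each methylation-class count and total genes, TE count and TE bp.
    """
    classes = sorted(set(labels.values()))
    rows = []
    for chrom, length in chrom_lengths.items():
        g_mid = np.array([g.midpoint for g in genes if g.chrom == chrom])
        g_lab = [labels.get(g.gene_id) for g in genes if g.chrom == chrom]
        t_start = np.array([t.start for t in tes if t.chrom == chrom])
        t_end = np.array([t.end for t in tes if t.chrom == chrom])
        start = 0
        while start < length or start == 0:
            end = min(start + window, length)
            in_win = (g_mid >= start) & (g_mid < end)
            row = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_genes": int(in_win.sum()),
            }
            for cls in classes:
                row[f"n_{cls}"] = int(
                    sum(1 for m, l in zip(g_mid, g_lab) if start <= m < end and l == cls)
                )
            if len(t_start):
                row["n_TEs"] = int(np.sum((t_start < end) & (t_end > start)))
                row["te_bp"] = int(
                    np.sum(np.clip(np.minimum(t_end, end) - np.maximum(t_start, start), 0, None))
                )
            else:
                row["n_TEs"] = 0
                row["te_bp"] = 0
            rows.append(row)
            start += step
            if start >= length:
                break
    prof = pd.DataFrame(rows)
    corr_rows = []
    for cls in classes:
        for other in ("n_genes", "n_TEs", "te_bp"):
            x = prof[f"n_{cls}"].to_numpy(float)
            y = prof[other].to_numpy(float)
            if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            corr_rows.append({"class": cls, "versus": other, "r": r, "p": p})
    corr = pd.DataFrame(corr_rows)
    if not corr.empty:
        corr["q"] = bh_adjust(corr["p"].to_numpy())
    return prof, corr


# ---------------------------------------------------------------------------
# PAV and population epiallele frequency


def call_pav(coverage: pd.DataFrame, threshold: float = 0.2) -> pd.Index:
    """Presence-absence variable genes: average read coverage < threshold
    in at least one accession (strict inequality)."""
    if (coverage.to_numpy() < 0).any():
        raise ValueError("coverage must be nonnegative")
    mask = (coverage < threshold).any(axis=1)
    return coverage.index[mask]


def bin_frequency(freq: float) -> str:
    """Bin a class frequency (0..1) per the population epiallele bins.

    Exactly 0 -> "0%"; (0, 0.25) -> "<25%"; [0.25, 0.5) -> "25-50%";
    [0.5, 0.75) -> "50-75%"; [0.75, 1] -> ">75%".
    """
    if not 0 <= freq <= 1:
        raise ValueError("frequency outside [0, 1]")
    if freq == 0:
        return "0%"
    if freq < 0.25:
        return "<25%"
    if freq < 0.50:
        return "25-50%"
    if freq < 0.75:
        return "50-75%"
    return ">75%"


def population_frequency(
    label_matrix: pd.DataFrame,
    classes: Sequence[str] = ("gbM", "teM", "unM", "unclassified"),
    missing_token: str = "missing",
) -> pd.DataFrame:
    """Per-gene epiallele class frequencies across a population panel.

    ``label_matrix`` is genes x accessions of class labels (``missing`` or
    NaN = no data for that accession). Frequencies are over accessions with
    data; genes with no informative accession are excluded (logged).
    """
    rows = []
    for gene, row in label_matrix.iterrows():
        vals = row.dropna()
        vals = vals[vals != missing_token]
        n = len(vals)
        if n == 0:
            logger.warning("gene %s has no informative accessions; excluded", gene)
            continue
        rec = {"gene_id": gene, "n_accessions_with_data": n}
        for cls in classes:
            f = float((vals == cls).sum()) / n
            rec[f"freq_{cls}"] = f
            rec[f"bin_{cls}"] = bin_frequency(f)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame()


def summarize_by_group(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Per-group n, median and quartiles, ranked by median.

    Undefined (NaN) values are excluded and counted per group.
    """
    df = pd.DataFrame({"value": values, "group": groups})
    out = []
    for name, sub in df.groupby("group", dropna=False):
        vals = sub["value"].dropna()
        out.append(
            {
                "group": name,
                "n": len(vals),
                "n_undefined": int(sub["value"].isna().sum()),
                "median": float(vals.median()) if len(vals) else np.nan,
                "q1": float(vals.quantile(0.25)) if len(vals) else np.nan,
                "q3": float(vals.quantile(0.75)) if len(vals) else np.nan,
            }
        )
    res = pd.DataFrame(out)
    return res.sort_values("median", na_position="last").reset_index(drop=True)
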