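"""Readers/writers for external formats and the shared coordinate model.

All coordinates are stored 0-based half-open internally. GFF3 (1-based
inclusive) and allc positions (1-based) are converted on read and
reconverted on write, so interval arithmetic inside the package is
unambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALLC_COLUMNS = ["chrom", "pos", "strand", "context", "mc", "cov", "methylated"]


@dataclass
class GeneModel:
    """A gene with the CDS intervals of its primary transcript.

    ``rank`` is the 0-based order index of the gene along its chromosome
    (sorted by start), used for tandem/proximal typing and collinearity.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS intervals")
        self.cds_intervals = ivs

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass
class TEFeature:
    chrom: str
    start: int
    end: int
    family: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("TE feature: start must be < end")


def context_class(context: str) -> str:
    """Classify a cytosine trinucleotide context as CG, CHG or CHH.

    The site is a cytosine at the first position: a following G makes it
    CG; otherwise a G in the third position makes it CHG; else CHH.
    """
    if len(context) < 3:
        raise ValueError(f"context string too short: {context!r}")
    if context[1] == "G":
        return "CG"
    if context[2] == "G":
        return "CHG"
    return "CHH"


# ---------------------------------------------------------------------------
# GFF3


def _assign_ranks(genes: list[GeneModel]) -> list[GeneModel]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for members in by_chrom.values():
        members.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(members):
            g.rank = i
    return genes


def read_gff(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into GeneModels (one per gene, primary transcript).

    The primary transcript is the one with the longest total CDS, ties
    broken by lexicographic transcript id. GFF3 1-based inclusive
    coordinates are converted to 0-based half-open. A gene without CDS is
    emitted with empty ``cds_intervals`` and a logged warning.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        return []
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        best: tuple[int, str] | None = None
        best_cds: list[tuple[int, int]] = []
        for tx in db.children(gene, level=1):
            if tx.featuretype not in ("mRNA", "transcript"):
                continue
            cds = [(c.start - 1, c.end) for c in db.children(tx, featuretype="CDS")]
            cds.sort()
            total = sum(e - s for s, e in cds)
            key = (-total, tx.id)
            if best is None or key < best:
                best, best_cds = key, cds
        if not best_cds:
            # genes annotated without mRNA children may carry CDS directly
            best_cds = sorted(
                (c.start - 1, c.end) for c in db.children(gene, featuretype="CDS")
            )
        if not best_cds:
            logger.warning("gene %s has no CDS; emitting empty intervals", gene.id)
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                start=gene.start - 1,
                end=gene.end,
                strand=gene.strand if gene.strand in "+-" else "+",
                cds_intervals=best_cds,
            )
        )
    return _assign_ranks(genes)


def write_gff(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write GeneModels as GFF3 (gene/mRNA/CDS), inverse of :func:`read_gff`."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tmethyldup\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tmethyldup\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.cds_intervals):
                fh.write(
                    f"{g.chrom}\tmethyldup\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tID={mrna}.cds{i};Parent={mrna}\n"
                )


# ---------------------------------------------------------------------------
# allc methylation calls


def read_allc(path: str | Path) -> pd.DataFrame:
    """Read a 7-column allc table of per-cytosine methylation calls.

    Columns: chrom, pos (1-based), strand, trinucleotide context, methylated
    reads, total reads, methylated call (0/1). Returns a DataFrame with
    ``pos`` converted to 0-based, a derived ``context_class`` column and a
    boolean ``covered`` flag (sites with zero coverage are retained).
    """
    df = pd.read_csv(
        str(path),
        sep="\t",
        names=ALLC_COLUMNS,
        dtype={"chrom": str, "strand": str, "context": str},
        comment="#",
    )
    for col in ("pos", "mc", "cov", "methylated"):
        try:
            df[col] = df[col].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"allc column {col!r} must be integer: {exc}") from exc
    bad = df.index[df["mc"] > df["cov"]]
    if len(bad):
        raise ValueError(f"allc row {bad[0] + 1}: mc exceeds cov")
    df["pos"] = df["pos"] - 1
    df["context_class"] = [context_class(c) for c in df["context"]]
    df["covered"] = df["cov"] > 0
    df["methylated"] = df["methylated"].astype(bool)
    return df


def write_allc(df: pd.DataFrame, path: str | Path) -> None:
    out = df[ALLC_COLUMNS].copy()
    out["pos"] = out["pos"] + 1
    out["methylated"] = out["methylated"].astype(int)
    out.to_csv(str(path), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# BLAST-like hits


def read_hits(
    path: str | Path,
    max_evalue: float = 1e-5,
    og_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read an outfmt-6-like hit table and apply the retention filters.

    Self-hits are removed; hits with evalue >= ``max_evalue`` are removed;
    if ``og_map`` is given, hits whose genes fall in different orthogroups
    are removed; reciprocal duplicates (A,B)/(B,A) are collapsed keeping
    the smaller evalue (exact ties broken by lexicographic pair order,
    which the canonical pair ordering makes automatic).
    """
    df = pd.read_csv(
        str(path), sep="\t", header=None, comment="#", float_precision="round_trip"
    )
    if df.shape[1] < 3:
        raise ValueError("hit table needs >= 3 columns (query, subject, evalue)")
    # outfmt 6 puts the e-value in column 11; accept the 3-column short form
    ecol = 10 if df.shape[1] >= 11 else 2
    hits = pd.DataFrame(
        {
            "query": df[0].astype(str),
            "subject": df[1].astype(str),
            "evalue": pd.to_numeric(df[ecol], errors="raise"),
        }
    )
    return filter_hits(hits, max_evalue=max_evalue, og_map=og_map)


def filter_hits(
    hits: pd.DataFrame,
    max_evalue: float = 1e-5,
    og_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Apply the hit retention filters to an in-memory (query, subject, evalue) table."""
    hits = hits.loc[hits["query"] != hits["subject"]]
    hits = hits.loc[hits["evalue"] < max_evalue]
    if og_map is not None:
        same_og = [
            og_map.get(q) is not None and og_map.get(q) == og_map.get(s)
            for q, s in zip(hits["query"], hits["subject"])
        ]
        hits = hits.loc[same_og]
    if hits.empty:
        return hits.reset_index(drop=True)
    a = np.minimum(hits["query"], hits["subject"])
    b = np.maximum(hits["query"], hits["subject"])
    canon = hits.assign(query=a.values, subject=b.values)
    canon = canon.sort_values(["query", "subject", "evalue"], kind="stable")
    canon = canon.drop_duplicates(["query", "subject"], keep="first")
    return canon.reset_index(drop=True)


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits[["query", "subject", "evalue"]].to_csv(
        str(path), sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# TEs (BED), orthogroups, expression, species map


def read_bed(path: str | Path) -> list[TEFeature]:
    """Read TE features from a BED file (0-based half-open, as BED is)."""
    tes: list[TEFeature] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED line {ln}: fewer than 3 columns")
            tes.append(
                TEFeature(
                    chrom=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    family=parts[3] if len(parts) > 3 else None,
                )
            )
    return tes


def write_bed(tes: Iterable[TEFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for te in tes:
            fam = te.family if te.family is not None else "."
            fh.write(f"{te.chrom}\t{te.start}\t{te.end}\t{fam}\n")


def read_orthogroups(path: str | Path) -> dict[str, dict[str, list[str]]]:
    """Read an Orthofinder-style Orthogroups.tsv.

    First column is the orthogroup id; one column per species with
    comma-separated gene ids. Returns og_id -> {species: [gene ids]}.
    """
    df = pd.read_csv(str(path), sep="\t", dtype=str).fillna("")
    species = list(df.columns[1:])
    table: dict[str, dict[str, list[str]]] = {}
    for _, row in df.iterrows():
        members = {}
        for sp in species:
            genes = [g.strip() for g in str(row[sp]).split(",") if g.strip()]
            if genes:
                members[sp] = genes
        table[str(row.iloc[0])] = members
    return table


def write_orthogroups(
    table: Mapping[str, Mapping[str, Sequence[str]]],
    species: Sequence[str],
    path: str | Path,
) -> None:
    rows = []
    for og_id, members in table.items():
        row = {"Orthogroup": og_id}
        for sp in species:
            row[sp] = ", ".join(members.get(sp, []))
        rows.append(row)
    pd.DataFrame(rows, columns=["Orthogroup", *species]).to_csv(
        str(path), sep="\t", index=False
    )


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a normalized expression matrix (rows genes, columns conditions)."""
    df = pd.read_csv(str(path), sep="\t", index_col=0)
    return df.astype(float)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(str(path), sep="\t")


def read_species_map(path: str | Path) -> dict[str, str]:
    """Read a two-column species -> family TSV."""
    df = pd.read_csv(str(path), sep="\t", header=None, dtype=str)
    return dict(zip(df[0], df[1]))
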