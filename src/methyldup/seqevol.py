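"""Ka/Ks estimation for codon-aligned duplicate pairs (Nei-Gojobori 1986).

Synonymous/nonsynonymous site counts come from per-codon mutational
opportunity under the standard genetic code (changes to stop codons count
as nonsynonymous); observed differences are averaged over all minimal
mutational pathways between the two codons, excluding pathways that pass
through a stop codon. Proportions are Jukes-Cantor corrected,
d = -(3/4) ln(1 - 4p/3), and omega = Ka/Ks.
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
CODON_TO_AA = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
SENSE_CODONS = sorted(CODON_TO_AA)


def _syn_fraction(codon: str) -> float:
    """Number of synonymous sites in a codon (0..3).

    Each position contributes the fraction of its three possible changes
    that preserve the amino acid; changes to stops are nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt not in STOP_CODONS and CODON_TO_AA[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s


SYN_SITES = {codon: _syn_fraction(codon) for codon in SENSE_CODONS}


@functools.lru_cache(maxsize=None)
def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons.

    All orderings of the differing positions are enumerated; pathways
    through stop codons are excluded (all pathways are used if every one
    is blocked).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else valid).append((sd, nd))
    paths = valid if valid else [
        p for p in _all_paths_counting_stops(c1, c2)
    ]
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _all_paths_counting_stops(c1: str, c2: str) -> list[tuple[int, int]]:
    """Fallback when every pathway passes a stop: count steps through
    stops as nonsynonymous so the difference mass is not lost."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    out = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if (
                nxt not in STOP_CODONS
                and cur not in STOP_CODONS
                and CODON_TO_AA[nxt] == CODON_TO_AA[cur]
            ):
                sd += 1
            else:
                nd += 1
            cur = nxt
        out.append((sd, nd))
    return out


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction; NaN at saturation (p >= 3/4)."""
    if p < 0:
        raise ValueError("proportion must be nonnegative")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KaKsResult:
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    omega: float
    saturated: bool = False


def compute_kaks(seq1: str, seq2: str) -> KaKsResult:
    """NG86 Ka, Ks and omega for one aligned sequence pair.

    Sequences must be equal-length codon alignments over {A,C,G,T,-};
    codons containing gaps/ambiguity or observed stop codons are dropped
    pairwise. omega is undefined (NaN) when Ks = 0 or saturated.
    """
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError("aligned sequences differ in length")
    if len(seq1) % 3:
        raise ValueError("alignment length not divisible by 3")
    s1 = s2 = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if c1 not in SYN_SITES or c2 not in SYN_SITES:
            continue  # gap, ambiguity or stop codon: dropped pairwise
        n_codons += 1
        s1 += SYN_SITES[c1]
        s2 += SYN_SITES[c2]
        d_s, d_n = _path_counts(c1, c2)
        sd += d_s
        nd += d_n
    if n_codons == 0:
        raise ValueError("no comparable codons in alignment")
    S = (s1 + s2) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else float("nan")
    pN = nd / N if N > 0 else float("nan")
    Ks = jukes_cantor(pS) if not math.isnan(pS) else float("nan")
    Ka = jukes_cantor(pN) if not math.isnan(pN) else float("nan")
    saturated = (not math.isnan(pS) and pS >= 0.75) or (
        not math.isnan(pN) and pN >= 0.75
    )
    omega = Ka / Ks if Ks and Ks > 0 and not math.isnan(Ka) else float("nan")
    return KaKsResult(
        n_codons=n_codons,
        S=S,
        N=N,
        Sd=sd,
        Nd=nd,
        pS=pS,
        pN=pN,
        Ks=Ks,
        Ka=Ka,
        omega=omega,
        saturated=saturated,
    )


def selection_regime(omega: float, tol: float = 1e-9) -> str:
    """Interpret omega: < 1 purifying, > 1 diversifying, ~1 neutral."""
    if omega is None or math.isnan(omega):
        return "undefined"
    if abs(omega - 1.0) <= tol:
        return "neutral"
    return "purifying" if omega < 1.0 else "diversifying"


def kaks_table(
    alignments: Iterable[tuple[str, str, str, str]], max_ks: float | None = None
) -> pd.DataFrame:
    """Ka/Ks for (gene1, gene2, seq1, seq2) records; optional Ks cap filter."""
    rows = []
    for g1, g2, s1, s2 in alignments:
        r = compute_kaks(s1, s2)
        rows.append(
            {
                "gene1": g1,
                "gene2": g2,
                "S": r.S,
                "N": r.N,
                "Sd": r.Sd,
                "Nd": r.Nd,
                "Ks": r.Ks,
                "Ka": r.Ka,
                "omega": r.omega,
                "regime": selection_regime(r.omega),
                "saturated": r.saturated,
            }
        )
    df = pd.DataFrame(rows)
    if max_ks is not None and not df.empty:
        df = df.loc[~(df["Ks"] > max_ks)]
    return df.reset_index(drop=True)


def read_alignments(
    fasta_path: str | Path, pairs_path: str | Path
) -> list[tuple[str, str, str, str]]:
    """Load codon alignments from a FASTA plus a two-column pair manifest."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    pairs = pd.read_csv(str(pairs_path), sep="\t", header=None, names=["gene1", "gene2"])
    out = []
    for g1, g2 in zip(pairs["gene1"], pairs["gene2"]):
        if g1 not in seqs or g2 not in seqs:
            raise KeyError(f"pair ({g1}, {g2}) missing from alignment FASTA")
        out.append((g1, g2, seqs[g1], seqs[g2]))
    return out


def read_kaks_import(path: str | Path) -> pd.DataFrame:
    """Import externally computed Ka/Ks (gene1, gene2, Ka, Ks, omega TSV)."""
    df = pd.read_csv(
        str(path), sep="\t", header=None, names=["gene1", "gene2", "Ka", "Ks", "omega"]
    )
    return df
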