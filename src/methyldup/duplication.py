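"""Duplicate gene typing: WGD, tandem, proximal, translocated, dispersed.

Collinear blocks (chains of >= 5 anchor gene pairs with bounded rank gaps)
are detected by dynamic programming over filtered protein hits. Pairs are
then typed with the priority WGD > tandem > proximal > translocated >
dispersed: WGD pairs are anchors of an intra-genome block; tandem pairs
are rank-adjacent on one chromosome; proximal pairs have <= 10 intervening
genes; translocated pairs have exactly one syntenic gene (the parent);
everything else is dispersed. Translocated duplicates are aged into epochs
by a ladder of outgroups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

DUP_TYPES = ("WGD", "tandem", "proximal", "translocated", "dispersed")
PAIR_CLASS_ORDER = {"gbM": 0, "unM": 1, "teM": 2}


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[tuple[str, str]] = field(default_factory=list)

    @property
    def score(self) -> int:
        return len(self.anchors)


GeneIndex = Mapping[str, tuple[str, int]]  # gene id -> (chrom, rank)


def _best_chain(
    matches: list[tuple[int, int, str, str]], orientation: str, max_gap: int
) -> list[int]:
    """Longest chain (indices into ``matches``) for one orientation.

    A match j extends i when both rank gaps are in [1, max_gap]; for
    inverted chains the b-axis decreases. Ties prefer the earliest indices
    (deterministic).
    """
    n = len(matches)
    dp = [1] * n
    prev = [-1] * n
    for j in range(n):
        ra_j, rb_j = matches[j][0], matches[j][1]
        for i in range(j):
            ra_i, rb_i = matches[i][0], matches[i][1]
            da = ra_j - ra_i
            db = rb_j - rb_i if orientation == "same" else rb_i - rb_j
            if 1 <= da <= max_gap and 1 <= db <= max_gap and dp[i] + 1 > dp[j]:
                dp[j] = dp[i] + 1
                prev[j] = i
    if not n:
        return []
    end = max(range(n), key=lambda j: (dp[j], -j))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    return chain[::-1]


def detect_collinear_blocks(
    hits: pd.DataFrame,
    ranks_a: GeneIndex,
    ranks_b: GeneIndex | None = None,
    max_gap: int = 25,
    min_anchors: int = 5,
    self_offset_min: int | None = None,
) -> list[CollinearBlock]:
    """Find collinear blocks among hits by DP chaining with greedy extraction.

    ``ranks_a``/``ranks_b`` map gene ids to (chromosome, rank); when
    ``ranks_b`` is omitted the comparison is intra-genome (query and
    subject ranks from the same map, self chromosome pairs deduplicated by
    keeping rank_a < rank_b). Chains are extracted best-first; overlapping
    lower-scoring chains lose their shared matches. Chains shorter than
    ``min_anchors`` are dropped.

    In a self comparison, independent local duplicates (tandem/proximal
    pairs) line up along the plot diagonal and would chain into spurious
    "blocks" whose two segments overlap; matches on the same chromosome
    closer than ``self_offset_min`` ranks to the diagonal (default
    ``max_gap``) are therefore excluded from chaining, as self-synteny
    tools conventionally do.
    """
    intra = ranks_b is None
    if intra:
        ranks_b = ranks_a
    if self_offset_min is None:
        self_offset_min = max_gap
    groups: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for q, s in zip(hits["query"], hits["subject"]):
        if q not in ranks_a or s not in ranks_b:
            continue
        ca, ra = ranks_a[q]
        cb, rb = ranks_b[s]
        if intra:
            # orient the match canonically so mirrored matches coincide
            if (ca, ra) > (cb, rb):
                (ca, ra, q), (cb, rb, s) = (cb, rb, s), (ca, ra, q)
            if ca == cb and rb - ra <= self_offset_min:
                continue
        groups.setdefault((ca, cb), []).append((ra, rb, q, s))

    blocks: list[CollinearBlock] = []
    for (ca, cb), matches in sorted(groups.items()):
        pool = sorted(set(matches))
        while pool:
            candidates = []
            for orientation in ("same", "inverted"):
                idx = _best_chain(pool, orientation, max_gap)
                candidates.append((len(idx), orientation == "same", orientation, idx))
            score, _, orientation, idx = max(candidates)
            if score < min_anchors:
                break
            chosen = [pool[i] for i in idx]
            blocks.append(
                CollinearBlock(
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orientation,
                    anchors=[(m[2], m[3]) for m in chosen],
                )
            )
            used = set(chosen)
            pool = [m for m in pool if m not in used]
    return blocks


def anchor_pairs(blocks: Sequence[CollinearBlock]) -> set[frozenset]:
    return {frozenset((a, b)) for blk in blocks for a, b in blk.anchors}


def anchor_genes(blocks: Sequence[CollinearBlock], side: str = "both") -> set[str]:
    out: set[str] = set()
    for blk in blocks:
        for a, b in blk.anchors:
            if side in ("a", "both"):
                out.add(a)
            if side in ("b", "both"):
                out.add(b)
    return out


def select_unique_pairs(hits: pd.DataFrame) -> pd.DataFrame:
    """Retain, for each gene, only its lowest-e-value pair; deduplicate.

    Exact e-value ties are broken toward the lexicographically smaller
    partner id (logged).
    """
    best: dict[str, tuple[float, str]] = {}
    for q, s, e in zip(hits["query"], hits["subject"], hits["evalue"]):
        for g, partner in ((q, s), (s, q)):
            cur = best.get(g)
            if cur is None or (e, partner) < cur:
                if cur is not None and cur[0] == e:
                    logger.info("e-value tie for %s resolved lexicographically", g)
                best[g] = (e, partner)
    pairs = {}
    for g, (e, partner) in best.items():
        key = (min(g, partner), max(g, partner))
        pairs.setdefault(key, e)
    out = pd.DataFrame(
        [(g1, g2, e) for (g1, g2), e in sorted(pairs.items())],
        columns=["gene1", "gene2", "evalue"],
    )
    return out


def classify_pairs(
    pairs: pd.DataFrame,
    gene_index: GeneIndex,
    wgd_anchor_pairs: set[frozenset],
    syntenic_genes: set[str],
    max_intervening: int = 10,
) -> pd.DataFrame:
    """Assign each pair one duplication type (priority order as module doc).

    Returns the input with ``dup_type`` and, for translocated pairs,
    ``parent``/``daughter`` columns (parent = the syntenic gene).
    """
    dup_types, parents, daughters = [], [], []
    for g1, g2 in zip(pairs["gene1"], pairs["gene2"]):
        for g in (g1, g2):
            if g not in gene_index:
                raise KeyError(f"gene {g} absent from gene index")
        (c1, r1), (c2, r2) = gene_index[g1], gene_index[g2]
        parent = daughter = None
        if frozenset((g1, g2)) in wgd_anchor_pairs:
            dt = "WGD"
        elif c1 == c2 and abs(r1 - r2) == 1:
            dt = "tandem"
        elif c1 == c2 and 2 <= abs(r1 - r2) <= max_intervening + 1:
            dt = "proximal"
        elif (g1 in syntenic_genes) != (g2 in syntenic_genes):
            dt = "translocated"
            parent, daughter = (g1, g2) if g1 in syntenic_genes else (g2, g1)
        else:
            dt = "dispersed"
        dup_types.append(dt)
        parents.append(parent)
        daughters.append(daughter)
    out = pairs.copy()
    out["dup_type"] = dup_types
    out["parent"] = parents
    out["daughter"] = daughters
    return out


def assign_epoch(outgroup_synteny: Sequence[bool]) -> int | None:
    """Epoch of a translocated duplicate from a ladder of outgroups.

    ``outgroup_synteny`` lists, closest outgroup first, whether the
    daughter locus is syntenic against each outgroup. The epoch is the
    1-based index of the first syntenic outgroup (the duplication predates
    that divergence node), or 0 if syntenic against none (youngest,
    lineage-specific). Empty ladder -> undefined (None).
    """
    if len(outgroup_synteny) == 0:
        return None
    for j, flag in enumerate(outgroup_synteny, start=1):
        if flag:
            return j
    return 0


def pair_meth_class(label1: str, label2: str) -> tuple[str | None, str | None]:
    """Unordered pair methylation class, e.g. ("gbM-teM", "different").

    Pairs where either gene is missing or unclassified are excluded
    (returns (None, None)).
    """
    if label1 not in PAIR_CLASS_ORDER or label2 not in PAIR_CLASS_ORDER:
        return None, None
    a, b = sorted((label1, label2), key=PAIR_CLASS_ORDER.get)
    return f"{a}-{b}", ("same" if label1 == label2 else "different")


def switch_direction(parent_label: str, daughter_label: str) -> str:
    """Methylation switch of a translocated daughter relative to its parent.

    The parental (syntenic) locus is taken as the ancestral state; a
    differing daughter reports "to-<daughter label>".
    """
    for lab in (parent_label, daughter_label):
        if lab not in PAIR_CLASS_ORDER:
            raise ValueError(f"label {lab!r} not in gbM/unM/teM")
    if parent_label == daughter_label:
        return "same"
    return f"to-{daughter_label}"
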