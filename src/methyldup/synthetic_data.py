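"""Synthetic datasets with ground truth for every pipeline stage.

Generates toy genomes with planted duplication events (WGD collinear
blocks, tandem, proximal, translocated, dispersed), per-cytosine
methylomes with class-dependent emission rates, codon alignments with
target Ks/omega, condition expression profiles with target tau,
orthogroup tables with planted categories, TE annotations biased toward
teM genes, accession panels with configurable epiallele switch rates, and
PAV coverage matrices. Every stochastic draw flows from a single integer
seed through named substreams, so identical seed + config reproduce
byte-identical outputs and adding one output never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import core_io
from .core_io import GeneModel, TEFeature
from .methylome import recall_methylated
from .seqevol import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, SYN_SITES

_STREAMS = {
    "genome": 1,
    "methylome": 2,
    "sequences": 3,
    "expression": 4,
    "orthogroups": 5,
    "tes": 6,
    "population": 7,
    "coverage": 8,
    "classes": 9,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), _STREAMS[stream]])


@dataclass
class SimulationConfig:
    """Study conditions for the simulator (defaults are the test conditions)."""

    # genome layout
    n_chromosomes: int = 3
    genes_per_chromosome: int = 300
    gene_spacing: int = 5000
    gene_length: int = 1500
    cds_offset: int = 100
    cds_length: int = 1200
    # planted duplication events
    n_wgd_blocks: int = 1
    wgd_block_size: int = 10
    n_tandem: int = 20
    n_proximal: int = 20
    n_translocated: int = 20
    n_dispersed: int = 20
    spurious_hit_rate: float = 0.0
    n_epochs: int = 3
    # methylome emission
    class_probs: dict = field(
        default_factory=lambda: {"gbM": 0.30, "teM": 0.25, "unM": 0.45}
    )
    site_means: dict = field(default_factory=lambda: {"CG": 30, "CHG": 25, "CHH": 60})
    class_rates: dict = field(
        default_factory=lambda: {
            "gbM": {"CG": 0.85, "CHG": 0.01, "CHH": 0.01},
            "teM": {"CG": 0.90, "CHG": 0.65, "CHH": 0.10},
            "unM": {"CG": 0.005, "CHG": 0.005, "CHH": 0.005},
        }
    )
    mean_coverage: float = 20.0
    error_rate: float = 0.005
    call_alpha: float = 0.01
    # sequences
    n_codons: int = 300
    target_ks: float = 0.3
    target_omega: float = 0.2
    # expression
    n_conditions: int = 10
    class_tau: dict = field(
        default_factory=lambda: {"gbM": 0.2, "unM": 0.5, "teM": 0.8}
    )
    dirichlet_concentration: float = 30000.0
    # orthogroups
    n_species: int = 58
    n_families: int = 8
    og_counts: dict = field(
        default_factory=lambda: {
            "core:single-copy": 40,
            "core:multicopy": 30,
            "cross-family": 30,
            "family-specific": 20,
            "species-specific": 20,
        }
    )
    core_fraction: float = 0.879
    sc_fraction: float = 0.70
    # TEs
    te_prob_teM: float = 0.8
    te_prob_other: float = 0.1
    te_length: int = 500
    # population panel
    n_accessions: int = 928
    switch_rates: dict = field(
        default_factory=lambda: {
            "gbM": {"unM": 0.05, "teM": 0.02},
            "teM": {"unM": 0.10, "gbM": 0.02},
            "unM": {"gbM": 0.03, "teM": 0.02},
        }
    )
    missing_rate: float = 0.02
    # PAV coverage
    pav_fraction: float = 0.05

    def validate(self) -> None:
        for cls, rates in self.switch_rates.items():
            if sum(rates.values()) > 1:
                raise ValueError(f"switch rates for {cls} sum to > 1")
        for p in (self.spurious_hit_rate, self.missing_rate, self.pav_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimulatedGenome:
    genes: list[GeneModel]
    gene_index: dict[str, tuple[str, int]]
    chrom_lengths: dict[str, int]
    hits: pd.DataFrame
    outgroup_hits: pd.DataFrame
    outgroup_index: dict[str, tuple[str, int]]
    truth_pairs: pd.DataFrame
    epoch_flags: pd.DataFrame


class _Reserver:
    """Collision-free allocation of base-gene index ranges per chromosome."""

    def __init__(self, rng: np.random.Generator, n_genes: int):
        self.rng = rng
        self.n = n_genes
        self.taken: list[tuple[int, int]] = []

    def reserve(self, width: int, tries: int = 500) -> int:
        for _ in range(tries):
            p = int(self.rng.integers(1, self.n - width - 1))
            lo, hi = p - 1, p + width + 1
            if all(hi <= s or lo >= e for s, e in self.taken):
                self.taken.append((lo, hi))
                return p
        raise ValueError("planted events exceed genome capacity")


def simulate_genome(config: SimulationConfig, seed: int) -> SimulatedGenome:
    """Lay out genes, plant duplication events and emit hit tables.

    Base genes mirror an outgroup genome gene-for-gene (so every base gene
    is syntenic against the outgroup); inserted duplicate copies are not.
    Planted hit e-values are far below the 1e-5 cutoff; optional spurious
    hits are drawn between random genes at a configured rate.
    """
    config.validate()
    rng = _rng(seed, "genome")
    nch, npc = config.n_chromosomes, config.genes_per_chromosome
    chroms = [f"chr{c + 1}" for c in range(nch)]
    base: dict[str, list[str]] = {
        ch: [f"{ch}g{i:04d}" for i in range(npc)] for ch in chroms
    }
    reservers = {ch: _Reserver(rng, npc) for ch in chroms}
    insertions: dict[str, dict[int, list[str]]] = {ch: {} for ch in chroms}
    pair_rows: list[dict] = []
    epoch_rows: list[dict] = []

    def _evalue() -> float:
        return float(10.0 ** -rng.uniform(50, 180))

    def _other_chrom(ch: str) -> str:
        choices = [c for c in chroms if c != ch]
        return choices[int(rng.integers(len(choices)))]

    if nch < 2 and (config.n_wgd_blocks or config.n_translocated or config.n_dispersed):
        raise ValueError("need >= 2 chromosomes for inter-chromosomal events")

    for b in range(config.n_wgd_blocks):
        k = config.wgd_block_size
        ca = chroms[int(rng.integers(nch))]
        p = reservers[ca].reserve(k)
        cb = _other_chrom(ca)
        q = reservers[cb].reserve(1)
        copies = [f"{g}_wgd{b}" for g in base[ca][p : p + k]]
        insertions[cb].setdefault(q, []).extend(copies)
        for src, cp in zip(base[ca][p : p + k], copies):
            pair_rows.append(
                {"gene1": src, "gene2": cp, "dup_type": "WGD", "evalue": _evalue()}
            )

    for t in range(config.n_tandem):
        ch = chroms[int(rng.integers(nch))]
        p = reservers[ch].reserve(2)
        src = base[ch][p]
        cp = f"{src}_tan"
        insertions[ch].setdefault(p, []).append(cp)
        pair_rows.append(
            {"gene1": src, "gene2": cp, "dup_type": "tandem", "evalue": _evalue()}
        )

    for t in range(config.n_proximal):
        ch = chroms[int(rng.integers(nch))]
        gap = int(rng.integers(2, 11))
        p = reservers[ch].reserve(gap + 2)
        src = base[ch][p]
        cp = f"{src}_prox"
        insertions[ch].setdefault(p + gap, []).append(cp)
        pair_rows.append(
            {"gene1": src, "gene2": cp, "dup_type": "proximal", "evalue": _evalue()}
        )

    for t in range(config.n_translocated):
        ca = chroms[int(rng.integers(nch))]
        p = reservers[ca].reserve(1)
        src = base[ca][p]
        cb = _other_chrom(ca)
        q = reservers[cb].reserve(1)
        cp = f"{src}_tra"
        insertions[cb].setdefault(q, []).append(cp)
        pair_rows.append(
            {
                "gene1": src,
                "gene2": cp,
                "dup_type": "translocated",
                "parent": src,
                "daughter": cp,
                "evalue": _evalue(),
            }
        )
        epoch = int(rng.integers(0, config.n_epochs + 1))
        flags = [j >= epoch and epoch > 0 for j in range(1, config.n_epochs + 1)]
        epoch_rows.append(
            {
                "daughter": cp,
                "epoch": epoch,
                **{f"outgroup{j + 1}_syntenic": f for j, f in enumerate(flags)},
            }
        )

    for t in range(config.n_dispersed):
        ca = chroms[int(rng.integers(nch))]
        cb = _other_chrom(ca)
        p = reservers[ca].reserve(1)
        q = reservers[cb].reserve(1)
        pair_rows.append(
            {
                "gene1": base[ca][p],
                "gene2": base[cb][q],
                "dup_type": "dispersed",
                "evalue": _evalue(),
            }
        )

    # final gene order per chromosome
    genes: list[GeneModel] = []
    gene_index: dict[str, tuple[str, int]] = {}
    chrom_lengths: dict[str, int] = {}
    for ch in chroms:
        order: list[str] = []
        for i, g in enumerate(base[ch]):
            order.append(g)
            order.extend(insertions[ch].get(i, []))
        for rank, gid in enumerate(order):
            start = rank * config.gene_spacing
            genes.append(
                GeneModel(
                    gene_id=gid,
                    chrom=ch,
                    start=start,
                    end=start + config.gene_length,
                    strand="+",
                    cds_intervals=[
                        (
                            start + config.cds_offset,
                            start + config.cds_offset + config.cds_length,
                        )
                    ],
                    rank=rank,
                )
            )
            gene_index[gid] = (ch, rank)
        chrom_lengths[ch] = len(order) * config.gene_spacing

    truth_pairs = pd.DataFrame(
        pair_rows, columns=["gene1", "gene2", "dup_type", "parent", "daughter", "evalue"]
    )
    hits = truth_pairs[["gene1", "gene2", "evalue"]].rename(
        columns={"gene1": "query", "gene2": "subject"}
    )
    n_spurious = int(round(config.spurious_hit_rate * len(hits)))
    if n_spurious:
        all_ids = list(gene_index)
        rows = []
        while len(rows) < n_spurious:
            g1, g2 = rng.choice(all_ids, size=2, replace=False)
            rows.append(
                {"query": g1, "subject": g2, "evalue": float(10.0 ** -rng.uniform(6, 30))}
            )
        hits = pd.concat([hits, pd.DataFrame(rows)], ignore_index=True)

    # outgroup mirrors the ancestral (base) gene order
    outgroup_index: dict[str, tuple[str, int]] = {}
    og_rows = []
    for ch in chroms:
        for i, g in enumerate(base[ch]):
            og = f"out_{g}"
            outgroup_index[og] = (f"out_{ch}", i)
            og_rows.append({"query": g, "subject": og, "evalue": 1e-100})
    outgroup_hits = pd.DataFrame(og_rows)

    return SimulatedGenome(
        genes=genes,
        gene_index=gene_index,
        chrom_lengths=chrom_lengths,
        hits=hits,
        outgroup_hits=outgroup_hits,
        outgroup_index=outgroup_index,
        truth_pairs=truth_pairs,
        epoch_flags=pd.DataFrame(epoch_rows),
    )


def assign_classes(
    gene_ids: Sequence[str], config: SimulationConfig, seed: int
) -> pd.Series:
    """Draw a true methylation class per gene from the class mix."""
    rng = _rng(seed, "classes")
    classes = list(config.class_probs)
    probs = np.array([config.class_probs[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    return pd.Series(rng.choice(classes, size=len(gene_ids), p=probs), index=gene_ids)


_H = np.array(list("ACT"))


def simulate_methylome(
    genes: Sequence[GeneModel],
    classes: Mapping[str, str],
    config: SimulationConfig,
    seed: int,
) -> pd.DataFrame:
    """Per-cytosine allc-style calls emitted from class-specific rates.

    Site counts per context are Poisson around the configured means,
    coverage is Poisson(mean_coverage), methylated reads are binomial with
    the class rate, and the methylated call applies the binomial re-caller
    against the error rate (so unM genes still show sporadic calls).
    """
    rng = _rng(seed, "methylome")
    cols: dict[str, list] = {
        k: [] for k in ("chrom", "pos", "strand", "context", "mc", "cov", "methylated")
    }
    for g in genes:
        cls = classes[g.gene_id]
        rates = config.class_rates[cls]
        cds_s, cds_e = g.cds_intervals[0] if g.cds_intervals else (g.start, g.end)
        span = cds_e - cds_s
        for ctx in ("CG", "CHG", "CHH"):
            n = int(rng.poisson(config.site_means[ctx]))
            if n == 0 or n > span:
                continue
            pos = cds_s + rng.choice(span, size=n, replace=False)
            cov = rng.poisson(config.mean_coverage, size=n)
            mc = rng.binomial(cov, rates[ctx])
            meth = recall_methylated(
                mc, cov, error_rate=config.error_rate, alpha=config.call_alpha
            )
            if ctx == "CG":
                ctxs = np.char.add("CG", rng.choice(list("ACGT"), size=n))
            elif ctx == "CHG":
                ctxs = np.char.add(np.char.add("C", rng.choice(_H, size=n)), "G")
            else:
                ctxs = np.char.add(
                    np.char.add("C", rng.choice(_H, size=n)), rng.choice(_H, size=n)
                )
            cols["chrom"].append(np.full(n, g.chrom, dtype=object))
            cols["pos"].append(np.sort(pos))
            cols["strand"].append(rng.choice(["+", "-"], size=n))
            cols["context"].append(ctxs)
            cols["mc"].append(mc)
            cols["cov"].append(cov)
            cols["methylated"].append(meth)
    allc = pd.DataFrame({k: np.concatenate(v) for k, v in cols.items()})
    allc["pos"] = allc["pos"].astype(np.int64)
    allc["mc"] = allc["mc"].astype(np.int64)
    allc["cov"] = allc["cov"].astype(np.int64)
    allc["methylated"] = allc["methylated"].astype(bool)
    allc["context_class"] = [core_io.context_class(c) for c in allc["context"]]
    allc["covered"] = allc["cov"] > 0
    return allc.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_sequences(
    pairs: pd.DataFrame, config: SimulationConfig, seed: int
) -> list[tuple[str, str, str, str]]:
    """Codon alignment per pair with target Ks/omega.

    The ancestor is uniform over sense codons; one lineage accrues
    round(Ks*S) synonymous and round(Ka*N) nonsynonymous single-nucleotide
    substitutions (stop codons rejected), so the realized NG86 estimates
    scatter around the targets. Per-pair ``target_ks``/``target_omega``
    columns override the config defaults.
    """
    rng = _rng(seed, "sequences")

    def _target(row: pd.Series, key: str, default: float) -> float:
        v = row.get(key)
        return default if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)

    out = []
    for _, row in pairs.iterrows():
        ks = _target(row, "target_ks", config.target_ks)
        omega = _target(row, "target_omega", config.target_omega)
        codons = list(rng.choice(SENSE_CODONS, size=config.n_codons))
        anc = "".join(codons)
        S = sum(SYN_SITES[c] for c in codons)
        N = 3 * config.n_codons - S
        syn_target = int(round(ks * S))
        nonsyn_target = int(round(omega * ks * N))
        cur = list(codons)
        syn_done = nonsyn_done = 0
        guard = 0
        while (syn_done < syn_target or nonsyn_done < nonsyn_target) and guard < 10**6:
            guard += 1
            ci = int(rng.integers(config.n_codons))
            pos = int(rng.integers(3))
            nt = "ACGT"[int(rng.integers(4))]
            codon = cur[ci]
            if codon[pos] == nt:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            if CODON_TO_AA[alt] == CODON_TO_AA[codon]:
                if syn_done < syn_target:
                    cur[ci] = alt
                    syn_done += 1
            else:
                if nonsyn_done < nonsyn_target:
                    cur[ci] = alt
                    nonsyn_done += 1
        out.append((row["gene1"], row["gene2"], anc, "".join(cur)))
    return out


def simulate_expression(
    classes: Mapping[str, str],
    config: SimulationConfig,
    seed: int,
    tau_targets: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Expression matrix with per-gene tau near the class target.

    Profiles are Dirichlet draws whose mean is the shape that realizes the
    target tau exactly (one dominant condition, the rest at 1 - tau);
    the high default concentration keeps the max-normalized tau of a draw
    unbiased. Rows are scaled by a lognormal magnitude.
    """
    rng = _rng(seed, "expression")
    cols = [f"cond{i}" for i in range(config.n_conditions)]
    rows = {}
    for gid, cls in classes.items():
        if tau_targets is not None and gid in tau_targets:
            tau = float(tau_targets[gid])
        else:
            tau = float(config.class_tau.get(cls, 0.5))
        w = np.full(config.n_conditions, 1.0 - tau)
        w[int(rng.integers(config.n_conditions))] = 1.0
        alpha = np.maximum(config.dirichlet_concentration * w / w.sum(), 1e-6)
        x = rng.dirichlet(alpha)
        scale = float(rng.lognormal(mean=2.0, sigma=0.5)) * config.n_conditions
        rows[gid] = x * scale
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def simulate_orthogroups(
    config: SimulationConfig, seed: int
) -> tuple[dict, dict[str, str], pd.Series]:
    """Orthogroup table with planted categories; returns (table, species->
    family map, truth categories)."""
    rng = _rng(seed, "orthogroups")
    species = [f"sp{i:02d}" for i in range(config.n_species)]
    species_family = {
        sp: f"fam{i % config.n_families}" for i, sp in enumerate(species)
    }
    fam_members: dict[str, list[str]] = {}
    for sp, fam in species_family.items():
        fam_members.setdefault(fam, []).append(sp)
    core_min = math.ceil(config.core_fraction * config.n_species)
    table: dict[str, dict[str, list[str]]] = {}
    truth = {}
    idx = 0

    def _genes(sp: str, og: str, k: int) -> list[str]:
        return [f"{sp}_{og}_{j}" for j in range(k)]

    for cat, count in config.og_counts.items():
        for _ in range(count):
            og = f"OG{idx:06d}"
            idx += 1
            members: dict[str, list[str]] = {}
            if cat.startswith("core"):
                n_present = int(rng.integers(core_min, config.n_species + 1))
                present = list(rng.choice(species, size=n_present, replace=False))
                sc_min = math.ceil(config.sc_fraction * n_present)
                if cat == "core:single-copy":
                    n_single = int(rng.integers(sc_min, n_present + 1))
                else:
                    n_single = int(rng.integers(0, sc_min))
                singles = set(present[:n_single])
                for sp in present:
                    members[sp] = _genes(sp, og, 1 if sp in singles else 2)
            elif cat == "cross-family":
                fams = rng.choice(list(fam_members), size=2, replace=False)
                pool = [fam_members[f][0] for f in fams]
                n_extra = int(rng.integers(0, core_min - 1 - 2))
                others = [sp for sp in species if sp not in pool]
                pool += list(rng.choice(others, size=n_extra, replace=False))
                pool = pool[: core_min - 1]
                for sp in pool:
                    members[sp] = _genes(sp, og, int(rng.integers(1, 3)))
            elif cat == "family-specific":
                fam = list(fam_members)[int(rng.integers(len(fam_members)))]
                k = int(rng.integers(2, len(fam_members[fam]) + 1))
                for sp in rng.choice(fam_members[fam], size=k, replace=False):
                    members[sp] = _genes(sp, og, int(rng.integers(1, 3)))
            elif cat == "species-specific":
                sp = species[int(rng.integers(len(species)))]
                members[sp] = _genes(sp, og, int(rng.integers(1, 4)))
            else:
                raise ValueError(f"unknown planted category {cat}")
            table[og] = members
            truth[og] = cat
    return table, species_family, pd.Series(truth, name="category")


def simulate_tes(
    genes: Sequence[GeneModel],
    classes: Mapping[str, str],
    config: SimulationConfig,
    seed: int,
) -> list[TEFeature]:
    """Place TEs just upstream of genes, preferentially near teM genes."""
    rng = _rng(seed, "tes")
    tes = []
    for g in genes:
        p = config.te_prob_teM if classes[g.gene_id] == "teM" else config.te_prob_other
        if rng.random() < p:
            end = g.start - int(rng.integers(50, 900))
            start = end - config.te_length
            if start >= 0:
                tes.append(TEFeature(chrom=g.chrom, start=start, end=end, family="LTR"))
    return tes


def simulate_population(
    classes: Mapping[str, str], config: SimulationConfig, seed: int
) -> pd.DataFrame:
    """Per-accession label matrix (genes x accessions).

    Each accession keeps a gene's base class or switches per the switch-
    rate matrix; a configurable fraction of entries are "missing".
    """
    rng = _rng(seed, "population")
    acc = [f"acc{i:04d}" for i in range(config.n_accessions)]
    rows = {}
    for gid, base in classes.items():
        switches = config.switch_rates.get(base, {})
        targets = list(switches)
        probs = [switches[t] for t in targets]
        stay = 1.0 - sum(probs)
        labels = rng.choice([base, *targets], size=config.n_accessions, p=[stay, *probs])
        if config.missing_rate > 0:
            miss = rng.random(config.n_accessions) < config.missing_rate
            labels = np.where(miss, "missing", labels)
        rows[gid] = labels
    return pd.DataFrame.from_dict(rows, orient="index", columns=acc)


def simulate_coverage(
    gene_ids: Sequence[str], config: SimulationConfig, seed: int, n_accessions: int = 20
) -> tuple[pd.DataFrame, set[str]]:
    """PAV coverage matrix: most genes ~1x everywhere; a planted fraction
    drop below the 0.2 threshold in >= 1 accession. Returns (matrix, truth)."""
    rng = _rng(seed, "coverage")
    acc = [f"acc{i:03d}" for i in range(n_accessions)]
    cov = rng.lognormal(mean=0.0, sigma=0.2, size=(len(gene_ids), n_accessions))
    cov = np.maximum(cov, 0.3)
    truth = set()
    for i, gid in enumerate(gene_ids):
        if rng.random() < config.pav_fraction:
            j = int(rng.integers(n_accessions))
            cov[i, j] = float(rng.uniform(0.0, 0.15))
            truth.add(gid)
    return pd.DataFrame(cov, index=gene_ids, columns=acc), truth


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    seed: int
    genome: SimulatedGenome
    classes: pd.Series
    allc: pd.DataFrame
    tes: list[TEFeature]
    expression: pd.DataFrame
    og_table: dict
    species_family: dict[str, str]
    og_truth: pd.Series
    population: pd.DataFrame
    alignments: list[tuple[str, str, str, str]]
    coverage: pd.DataFrame
    pav_truth: set[str]


def simulate_all(
    config: SimulationConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SimulatedDataset:
    """Generate the full dataset; optionally write all files to ``out_dir``."""
    config = config or SimulationConfig()
    genome = simulate_genome(config, seed)
    gene_ids = [g.gene_id for g in genome.genes]
    classes = assign_classes(gene_ids, config, seed)
    allc = simulate_methylome(genome.genes, classes, config, seed)
    tes = simulate_tes(genome.genes, classes, config, seed)
    expression = simulate_expression(classes, config, seed)
    og_table, species_family, og_truth = simulate_orthogroups(config, seed)
    population = simulate_population(classes, config, seed)
    alignments = simulate_sequences(genome.truth_pairs, config, seed)
    coverage, pav_truth = simulate_coverage(gene_ids, config, seed)
    ds = SimulatedDataset(
        config=config,
        seed=seed,
        genome=genome,
        classes=classes,
        allc=allc,
        tes=tes,
        expression=expression,
        og_table=og_table,
        species_family=species_family,
        og_truth=og_truth,
        population=population,
        alignments=alignments,
        coverage=coverage,
        pav_truth=pav_truth,
    )
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: SimulatedDataset, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    core_io.write_gff(ds.genome.genes, out / "genome.gff3")
    core_io.write_allc(ds.allc, out / "allc.tsv")
    core_io.write_bed(ds.tes, out / "tes.bed")
    core_io.write_hits(ds.genome.hits, out / "hits.tsv")
    core_io.write_hits(ds.genome.outgroup_hits, out / "outgroup_hits.tsv")
    species = sorted({sp for m in ds.og_table.values() for sp in m})
    core_io.write_orthogroups(ds.og_table, species, out / "orthogroups.tsv")
    pd.Series(ds.species_family).to_csv(
        out / "species_family.tsv", sep="\t", header=False
    )
    core_io.write_expression(ds.expression, out / "expression.tsv")
    ds.population.to_csv(out / "population_labels.tsv", sep="\t")
    ds.coverage.to_csv(out / "coverage.tsv", sep="\t")
    with open(out / "alignments.fa", "w") as fh, open(out / "pairs.tsv", "w") as ph:
        for g1, g2, s1, s2 in ds.alignments:
            fh.write(f">{g1}\n{s1}\n>{g2}\n{s2}\n")
            ph.write(f"{g1}\t{g2}\n")
    truth = out / "truth"
    truth.mkdir(exist_ok=True)
    ds.classes.rename("class").to_csv(truth / "classes.tsv", sep="\t")
    ds.genome.truth_pairs.to_csv(truth / "pairs.tsv", sep="\t", index=False)
    if not ds.genome.epoch_flags.empty:
        ds.genome.epoch_flags.to_csv(truth / "epochs.tsv", sep="\t", index=False)
    ds.og_truth.rename("category").to_csv(truth / "og_categories.tsv", sep="\t")
    pd.Series(sorted(ds.pav_truth)).to_csv(
        truth / "pav_genes.tsv", sep="\t", index=False, header=False
    )
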