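"""End-to-end orchestration: methylome -> duplicates -> orthogroups ->
Ka/Ks -> tau -> association statistics, with a run manifest.

``run_all`` consumes a declarative config (paths + thresholds), executes
the stages in dependency order, writes per-stage TSVs and a combined
gene-level master table, and records input checksums and row counts in a
JSON manifest. Optional inputs (expression, coverage, population panel)
simply skip their stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import assoc_stats, core_io, duplication, expression, methylome, orthogroups, seqevol

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "alpha": 0.05,
    "min_sites": 10,
    "unm_weighted_max": 0.02,
    "unm_max_methylated": 1,
    "max_evalue": 1e-5,
    "min_anchors": 5,
    "max_gap": 25,
    "max_intervening": 10,
    "te_margin": 1000,
    "window": 100_000,
    "step": 50_000,
    "pav_threshold": 0.2,
    "core_fraction": 0.879,
    "sc_fraction": 0.70,
    "background": "per-species",
    "species_name": "species1",
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def report_divergence(pairs: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair methylation divergence per duplication type, and switch
    directions among translocated pairs.

    Returns (divergence, switches): divergence has per dup_type the
    proportions of pairs with the same vs different class (excluded pairs
    reported separately); switches counts to-gbM/to-unM/to-teM among
    translocated pairs with classified parent and daughter.
    """
    rows = []
    for dt, sub in pairs.groupby("dup_type"):
        n = len(sub)
        same = int((sub["pair_same"] == "same").sum())
        diff = int((sub["pair_same"] == "different").sum())
        excl = n - same - diff
        rows.append(
            {
                "dup_type": dt,
                "n_pairs": n,
                "prop_same": same / n if n else float("nan"),
                "prop_different": diff / n if n else float("nan"),
                "prop_excluded": excl / n if n else float("nan"),
            }
        )
    divergence = pd.DataFrame(rows)
    sw_counts: dict[str, int] = {}
    tra = pairs.loc[pairs["dup_type"] == "translocated"]
    for _, row in tra.iterrows():
        pl, dl = row.get("parent_label"), row.get("daughter_label")
        if pl in duplication.PAIR_CLASS_ORDER and dl in duplication.PAIR_CLASS_ORDER:
            d = duplication.switch_direction(pl, dl)
            sw_counts[d] = sw_counts.get(d, 0) + 1
    switches = pd.DataFrame(
        [{"direction": k, "n": v} for k, v in sorted(sw_counts.items())],
        columns=["direction", "n"],
    )
    return divergence, switches


def run_all(config: Mapping[str, Any], out_dir: str | Path) -> Path:
    """Execute the full pipeline from a config mapping.

    Required config keys: ``gff``, ``allc``, ``hits``. Optional: ``tes``,
    ``outgroup_hits``, ``orthogroups``, ``species_family``, ``expression``,
    ``coverage``, ``population``, plus any threshold in ``DEFAULTS``.
    """
    cfg = {**DEFAULTS, **dict(config)}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"inputs": {}, "rows": {}, "config": {}}
    for k, v in cfg.items():
        manifest["config"][k] = str(v)

    for key in ("gff", "allc", "hits"):
        if key not in cfg or not Path(cfg[key]).exists():
            raise FileNotFoundError(f"required input {key!r} missing (stage: inputs)")
    for key in (
        "gff", "allc", "hits", "tes", "outgroup_hits", "orthogroups",
        "species_family", "expression", "coverage", "population",
    ):
        if key in cfg and cfg[key] and Path(cfg[key]).exists():
            manifest["inputs"][key] = _sha256(Path(cfg[key]))

    # --- methylome ---------------------------------------------------------
    genes = core_io.read_gff(cfg["gff"])
    sites = core_io.read_allc(cfg["allc"])
    summaries = methylome.summarize_genes(sites, genes)
    background = methylome.compute_background(summaries)
    meth = methylome.classify_genes(
        summaries,
        background,
        alpha=cfg["alpha"],
        min_sites=cfg["min_sites"],
        unm_weighted_max=cfg["unm_weighted_max"],
        unm_max_methylated=cfg["unm_max_methylated"],
    )
    meth.to_csv(out / "methylome.tsv", sep="\t")
    labels = meth["label"]
    manifest["rows"]["methylome"] = len(meth)

    # --- duplicates --------------------------------------------------------
    gene_index = {g.gene_id: (g.chrom, g.rank) for g in genes}
    hits = core_io.read_hits(cfg["hits"], max_evalue=cfg["max_evalue"])
    intra_blocks = duplication.detect_collinear_blocks(
        hits, gene_index, max_gap=cfg["max_gap"], min_anchors=cfg["min_anchors"]
    )
    syntenic = duplication.anchor_genes(intra_blocks)
    if cfg.get("outgroup_hits"):
        og_hits = core_io.read_hits(cfg["outgroup_hits"], max_evalue=cfg["max_evalue"])
        if cfg.get("outgroup_ranks"):
            subj_index = cfg["outgroup_ranks"]
        elif cfg.get("outgroup_gff"):
            subj_index = {
                g.gene_id: (g.chrom, g.rank) for g in core_io.read_gff(cfg["outgroup_gff"])
            }
        else:
            # no outgroup coordinates: assume subject ids sort in gene order
            subj_index = {
                s: ("outgroup", i)
                for i, s in enumerate(sorted(og_hits["subject"].unique()))
            }
        out_blocks = duplication.detect_collinear_blocks(
            og_hits,
            gene_index,
            subj_index,
            max_gap=cfg["max_gap"],
            min_anchors=cfg["min_anchors"],
        )
        syntenic |= duplication.anchor_genes(out_blocks, side="a")
    pairs = duplication.select_unique_pairs(hits)
    pairs = duplication.classify_pairs(
        pairs,
        gene_index,
        duplication.anchor_pairs(intra_blocks),
        syntenic,
        max_intervening=cfg["max_intervening"],
    )
    pc = [
        duplication.pair_meth_class(labels.get(g1), labels.get(g2))
        for g1, g2 in zip(pairs["gene1"], pairs["gene2"])
    ]
    pairs["pair_meth_class"] = [c for c, _ in pc]
    pairs["pair_same"] = [s for _, s in pc]
    pairs["parent_label"] = [
        labels.get(p) if p else None for p in pairs["parent"]
    ]
    pairs["daughter_label"] = [
        labels.get(d) if d else None for d in pairs["daughter"]
    ]
    blocks_rows = [
        {
            "block_id": i,
            "chrom_a": b.chrom_a,
            "chrom_b": b.chrom_b,
            "orientation": b.orientation,
            "n_anchors": b.score,
            "anchors": ";".join(f"{a},{bb}" for a, bb in b.anchors),
        }
        for i, b in enumerate(intra_blocks)
    ]
    pd.DataFrame(
        blocks_rows,
        columns=["block_id", "chrom_a", "chrom_b", "orientation", "n_anchors", "anchors"],
    ).to_csv(out / "blocks.tsv", sep="\t", index=False)
    manifest["rows"]["pairs"] = len(pairs)

    # --- orthogroups -------------------------------------------------------
    if cfg.get("orthogroups") and cfg.get("species_family"):
        og_table = core_io.read_orthogroups(cfg["orthogroups"])
        fam = core_io.read_species_map(cfg["species_family"])
        cats = orthogroups.categorize(
            og_table, fam, core_fraction=cfg["core_fraction"], sc_fraction=cfg["sc_fraction"]
        )
        cats.to_csv(out / "orthogroup_categories.tsv", sep="\t")
        sc = orthogroups.sc_status(cats, og_table)
        sc.to_csv(out / "sc_status.tsv", sep="\t", index=False)
        manifest["rows"]["orthogroups"] = len(cats)

    # --- Ka/Ks -------------------------------------------------------------
    if cfg.get("alignments") and cfg.get("pair_manifest"):
        alns = seqevol.read_alignments(cfg["alignments"], cfg["pair_manifest"])
        kaks = seqevol.kaks_table(alns, max_ks=cfg.get("max_ks"))
        pairs = pairs.merge(kaks, on=["gene1", "gene2"], how="left")
        manifest["rows"]["kaks"] = len(kaks)
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)

    # --- expression --------------------------------------------------------
    tau = None
    if cfg.get("expression"):
        matrix = core_io.read_expression(cfg["expression"])
        tau = expression.tau_table(matrix)
        tau.to_csv(out / "tau.tsv", sep="\t")
        expression.pair_expression(pairs, matrix).to_csv(
            out / "pair_expression.tsv", sep="\t", index=False
        )
        manifest["rows"]["tau"] = len(tau)

    # --- association statistics -------------------------------------------
    dup_category = {}
    for _, row in pairs.iterrows():
        for g in (row["gene1"], row["gene2"]):
            dup_category.setdefault(g, row["dup_type"])
    enr = assoc_stats.enrichment_scan(labels, pd.Series(dup_category))
    enr.to_csv(out / "enrichment_dup_types.tsv", sep="\t", index=False)

    te_flags = None
    if cfg.get("tes"):
        tes = core_io.read_bed(cfg["tes"])
        te_flags = assoc_stats.te_association(genes, tes, margin=cfg["te_margin"])
        chrom_lengths = cfg.get("chrom_lengths") or {
            ch: max(g.end for g in genes if g.chrom == ch) + cfg["te_margin"]
            for ch in {g.chrom for g in genes}
        }
        prof, corr = assoc_stats.sliding_windows(
            genes, labels.to_dict(), tes, chrom_lengths,
            window=cfg["window"], step=cfg["step"],
        )
        prof.to_csv(out / "windows.tsv", sep="\t", index=False)
        corr.to_csv(out / "window_correlations.tsv", sep="\t", index=False)

    pav = None
    if cfg.get("coverage"):
        coverage = pd.read_csv(cfg["coverage"], sep="\t", index_col=0)
        pav = assoc_stats.call_pav(coverage, threshold=cfg["pav_threshold"])
        pd.Series(sorted(pav)).to_csv(out / "pav_genes.tsv", sep="\t", index=False, header=False)

    if cfg.get("population"):
        pop = pd.read_csv(cfg["population"], sep="\t", index_col=0)
        freq = assoc_stats.population_frequency(pop)
        freq.to_csv(out / "population_frequency.tsv", sep="\t")
        manifest["rows"]["population"] = len(freq)

    divergence, switches = report_divergence(pairs)
    divergence.to_csv(out / "pair_divergence.tsv", sep="\t", index=False)
    switches.to_csv(out / "switch_directions.tsv", sep="\t", index=False)

    # --- master table ------------------------------------------------------
    master = pd.DataFrame({"label": labels})
    master["dup_type"] = pd.Series(dup_category).reindex(master.index)
    if tau is not None:
        master["tau"] = tau["tau"].reindex(master.index)
    if te_flags is not None:
        master["te_associated"] = te_flags.reindex(master.index)
    if pav is not None:
        master["pav"] = master.index.isin(set(pav))
    master.to_csv(out / "master_table.tsv", sep="\t")
    manifest["rows"]["master"] = len(master)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return out
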