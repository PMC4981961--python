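"""End-to-end orchestration of the discovery pipeline on synthetic data.

Stages run in the fixed order qc -> map -> annotate -> discover ->
families -> targets -> enrich; every stage consumes only the declared
artifacts of its predecessors.  All randomness flows from the single
root seed in the configuration, so a rerun with the same config is
bit-identical (the report bundle hash is part of the result).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import annotate as annotate_mod
from . import discover as discover_mod
from . import enrich as enrich_mod
from . import families as families_mod
from . import mapping as mapping_mod
from . import qc as qc_mod
from . import synthio
from . import targets as targets_mod
from .io import write_fasta, write_tsv

log = logging.getLogger("miralga")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 1
    out_dir: str = "miralga_out"
    min_len: int = 18
    min_qual: float = 20.0
    max_len: int | None = 43
    max_mm: int = 2
    max_gap: int = 3
    homology_budget: int = 3
    family_identity: float = 0.98
    family_max_mismatch: int = 1
    mfe_cutoff: float = -18.0
    overhang_max: int = 2
    bulge_max: int = 4
    preset_caps: dict = field(default_factory=lambda: dict(targets_mod.PRESETS))
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


@dataclass
class PipelineResult:
    qc_report: qc_mod.QCReport
    redundancy_ratio: float
    length_dist: dict
    mapping_summary: mapping_mod.MappingSummary
    annotation_summary: dict
    candidates: list
    families: list
    family_table: dict
    target_summary: targets_mod.TargetSummary
    go_results: list
    kegg_results: list
    degrees: dict
    novel_sensitivity: float
    novel_precision: float
    report_hash: str
    truth: synthio.PlantedTruth
    refs: synthio.References


def _novel_recovery(candidates: list, truth: synthio.PlantedTruth) -> tuple[float, float]:
    """Sensitivity/precision of novel calls against planted novel loci."""
    planted = {p.mature: p for p in truth.precursors if p.kind == "novel"}
    novel = [c for c in candidates if c.source == "novel"]
    tp = sum(1 for c in novel if c.mature in planted)
    recovered = len({c.mature for c in novel if c.mature in planted})
    sens = recovered / len(planted) if planted else 1.0
    prec = tp / len(novel) if novel else 1.0
    return sens, prec


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Run every stage on a synthetic study generated from cfg.seed."""
    for key, value in sorted(asdict(cfg).items()):
        log.info("config %s = %r", key, value)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_cfg = synthio.SimConfig(seed=cfg.seed, **cfg.sim)
    contigs, truth = synthio.make_genome(sim_cfg)
    raw = synthio.simulate_reads(contigs, truth, sim_cfg)
    refs = synthio.make_references(sim_cfg, truth)

    # --- qc ---------------------------------------------------------------
    unique, labels, report = qc_mod.clean_reads(
        raw, min_len=cfg.min_len, min_qual=cfg.min_qual, max_len=cfg.max_len)
    ratio = qc_mod.redundancy_ratio(report.clean_reads, len(unique))
    length_dist = qc_mod.length_distribution(unique, weighted=True)
    log.info("qc: %d clean of %d (%.2f%%), %d unique, redundancy %.1f",
             report.clean_reads, report.high_quality,
             report.percentages["clean_reads"], len(unique), ratio)

    # --- map --------------------------------------------------------------
    hits, msum = mapping_mod.map_reads(unique, contigs)
    hits_by_read: dict[str, list] = {}
    for h in hits:
        hits_by_read.setdefault(h.read_id, []).append(h)
    log.info("map: %d/%d unique (%.2f%%), %d/%d total (%.2f%%)",
             msum.unique_mapped, msum.unique_total, msum.unique_pct,
             msum.reads_mapped, msum.reads_total, msum.reads_pct)

    # --- annotate ---------------------------------------------------------
    ann, ann_summary = annotate_mod.annotate_cascade(
        unique, refs.ncrna, refs.mature_db, cfg.max_mm, cfg.max_gap)
    log.info("annotate: %s", {k: v["unique"] for k, v in ann_summary.items()})

    # --- discover ---------------------------------------------------------
    filt = discover_mod.NovelFilterConfig(
        mfe_cutoff=cfg.mfe_cutoff, overhang_max=cfg.overhang_max,
        bulge_max=cfg.bulge_max)
    known = discover_mod.known_from_reads(ann, refs.mature_db, contigs,
                                          hits_by_read, filt)
    est = discover_mod.conserved_from_ests(refs.ests, refs.mature_db,
                                           refs.ncrna, cfg.homology_budget, filt)
    novel = discover_mod.novel_from_loci(ann, hits_by_read, contigs, filt)
    candidates = known + est + novel
    sens, prec = _novel_recovery(candidates, truth)
    log.info("discover: %d known, %d est, %d novel (sens %.2f prec %.2f)",
             len(known), len(est), len(novel), sens, prec)

    # --- families ---------------------------------------------------------
    fams = families_mod.cluster_families(candidates, cfg.family_identity,
                                         cfg.family_max_mismatch)
    fam_table = families_mod.family_size_table(fams)

    # --- targets ----------------------------------------------------------
    mirnas = {c.id: c.mature for c in candidates}
    mirna_class = {c.id: ("novel" if c.source == "novel" else "conserved")
                   for c in candidates}
    sites = targets_mod.scan_all(mirnas, refs.transcripts, cfg.mfe_cutoff)
    tsum = targets_mod.summarize_targets(sites, mirna_class)

    # --- enrich -----------------------------------------------------------
    background = set(refs.transcripts)
    selected = {s.transcript_id for s in tsum.union}
    go_res = enrich_mod.hypergeom_enrich(selected, refs.go_map, background) \
        if selected else []
    kegg_res = enrich_mod.hypergeom_enrich(selected, refs.kegg_map, background) \
        if selected else []
    edges, degrees = enrich_mod.export_network(tsum.union)

    # --- report bundle ----------------------------------------------------
    write_tsv(out / "qc_report.tsv", ["Type", "Reads", "Percent"], report.rows())
    write_tsv(out / "mapping_summary.tsv",
              ["Metric", "Unique reads", "Percent", "Clean reads", "Percent"],
              [("Total", msum.unique_total, "100 %", msum.reads_total, "100 %"),
               ("Mapping to genome", msum.unique_mapped, f"{msum.unique_pct:.2f} %",
                msum.reads_mapped, f"{msum.reads_pct:.2f} %")])
    write_tsv(out / "length_distribution.tsv", ["length", "fraction"],
              [(k, f"{v:.6f}") for k, v in length_dist.items()])
    write_tsv(out / "annotation_summary.tsv", ["category", "unique", "total"],
              [(c, v["unique"], v["total"]) for c, v in ann_summary.items()])
    write_tsv(out / "candidates.tsv",
              ["id", "source", "mature", "precursor_len", "mfe", "structure",
               "total_reads", "unique_reads", "family_hit"],
              [(c.id, c.source, c.mature, len(c.precursor),
                f"{c.fold_result.mfe:.1f}" if c.fold_result else "",
                c.fold_result.structure if c.fold_result else "",
                c.total_reads, c.unique_reads, c.homolog_family)
               for c in candidates])
    write_tsv(out / "family_sizes.tsv",
              ["size", "n_families", "conserved_pct", "novel_pct"],
              [(s, d["n"], f"{d['conserved_pct']:.2f} %", f"{d['novel_pct']:.2f} %")
               for s, d in fam_table["by_size"].items()])
    write_tsv(out / "target_summary.tsv",
              ["class", "preset", "n_mirnas", "n_target_genes",
               "cleavage_loci", "ti_loci", "ti_pct"],
              [(r["class"], r["preset"], r["n_mirnas"], r["n_target_genes"],
                r["cleavage_loci"], r["ti_loci"], f"{r['ti_pct']:.2f} %")
               for r in tsum.rows])
    write_tsv(out / "go_enrichment.tsv",
              ["term", "name", "k", "K", "n", "N", "p", "p_adj", "q", "significant"],
              [(r.term_id, r.term_name, r.k, r.K, r.n, r.N, f"{r.p:.3e}",
                f"{r.p_adj:.3e}", f"{r.q:.3e}", r.significant_go) for r in go_res])
    write_tsv(out / "kegg_enrichment.tsv",
              ["term", "name", "k", "K", "n", "N", "p", "p_adj", "q", "significant"],
              [(r.term_id, r.term_name, r.k, r.K, r.n, r.N, f"{r.p:.3e}",
                f"{r.p_adj:.3e}", f"{r.q:.3e}", r.significant_kegg) for r in kegg_res])
    with open(out / "network.sif", "w") as fh:
        fh.write("miRNA\trelation\tgene\n")
        for a, rel, b in edges:
            fh.write(f"{a}\t{rel}\t{b}\n")
    write_fasta(out / "mature.fasta", [(c.id, c.mature) for c in candidates])
    write_fasta(out / "precursors.fasta",
                [(f"{c.id} {c.fold_result.structure}" if c.fold_result else c.id,
                  c.precursor) for c in candidates])
    novel_cands = [c for c in candidates if c.source == "novel"]
    if novel_cands:
        pos_matrix, first_base, length_hist = \
            discover_mod.composition_stats(novel_cands)
        write_tsv(out / "novel_base_by_position.tsv",
                  ["position", "A", "C", "G", "U"],
                  [(p, *(f"{v[b]:.4f}" for b in "ACGU"))
                   for p, v in pos_matrix.items()])
        write_tsv(out / "novel_first_base.tsv", ["base", "fraction"],
                  [(b, f"{first_base[b]:.4f}") for b in "ACGU"])
        write_tsv(out / "novel_length_hist.tsv", ["length", "fraction"],
                  [(k, f"{v:.4f}") for k, v in length_hist.items()])
    posdist = mapping_mod.positional_distribution(hits, contigs, bin_size=1000)
    write_tsv(out / "positional_distribution.tsv",
              ["contig", "bin_start", "hits"],
              [(cid, i * 1000, n) for cid in sorted(posdist)
               for i, n in enumerate(posdist[cid])])
    counts = families_mod.species_family_counts(refs.mature_db)
    fam_names, species, matrix = families_mod.conservation_matrix(
        fams, counts, sorted({sp for sp, _ in counts}))
    write_tsv(out / "conservation_matrix.tsv", ["family"] + species,
              [(name, *row) for name, row in zip(fam_names, matrix)])

    sha = hashlib.sha256()
    for name in sorted(p.name for p in out.iterdir() if p.is_file()):
        sha.update(name.encode())
        sha.update((out / name).read_bytes())
    report_hash = sha.hexdigest()
    log.info("report hash %s", report_hash)

    return PipelineResult(
        qc_report=report, redundancy_ratio=ratio, length_dist=length_dist,
        mapping_summary=msum, annotation_summary=ann_summary,
        candidates=candidates, families=fams, family_table=fam_table,
        target_summary=tsum, go_results=go_res, kegg_results=kegg_res,
        degrees=degrees, novel_sensitivity=sens, novel_precision=prec,
        report_hash=report_hash, truth=truth, refs=refs,
    )
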