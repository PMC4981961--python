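"""Synthetic study generator: determinism, planted-truth consistency."""

import hashlib
from pathlib import Path

import pytest

from miralga.discover import NovelFilterConfig, passes_novel_filters
from miralga.fold import PAIR_INDEX, fold
from miralga.io import revcomp
from miralga.qc import clean_reads
from miralga.synthio import (SimConfig, make_genome, make_references,
                             simulate_reads, write_all)


def dir_hash(path: Path) -> str:
    sha = hashlib.sha256()
    for p in sorted(path.iterdir()):
        sha.update(p.name.encode())
        sha.update(p.read_bytes())
    return sha.hexdigest()


def test_identical_seed_gives_byte_identical_outputs(tmp_path):
    cfg = SimConfig(seed=1, n_reads=500, n_planted_precursors=4,
                    n_planted_known=3, n_contigs=6, n_transcripts=40,
                    n_ests=20, n_planted_targets=8, n_planted_est_homologs=2)
    write_all(tmp_path / "a", cfg)
    write_all(tmp_path / "b", cfg)
    assert dir_hash(tmp_path / "a") == dir_hash(tmp_path / "b")


def test_nothing_planted_leaves_no_long_complementary_window():
    cfg = SimConfig(seed=1, n_planted_precursors=0, n_planted_known=0,
                    n_contigs=4, contig_len=2000)
    contigs, truth = make_genome(cfg)
    assert truth.precursors == []
    # exhaustive scan: no 18 bp perfectly complementary stem anywhere
    for seq in contigs.values():
        rc = revcomp(seq)
        k = 18
        windows = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        for j in range(len(rc) - k + 1):
            assert rc[j : j + k] not in windows


def test_planted_loci_reextractable_from_fasta(tmp_path):
    cfg = SimConfig(seed=7, n_planted_precursors=12, n_planted_known=8)
    contigs, truth = make_genome(cfg)
    assert len(truth.precursors) == 20
    for p in truth.precursors:
        region = contigs[p.contig][p.start : p.end]
        assert region.startswith(p.mature)
        assert region.endswith(p.star)
        assert contigs[p.contig][p.mature_start : p.mature_start + len(p.mature)] == p.mature


def test_contig_too_short_rejected():
    with pytest.raises(ValueError, match="too short"):
        make_genome(SimConfig(contig_len=60))


def test_invalid_rates_rejected():
    with pytest.raises(ValueError, match="sum"):
        SimConfig(contamination_rates={"polyA": 0.6, "short_lt18": 0.5}).validate()
    with pytest.raises(ValueError, match="unknown"):
        SimConfig(contamination_rates={"weird": 0.1}).validate()
    with pytest.raises(ValueError):
        SimConfig(n_reads=-1).validate()


class TestReadSimulation:
    def test_zero_contamination_gives_all_clean(self):
        cfg = SimConfig(seed=2, n_reads=400,
                        contamination_rates={c: 0.0 for c in
                                             ("low_quality", "polyA")})
        contigs, truth = make_genome(cfg)
        reads = simulate_reads(contigs, truth, cfg)
        _, labels, rep = clean_reads(reads)
        assert rep.clean_reads == rep.high_quality == 400
        assert truth.read_categories.count("clean") == 400

    def test_qc_bins_match_drawn_truth_exactly(self):
        cfg = SimConfig(seed=3, n_reads=1000,
                        contamination_rates={"short_lt18": 0.1})
        contigs, truth = make_genome(cfg)
        reads = simulate_reads(contigs, truth, cfg)
        _, labels, rep = clean_reads(reads)
        drawn = truth.read_categories.count("short_lt18")
        assert drawn > 0
        assert rep.removed["short_lt18"] == drawn
        assert labels == truth.read_categories

    def test_highly_expressed_mature_is_top_collapsed_read(self):
        cfg = SimConfig(seed=4, n_reads=3000)
        contigs, truth = make_genome(cfg)
        reads = simulate_reads(contigs, truth, cfg)
        unique, _, _ = clean_reads(reads)
        planted = {p.mature for p in truth.precursors}
        assert unique[0].sequence in planted


class TestReferences:
    def test_zero_gu_rate_means_pure_watson_crick_duplexes(self):
        cfg = SimConfig(seed=5, gu_rate=0.0, n_planted_precursors=10)
        _, truth = make_genome(cfg)
        for p in truth.precursors:
            assert p.star == revcomp(p.mature)

    def test_est_decoys_sit_past_the_homology_budget(self, study):
        import edlib
        truth, refs = study["truth"], study["refs"]
        decoys = [e for e in truth.est_homologs if not e.compliant]
        assert decoys
        for d in decoys:
            dist = min(edlib.align(d.mature, m, mode="NW")["editDistance"]
                       for m in refs.mature_db.values())
            assert dist >= 4

    def test_planted_target_sites_reextractable(self, study):
        truth, refs = study["truth"], study["refs"]
        assert truth.target_sites
        for s in truth.target_sites:
            window = refs.transcripts[s.transcript_id][
                s.site_start : s.site_start + len(s.mirna_seq)]
            # pairing pattern holds position by position
            L = len(s.mirna_seq)
            for i, state in enumerate(s.pattern):
                m, t = s.mirna_seq[i], window[L - 1 - i]
                wc = revcomp(m) == t
                gu = (m, t) in (("G", "U"), ("U", "G"))
                assert state == ("|" if wc else "o" if gu else "x")

    def test_enriched_term_is_concentrated_in_targeted_genes(self, study):
        truth, refs = study["truth"], study["refs"]
        targeted = {s.transcript_id for s in truth.target_sites}
        with_term = {g for t, g, _ in refs.go_map if t == truth.enriched_term}
        inside = len(with_term & targeted) / len(targeted)
        outside = len(with_term - targeted) / (len(refs.transcripts) - len(targeted))
        assert inside > 5 * outside


def test_planted_precursors_pass_their_own_filters(study):
    """Truth consistency: run the novel-candidate filter battery on the
    planted precursor records alone (no reads, no mapping)."""
    fc = NovelFilterConfig()
    for p in study["truth"].precursors:
        fr = fold(study["contigs"][p.contig][p.start : p.end])
        ok, why = passes_novel_filters(fr, (0, len(p.mature)), fc)
        assert ok, f"{p.name}: {why}"
        assert fr.n_hairpin_loops == 1
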