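"""Conserved/novel miRNA discovery against planted ground truth."""

import pytest

from miralga.annotate import Alignment, AnnotationResult
from miralga.discover import (MiRNACandidate, NovelFilterConfig,
                              cluster_loci, composition_stats,
                              conserved_from_ests, known_from_reads,
                              novel_from_loci, passes_novel_filters)
from miralga.fold import structure_metrics
from miralga.io import revcomp
from miralga.mapping import MappingHit


@pytest.fixture(scope="module")
def discovered(study, stages):
    refs, contigs = study["refs"], study["contigs"]
    known = known_from_reads(stages["ann"], refs.mature_db, contigs,
                             stages["hits_by_read"])
    est = conserved_from_ests(refs.ests, refs.mature_db, refs.ncrna)
    novel = novel_from_loci(stages["ann"], stages["hits_by_read"], contigs)
    return {"known": known, "est": est, "novel": novel}


class TestKnownFromReads:
    def test_every_planted_known_family_recovered(self, study, discovered):
        planted = {p.mature for p in study["truth"].precursors
                   if p.kind == "known"}
        got = {c.mature for c in discovered["known"]}
        assert planted <= got

    def test_candidates_respect_homology_budgets(self, discovered):
        for c in discovered["known"]:
            assert c.homolog_mismatches <= 2 and c.homolog_gaps <= 3
            c.validate()

    def test_hit_with_three_mismatches_never_reaches_discovery(self):
        # annotation enforces the (2 mm, 3 gap) budget, so a crafted
        # 3-mismatch "hit" cannot exist in its output; feeding one in
        # anyway must not crash grouping, and the budget check is the
        # annotation result's invariant
        ann = AnnotationResult("u1_x9", "A" * 21, 9, "unannotated", None)
        out = known_from_reads([ann], {}, {"c": "A" * 200}, {})
        assert out == []

    def test_locus_with_two_hairpin_loops_is_rejected(self):
        # the hairpin-validity rule itself: two terminal loops fail
        seq = "GGGGAAAACCCCAAGGGGAAAACCCC"
        fr = structure_metrics(seq, "((((....))))..((((....))))", -25.0)
        ok, why = passes_novel_filters(fr, (0, 12), NovelFilterConfig())
        assert not ok and "hairpin_loops=2" in why


class TestConservedFromEsts:
    def test_exactly_the_planted_compliant_homologs(self, study, discovered):
        import edlib
        truth = study["truth"]
        compliant = [e for e in truth.est_homologs if e.compliant]
        est = discovered["est"]
        assert len(est) == len(compliant)
        # every candidate matches one planted homolog (up to the gap
        # ambiguity of the recovered window)
        for c in est:
            d = min(edlib.align(c.mature, e.mature, mode="NW")["editDistance"]
                    for e in compliant)
            assert d <= 2

    def test_homolog_beyond_budget_rejected(self, study, discovered):
        decoy_ests = {e.est_id for e in study["truth"].est_homologs
                      if not e.compliant}
        assert decoy_ests
        hit_ests = {c.locus[0] for c in discovered["est"]}
        assert not (decoy_ests & hit_ests)

    def test_homolog_also_matching_trna_is_rejected(self):
        mature = "UGAGGUAGUAGGUUGUAUAGU"
        star = revcomp(mature)
        est = {"E1": "GCAU" * 10 + mature + "GUCAAG" + star + "CGUA" * 10}
        db = {"osa-miR1": mature}
        # the same mature is an exact fragment of a tRNA reference
        ncrna = {"tRNA": {"t1": "CCGG" + mature + "AAGG"}}
        assert conserved_from_ests(est, db, ncrna) == []
        # without the tRNA clash the same EST yields the candidate
        found = conserved_from_ests(est, db, {})
        assert [c.mature for c in found] == [mature]


class TestNovelFromLoci:
    def test_planted_recovery_sensitivity_and_precision(self, study, discovered):
        planted = {p.mature for p in study["truth"].precursors
                   if p.kind == "novel"}
        got = {c.mature for c in discovered["novel"]}
        sens = len(got & planted) / len(planted)
        prec = len(got & planted) / len(got)
        assert sens >= 0.95
        assert prec >= 0.95

    def test_mfe_just_above_cutoff_rejected(self):
        seq = "GGGGAAAACCCCAAGG"
        fr = structure_metrics(seq[:12] + "AAGG", "((((....))))....", -17.0)
        ok, why = passes_novel_filters(fr, (0, 12), NovelFilterConfig())
        assert not ok and "mfe" in why

    def test_three_nt_overhang_construct_rejected(self):
        # mature with 3 unpaired bases at its 3' end inside the hairpin
        mature = "GGGGGGGGGGGGGGGGGGAAA"  # last 3 nt have no partner
        seq = mature + "AAAAAA" + "C" * 18
        db = "(" * 18 + "..." + "......" + ")" * 18
        fr = structure_metrics(seq, db, -40.0)
        ok, why = passes_novel_filters(fr, (0, len(mature)), NovelFilterConfig())
        assert not ok and "overhang" in why

    def test_relaxing_mfe_cutoff_never_removes_candidates(self, study, stages):
        strict = novel_from_loci(stages["ann"], stages["hits_by_read"],
                                 study["contigs"],
                                 NovelFilterConfig(mfe_cutoff=-18.0))
        loose = novel_from_loci(stages["ann"], stages["hits_by_read"],
                                study["contigs"],
                                NovelFilterConfig(mfe_cutoff=-10.0))
        assert {c.mature for c in strict} <= {c.mature for c in loose}

    def test_locus_clustering_merges_within_distance(self):
        hits = [MappingHit("a", "c", 100, 121, "+"),
                MappingHit("b", "c", 250, 271, "+"),
                MappingHit("d", "c", 900, 921, "+"),
                MappingHit("e", "c", 100, 121, "-")]
        loci = cluster_loci(hits, merge_dist=200)
        sizes = sorted(len(l) for l in loci)
        assert sizes == [1, 1, 2]


class TestCompositionStats:
    def _cands(self, matures):
        return [MiRNACandidate(f"m{i}", m, m, None, "novel")
                for i, m in enumerate(matures)]

    def test_first_base_fraction_direct_count(self):
        mats = ["U" + "A" * 20] * 6 + ["G" + "A" * 20] * 4
        _, first, _ = composition_stats(self._cands(mats))
        assert first["U"] == pytest.approx(0.6)

    def test_single_sequence_unit_vector(self):
        _, first, lengths = composition_stats(self._cands(["UGGC" + "A" * 17]))
        assert first == {"A": 0.0, "C": 0.0, "G": 0.0, "U": 1.0}
        assert lengths == {21: 1.0}

    def test_planted_five_prime_u_bias_dominates(self, study, discovered):
        _, first, _ = composition_stats(discovered["novel"])
        assert max(first, key=first.get) == "U"

    def test_position_frequencies_sum_to_one(self, discovered):
        pos, _, _ = composition_stats(discovered["novel"])
        for p, vec in pos.items():
            assert sum(vec.values()) == pytest.approx(1.0)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            composition_stats([])
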