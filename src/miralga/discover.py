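"""Conserved and novel miRNA identification.

Three discovery routes feed one candidate type:

* known miRNAs from sequenced reads — reads annotated as known-miRNA are
  grouped by their best database hit and their genomic locus is excised
  and folded; a candidate survives when the locus forms a valid hairpin.
* conserved miRNAs from ESTs — database matures are searched inside EST
  sequences with a combined mismatch+gap budget of 3; a hit survives when
  it is 18–25 nt, matches no other ncRNA class, and its flanking window
  folds into a valid hairpin.
* novel miRNAs from unannotated mapped loci — reads are clustered into
  loci (<= 200 nt apart), the most abundant read is taken as the mature,
  two excision windows are folded, and a candidate passes only the full
  rejection battery: single stem-loop, duplex overhangs <= 2 nt, per-
  strand loops/bulges <= 4 nt, MFE <= -18 kcal/mol.

"Valid hairpin" means one hairpin loop with the mature mostly (>= 0.75)
paired into the stem.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .annotate import Alignment, AnnotationResult, WordIndex, align_banded
from .fold import FoldResult, duplex_metrics, fold, pair_table
from .io import revcomp
from .mapping import GenomeIndex, MappingHit

__all__ = ["MiRNACandidate", "NovelFilterConfig", "known_from_reads",
           "conserved_from_ests", "novel_from_loci", "composition_stats",
           "cluster_loci", "passes_novel_filters"]

MATURE_LEN_RANGE = (18, 25)


@dataclass
class NovelFilterConfig:
    mfe_cutoff: float = -18.0  # kcal/mol, candidate MFE must be <= this
    overhang_max: int = 2
    bulge_max: int = 4
    mature_paired_min: float = 0.75
    locus_merge_dist: int = 200
    min_locus_support: int = 5  # top-read count needed before folding
    excise_flank_long: int = 150
    excise_flank_short: int = 20


@dataclass
class MiRNACandidate:
    id: str
    mature: str
    precursor: str
    fold_result: FoldResult | None
    source: str  # reads_known | est_homolog | novel
    total_reads: int = 0
    unique_reads: int = 0
    homolog_family: str = ""
    homolog_mismatches: int = 0
    homolog_gaps: int = 0
    locus: tuple = ()  # (contig/est id, start, end, strand)
    notes: str = ""

    def validate(self) -> None:
        lo, hi = MATURE_LEN_RANGE
        if not (lo <= len(self.mature) <= hi):
            raise ValueError(f"mature length {len(self.mature)} outside [{lo}, {hi}]")
        if self.source == "est_homolog" and self.homolog_mismatches + self.homolog_gaps > 3:
            raise ValueError("EST homolog exceeds mismatch+gap budget of 3")


def _valid_hairpin(fr: FoldResult, mature_span: tuple[int, int],
                   min_paired: float = 0.75) -> bool:
    """One hairpin loop and a mostly-paired mature arm."""
    if fr.n_hairpin_loops != 1:
        return False
    a, b = mature_span
    table = pair_table(fr.structure)
    paired = sum(1 for i in range(a, b) if table[i] >= 0)
    return paired / (b - a) >= min_paired


def passes_novel_filters(
    fr: FoldResult, mature_span: tuple[int, int], cfg: NovelFilterConfig
) -> tuple[bool, str]:
    """Apply the novel-miRNA rejection battery; returns (ok, reason)."""
    if fr.n_hairpin_loops != 1:
        return False, f"hairpin_loops={fr.n_hairpin_loops}"
    if fr.mfe > cfg.mfe_cutoff:
        return False, f"mfe={fr.mfe:.1f}>" + f"{cfg.mfe_cutoff:.0f}"
    try:
        d = duplex_metrics(fr, mature_span)
    except ValueError:
        return False, "mature_not_in_stem"
    a, b = mature_span
    paired = sum(1 for i in range(a, b) if pair_table(fr.structure)[i] >= 0)
    if paired / (b - a) < cfg.mature_paired_min:
        return False, "mature_underpaired"
    if d.overhang_5p > cfg.overhang_max or d.overhang_3p > cfg.overhang_max:
        return False, f"overhang=({d.overhang_5p},{d.overhang_3p})"
    if max(d.max_bulge_or_loop_mature, d.max_bulge_or_loop_star) > cfg.bulge_max:
        return False, "bulge_gt_max"
    return True, ""


def _excise_windows(seq: str, m_start: int, m_len: int,
                    cfg: NovelFilterConfig) -> list[tuple[int, int]]:
    """Candidate precursor windows around a mature placement.

    A ladder of flank extents on each side (the mature may sit on the 5'
    or the 3' arm, near or far from the loop); the caller folds each and
    keeps the best valid hairpin.  Trying several extents matters: in a
    long window, spurious flank-against-flank stems can bury a genuine
    but weakly-paired hairpin.
    """
    wins = []
    long_flanks = sorted({cfg.excise_flank_long, 100, 60, 30}, reverse=True)
    for lf in long_flanks:
        for left, right in ((cfg.excise_flank_short, lf),
                            (lf, cfg.excise_flank_short)):
            a = max(0, m_start - left)
            b = min(len(seq), m_start + m_len + right)
            if b - a >= m_len + 20 and (a, b) not in wins:
                wins.append((a, b))
    return wins


def known_from_reads(
    annotated: list[AnnotationResult],
    mirna_db: dict[str, str],
    contigs: dict[str, str],
    hits_by_read: dict[str, list[MappingHit]],
    filter_cfg: NovelFilterConfig | None = None,
) -> list[MiRNACandidate]:
    """Known miRNA candidates from reads that hit the miRNA database.

    One candidate per best-hit mature; the precursor is excised from the
    genome around the most abundant read's locus and must fold into a
    valid hairpin.  Hit groups without a genomic locus are dropped (with
    a note collected on the returned list's side).
    """
    cfg = filter_cfg or NovelFilterConfig()
    groups: dict[str, list[AnnotationResult]] = defaultdict(list)
    for r in annotated:
        if r.category == "known_miRNA" and r.hit is not None:
            groups[r.hit.ref_id].append(r)
    candidates = []
    for ref_id in sorted(groups):
        members = groups[ref_id]
        members.sort(key=lambda r: (-r.count, r.sequence))
        top = members[0]
        locus_hits = hits_by_read.get(top.read_id, [])
        if not locus_hits:
            continue  # no genomic locus for this hit group
        h = locus_hits[0]
        contig = contigs[h.contig]
        strand_seq = contig if h.strand == "+" else revcomp(contig)
        m_start = h.start if h.strand == "+" else len(contig) - h.end
        m_len = h.end - h.start
        best = None
        for a, b in _excise_windows(strand_seq, m_start, m_len, cfg):
            span = (m_start - a, m_start - a + m_len)
            fr = fold(strand_seq[a:b], enclose=span)
            if _valid_hairpin(fr, span, cfg.mature_paired_min):
                best = (fr, (a, b))
                break
        if best is None:
            continue
        fr, (a, b) = best
        cand = MiRNACandidate(
            id=f"ppu-{ref_id}", mature=top.sequence, precursor=fr.sequence,
            fold_result=fr, source="reads_known",
            total_reads=sum(m.count for m in members), unique_reads=len(members),
            homolog_family=ref_id, homolog_mismatches=top.hit.mismatches,
            homolog_gaps=top.hit.gaps,
            locus=(h.contig, a, b, h.strand),
        )
        cand.validate()
        candidates.append(cand)
    return candidates


def conserved_from_ests(
    ests: dict[str, str],
    mirna_db: dict[str, str],
    ncrna_sets: dict[str, dict[str, str]],
    homology_budget: int = 3,
    filter_cfg: NovelFilterConfig | None = None,
) -> list[MiRNACandidate]:
    """Additional conserved miRNAs mined from EST sequences.

    For every database mature, EST windows within a combined
    mismatch+gap budget (default 3) are collected; survivors must not
    match any other ncRNA set and their flanking window must fold into a
    valid hairpin.  Duplicates across ESTs merge by mature sequence.
    """
    cfg = filter_cfg or NovelFilterConfig()
    seen_matures: dict[str, MiRNACandidate] = {}
    lo, hi = MATURE_LEN_RANGE
    ncrna_idx = {cls: WordIndex(refs) for cls, refs in ncrna_sets.items() if refs}
    for db_id in sorted(mirna_db):
        mat = mirna_db[db_id]
        if not (lo <= len(mat) <= hi):
            continue
        # combined budget: mismatches + gaps <= homology_budget
        aln = align_banded(mat, ests, max_mismatch=homology_budget,
                           max_gap=homology_budget, search_revcomp=False,
                           max_cost=homology_budget)
        if aln is None:
            continue
        est_seq = ests[aln.ref_id]
        if aln.gaps:
            # refine the matched span: the budget DP reports only the end
            import edlib as _edlib

            loc = _edlib.align(mat, est_seq, mode="HW", task="locations",
                               k=homology_budget)["locations"][0]
            w_start, w_end = loc[0], loc[1] + 1
        else:
            w_start, w_end = aln.start, min(aln.end, len(est_seq))
        window = est_seq[w_start:w_end]
        if not (lo <= len(window) <= hi):
            continue
        if window in seen_matures:
            continue
        # one locus can match several species variants of a family; keep
        # the first candidate per overlapping EST region
        overlapping = any(
            c.locus[0] == aln.ref_id and
            min(c.locus[2], w_end) - max(c.locus[1], w_start) > len(window) // 2
            for c in seen_matures.values())
        if overlapping:
            continue
        # must not already be identifiable as any other ncRNA class
        if any(idx.best_hit(window, 2, 3) is not None for idx in ncrna_idx.values()):
            continue
        best = None
        for a, b in _excise_windows(est_seq, w_start, len(window), cfg):
            span = (w_start - a, w_start - a + len(window))
            fr = fold(est_seq[a:b], enclose=span)
            if _valid_hairpin(fr, span, cfg.mature_paired_min):
                best = (fr, (a, b))
                break
        if best is None:
            continue
        fr, (a, b) = best
        cand = MiRNACandidate(
            id=f"ppu-{db_id}-est", mature=window, precursor=fr.sequence,
            fold_result=fr, source="est_homolog",
            homolog_family=db_id, homolog_mismatches=aln.mismatches,
            homolog_gaps=aln.gaps, locus=(aln.ref_id, a, b, "+"),
        )
        cand.validate()
        seen_matures[window] = cand
    return list(seen_matures.values())


def cluster_loci(
    hits: list[MappingHit], merge_dist: int = 200
) -> list[list[MappingHit]]:
    """Group hits on the same contig+strand within `merge_dist` nt."""
    by_key: dict[tuple[str, str], list[MappingHit]] = defaultdict(list)
    for h in hits:
        by_key[(h.contig, h.strand)].append(h)
    loci = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda h: h.start)
        cur = [group[0]]
        for h in group[1:]:
            if h.start - cur[-1].end <= merge_dist:
                cur.append(h)
            else:
                loci.append(cur)
                cur = [h]
        loci.append(cur)
    return loci


def novel_from_loci(
    unannotated: list[AnnotationResult],
    hits_by_read: dict[str, list[MappingHit]],
    contigs: dict[str, str],
    filter_cfg: NovelFilterConfig | None = None,
) -> list[MiRNACandidate]:
    """Novel miRNA candidates from unannotated genome-mapped read loci.

    The most abundant read of each locus is the putative mature; loci
    below the support threshold are not folded.  Both excision windows
    are tried and the better-scoring valid one kept.
    """
    cfg = filter_cfg or NovelFilterConfig()
    counts = {r.read_id: r.count for r in unannotated if r.category == "unannotated"}
    seqs = {r.read_id: r.sequence for r in unannotated}
    rel_hits = [h for r in unannotated if r.category == "unannotated"
                for h in hits_by_read.get(r.read_id, ())]
    candidates = []
    lo, hi = MATURE_LEN_RANGE
    for locus in cluster_loci(rel_hits, cfg.locus_merge_dist):
        # in a dense library a merged locus may chain several expressed
        # hairpins; every well-supported read that dominates its own
        # neighbourhood (no better-supported read within 60 nt) seeds a
        # precursor excision, so "most abundant read = mature" holds
        # locally around each candidate hairpin
        seeds = [h for h in locus
                 if counts.get(h.read_id, 0) >= cfg.min_locus_support]
        seeds.sort(key=lambda h: (-counts.get(h.read_id, 0), h.start))
        for top in seeds:
            top_count = counts[top.read_id]
            if any(counts.get(o.read_id, 0) > top_count
                   and o.start - 60 <= top.start and top.end <= o.end + 60
                   for o in locus):
                continue
            m_len = top.end - top.start
            if not (lo <= m_len <= hi):
                continue
            contig = contigs[top.contig]
            strand_seq = contig if top.strand == "+" else revcomp(contig)
            m_start = top.start if top.strand == "+" else len(contig) - top.end
            best = None
            for a, b in _excise_windows(strand_seq, m_start, m_len, cfg):
                span = (m_start - a, m_start - a + m_len)
                fr = fold(strand_seq[a:b], enclose=span)
                ok, _why = passes_novel_filters(fr, span, cfg)
                if ok:
                    best = (fr, (a, b))
                    break
            if best is None:
                continue
            fr, (a, b) = best
            wa, wb = ((a, b) if top.strand == "+"
                      else (len(contig) - b, len(contig) - a))
            near = [h for h in locus if h.start >= wa - 10 and h.end <= wb + 10]
            cand = MiRNACandidate(
                id="", mature=seqs[top.read_id], precursor=fr.sequence,
                fold_result=fr, source="novel",
                total_reads=sum(counts.get(h.read_id, 0) for h in near),
                unique_reads=len({h.read_id for h in near}),
                locus=(top.contig, a, b, top.strand),
            )
            cand.validate()
            candidates.append(cand)
    # a hairpin locus yields mirror calls on both strands (the mature also
    # matches the reverse complement of the star arm); merge by mature
    merged: dict[str, MiRNACandidate] = {}
    for cand in candidates:
        prev = merged.get(cand.mature)
        if prev is None:
            merged[cand.mature] = cand
        else:
            keep, drop = ((cand, prev)
                          if cand.fold_result.mfe < prev.fold_result.mfe
                          else (prev, cand))
            keep.total_reads = max(keep.total_reads, drop.total_reads)
            keep.unique_reads = max(keep.unique_reads, drop.unique_reads)
            merged[cand.mature] = keep
    out = []
    for n, cand in enumerate(merged.values()):
        cand.id = f"ppu-miR-n{n + 1}"
        out.append(cand)
    return out


def composition_stats(candidates: list[MiRNACandidate]):
    """Per-position base composition, first-base bias, length histogram.

    Returns (position_matrix, first_base, length_hist) where
    position_matrix is a {position (1-based): {base: fraction}} over the
    positions covered by at least one mature, first_base a {base:
    fraction} vector, and length_hist a {length: fraction} map.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    matures = [c.mature for c in candidates]
    max_len = max(len(m) for m in matures)
    pos_counts = np.zeros((max_len, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate("ACGU")}
    first = np.zeros(4)
    lengths: dict[int, int] = defaultdict(int)
    for m in matures:
        lengths[len(m)] += 1
        first[base_idx[m[0]]] += 1
        for p, b in enumerate(m):
            pos_counts[p, base_idx[b]] += 1
    pos_matrix = {}
    for p in range(max_len):
        tot = pos_counts[p].sum()
        pos_matrix[p + 1] = {b: pos_counts[p, i] / tot for b, i in base_idx.items()}
    n = len(matures)
    first_base = {b: first[i] / n for b, i in base_idx.items()}
    length_hist = {ln: c / n for ln, c in sorted(lengths.items())}
    return pos_matrix, first_base, length_hist
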