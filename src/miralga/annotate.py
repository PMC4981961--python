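"""ncRNA annotation cascade for collapsed small-RNA reads.

Reads are classified by similarity search against reference sets in a
fixed priority order — rRNA > tRNA > snRNA > snoRNA > known miRNA — and
whatever matches nothing is left unannotated (the input pool for novel
miRNA prediction).  The aligner finds the full query inside a reference
with separate mismatch and gap budgets (the homology criterion used for
known-miRNA assignment is "two mismatches and three gaps").

edlib provides a fast edit-distance prescreen over concatenated
references; every candidate is then re-aligned with an exact layered
dynamic program that tracks mismatches and gaps separately, since a
combined edit distance cannot enforce the two budgets independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import edlib

from .io import revcomp
from .qc import UniqueRead

__all__ = ["Alignment", "AnnotationResult", "align_banded", "best_hit",
           "annotate_cascade", "CASCADE_ORDER"]

CASCADE_ORDER = ("rRNA", "tRNA", "snRNA", "snoRNA", "known_miRNA")


@dataclass(frozen=True)
class Alignment:
    ref_id: str
    start: int  # on the reference
    end: int
    mismatches: int
    gaps: int
    strand: str = "+"

    @property
    def cost(self) -> int:
        return self.mismatches + self.gaps


@dataclass
class AnnotationResult:
    read_id: str
    sequence: str
    count: int
    category: str  # rRNA | tRNA | snRNA | snoRNA | known_miRNA | unannotated
    hit: Alignment | None = None


def _budget_dp(query: str, ref: str, max_mm: int, max_gap: int) -> tuple[int, int, int] | None:
    """Best placement of the whole query inside ref under both budgets.

    Layered DP over the gap count: D[g][i][j] = minimum mismatches
    aligning query[:i] ending at ref position j using exactly g gaps
    (insertions+deletions).  Returns (mismatches, gaps, end_position) of
    the minimum-cost compliant alignment, earliest end on ties, or None.
    """
    m, n = len(query), len(ref)
    INF = 10 ** 6
    # D[g][i] is a list over j (0..n); free leading gap on the reference
    prev_g: list[list[int]] = []
    for g in range(max_gap + 1):
        D = [[INF] * (n + 1) for _ in range(m + 1)]
        for j in range(n + 1):
            D[0][j] = 0 if g == 0 else INF
        for i in range(1, m + 1):
            qi = query[i - 1]
            row, above = D[i], D[i - 1]
            for j in range(0, n + 1):
                best = INF
                if j:
                    sub = above[j - 1] + (0 if ref[j - 1] == qi else 1)
                    if sub < best:
                        best = sub
                if g:
                    ins = prev_g[g - 1][i - 1][j]  # query base unaligned (gap in ref)
                    if ins < best:
                        best = ins
                    if j:
                        dele = prev_g[g - 1][i][j - 1]  # ref base skipped (gap in query)
                        if dele < best:
                            best = dele
                row[j] = best
        prev_g.append(D)
    best: tuple[int, int, int] | None = None
    for g in range(max_gap + 1):
        lastrow = prev_g[g][m]
        for j in range(n + 1):
            mm = lastrow[j]
            if mm <= max_mm:
                cand = (mm + g, mm, g, j)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    return best[1], best[2], best[3]


def align_banded(
    query: str,
    references: dict[str, str],
    max_mismatch: int = 2,
    max_gap: int = 3,
    search_revcomp: bool = True,
    max_cost: int | None = None,
) -> Alignment | None:
    """Minimum-cost placement of `query` inside any reference.

    Accepts only alignments with mismatches <= max_mismatch AND gaps <=
    max_gap (unit costs); `max_cost` optionally caps mismatches+gaps
    jointly (the EST homology criterion).  Ties break deterministically
    by (reference id, position).  Returns None when no reference admits
    such a placement.
    """
    if not query:
        raise ValueError("empty query")
    if max_mismatch < 0 or max_gap < 0:
        raise ValueError("budgets must be >= 0")
    k = max_mismatch + max_gap if max_cost is None else max_cost
    best: tuple[tuple, Alignment] | None = None
    for strand, q in (("+", query), ("-", revcomp(query))) if search_revcomp else (("+", query),):
        for rid in sorted(references):
            ref = references[rid]
            pre = edlib.align(q, ref, mode="HW", k=k)
            if pre["editDistance"] < 0:
                continue
            res = _budget_dp(q, ref, max_mismatch, max_gap)
            if res is None:
                continue
            mm, gaps, end = res
            if max_cost is not None and mm + gaps > max_cost:
                continue
            # ref span is len(q) +/- the gap split; start is exact for
            # ungapped placements and within `gaps` otherwise
            start = max(0, end - len(q))
            aln = Alignment(rid, start, end, mm, gaps, strand)
            key = (aln.cost, rid, start, strand)
            if best is None or key < best[0]:
                best = (key, aln)
    return best[1] if best else None


def best_hit(query: str, references: dict[str, str],
             max_mismatch: int = 2, max_gap: int = 3) -> Alignment | None:
    return align_banded(query, references, max_mismatch, max_gap)


class WordIndex:
    """Exact-word prescreen over a reference set, BLASTn style.

    A query is only aligned against references sharing an exact word
    (default 11 nt, the BLASTn default); reads that genuinely derive
    from a reference always share one, while chance agreement of a
    random ~21-mer is rare.  Both strands are indexed.
    """

    def __init__(self, references: dict[str, str], word: int = 11):
        self.references = references
        self.word = word
        self._index: dict[str, set[str]] = {}
        for rid, seq in references.items():
            for s in (seq, revcomp(seq)):
                for i in range(len(s) - word + 1):
                    self._index.setdefault(s[i : i + word], set()).add(rid)

    def candidates(self, query: str) -> dict[str, str]:
        w = self.word
        hits: set[str] = set()
        for i in range(len(query) - w + 1):
            hits |= self._index.get(query[i : i + w], set())
        return {rid: self.references[rid] for rid in hits}

    def best_hit(self, query: str, max_mismatch: int = 2,
                 max_gap: int = 3) -> Alignment | None:
        cands = self.candidates(query)
        if not cands:
            return None
        return align_banded(query, cands, max_mismatch, max_gap)


def annotate_cascade(
    unique: Iterable[UniqueRead],
    reference_sets: dict[str, dict[str, str]],
    mirna_db: dict[str, str],
    max_mismatch: int = 2,
    max_gap: int = 3,
    seed_word: int = 11,
) -> tuple[list[AnnotationResult], dict[str, dict[str, int]]]:
    """Assign each unique read to its first matching category.

    Parameters
    ----------
    reference_sets
        {"rRNA": {...}, "tRNA": {...}, "snRNA": {...}, "snoRNA": {...}};
        missing classes are treated as empty.
    mirna_db
        Mature + precursor miRNA reference sequences.

    Returns
    -------
    (per-read results, summary) where summary maps category ->
    {"unique": n, "total": count-weighted n}.  Categories partition the
    input: unique and total counts sum to the input totals.  Candidate
    references are prescreened with an exact shared word (`seed_word`
    nt) before the budgeted alignment, as a word-seeded BLASTn search
    would.
    """
    indexes = {}
    for cls in CASCADE_ORDER:
        refs = mirna_db if cls == "known_miRNA" else reference_sets.get(cls, {})
        if refs:
            indexes[cls] = WordIndex(refs, seed_word)
    results: list[AnnotationResult] = []
    summary = {c: {"unique": 0, "total": 0} for c in CASCADE_ORDER + ("unannotated",)}
    for k, u in enumerate(unique):
        rid = f"u{k + 1}_x{u.count}"
        category, hit = "unannotated", None
        for cls in CASCADE_ORDER:
            if cls not in indexes:
                continue
            aln = indexes[cls].best_hit(u.sequence, max_mismatch, max_gap)
            if aln is not None:
                category, hit = cls, aln
                break
        results.append(AnnotationResult(rid, u.sequence, u.count, category, hit))
        summary[category]["unique"] += 1
        summary[category]["total"] += u.count
    return results, summary
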