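"""Exact mapping of collapsed reads to genome contigs.

A read is mapped when it has at least one perfect full-length match on
either strand.  Contigs are indexed with 12-mers; read lengths of 18 nt
and up guarantee a seed hit, so exactness is preserved.  Coordinates are
0-based half-open internally; reports print 1-based.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .io import revcomp
from .qc import UniqueRead

__all__ = ["MappingHit", "MappingSummary", "GenomeIndex", "map_reads",
           "positional_distribution"]

SEED_LEN = 12


@dataclass(frozen=True)
class MappingHit:
    read_id: str
    contig: str
    start: int
    end: int  # exclusive
    strand: str  # "+" | "-"


@dataclass
class MappingSummary:
    unique_total: int = 0
    unique_mapped: int = 0
    reads_total: int = 0
    reads_mapped: int = 0
    skipped_bad_symbols: int = 0

    @property
    def unique_pct(self) -> float:
        return round(100.0 * self.unique_mapped / self.unique_total, 2) if self.unique_total else 0.0

    @property
    def reads_pct(self) -> float:
        return round(100.0 * self.reads_mapped / self.reads_total, 2) if self.reads_total else 0.0


class GenomeIndex:
    """12-mer index over a contig set for exact full-length lookup."""

    def __init__(self, contigs: dict[str, str]):
        if not contigs:
            raise ValueError("contigs must be non-empty")
        self.contigs = contigs
        self._idx: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for cid, seq in contigs.items():
            for i in range(len(seq) - SEED_LEN + 1):
                self._idx[seq[i : i + SEED_LEN]].append((cid, i))

    def find(self, query: str, max_hits: int = 50) -> list[tuple[str, int]]:
        """All exact occurrence loci of `query` on the + strand of contigs."""
        if len(query) < SEED_LEN:
            out = []
            for cid, seq in self.contigs.items():
                p = seq.find(query)
                while p >= 0 and len(out) < max_hits:
                    out.append((cid, p))
                    p = seq.find(query, p + 1)
            return out
        hits = []
        for cid, i in self._idx.get(query[:SEED_LEN], ()):
            if self.contigs[cid][i : i + len(query)] == query:
                hits.append((cid, i))
                if len(hits) >= max_hits:
                    break
        return hits


def map_reads(
    unique: list[UniqueRead],
    contigs: dict[str, str] | GenomeIndex,
    max_hits_per_read: int = 50,
) -> tuple[list[MappingHit], MappingSummary]:
    """Map unique reads to contigs by perfect full-length matching.

    Returns all hits (up to `max_hits_per_read` per read) and a summary
    with unique- and count-weighted mapped fractions.  Reads containing
    non-ACGU symbols are skipped and tallied.
    """
    index = contigs if isinstance(contigs, GenomeIndex) else GenomeIndex(contigs)
    hits: list[MappingHit] = []
    summary = MappingSummary(unique_total=len(unique),
                             reads_total=sum(u.count for u in unique))
    alphabet = set("ACGU")
    for k, u in enumerate(unique):
        if set(u.sequence) - alphabet:
            summary.skipped_bad_symbols += 1
            continue
        rid = f"u{k + 1}_x{u.count}"
        found = False
        for cid, i in index.find(u.sequence, max_hits_per_read):
            hits.append(MappingHit(rid, cid, i, i + len(u.sequence), "+"))
            found = True
        rc = revcomp(u.sequence)
        for cid, i in index.find(rc, max_hits_per_read):
            hits.append(MappingHit(rid, cid, i, i + len(u.sequence), "-"))
            found = True
        if found:
            summary.unique_mapped += 1
            summary.reads_mapped += u.count
    return hits, summary


def positional_distribution(
    hits: list[MappingHit], contigs: dict[str, str], bin_size: int = 1000
) -> dict[str, list[int]]:
    """Per-contig binned hit counts (each hit tallied by its start bin)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    out = {cid: [0] * ((len(seq) + bin_size - 1) // bin_size or 1)
           for cid, seq in contigs.items()}
    for h in hits:
        out[h.contig][h.start // bin_size] += 1
    return out
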