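"""Raw-read cleaning, contaminant accounting and read collapsing.

Each raw read passes a fixed cascade of filters in the order the summary
table reports them: quality -> 3'-adapter absent -> empty insert ->
5'-adapter contaminant -> insert shorter than the minimum -> poly(A) ->
clean.  A read receives exactly the first label whose test fires, so a
read that is simultaneously short and poly(A) is counted as short.
Percentages are reported against the high-quality read count, as in the
library summary table.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .synthio import ADAPTER_3P, ADAPTER_5P

__all__ = [
    "QCReport",
    "UniqueRead",
    "clean_reads",
    "collapse_unique",
    "length_distribution",
    "REMOVAL_CATEGORIES",
]

REMOVAL_CATEGORIES = (
    "adapter3_null",
    "insert_null",
    "adapter5_contaminant",
    "short_lt18",
    "polyA",
)


@dataclass
class QCReport:
    total_reads: int = 0
    high_quality: int = 0
    removed: dict = field(default_factory=lambda: {c: 0 for c in REMOVAL_CATEGORIES})
    clean_reads: int = 0

    @property
    def percentages(self) -> dict[str, float]:
        """Per-category share of high-quality reads, rounded to 2 decimals."""
        hq = self.high_quality
        out = {"high_quality": 100.0 if hq else 0.0}
        for cat, n in self.removed.items():
            out[cat] = round(100.0 * n / hq, 2) if hq else 0.0
        out["clean_reads"] = round(100.0 * self.clean_reads / hq, 2) if hq else 0.0
        return out

    def validate(self) -> None:
        if self.high_quality - sum(self.removed.values()) != self.clean_reads:
            raise ValueError("QC accounting broken: high_quality - removed != clean")
        if min([self.total_reads, self.high_quality, self.clean_reads]
               + list(self.removed.values())) < 0:
            raise ValueError("negative QC count")

    def rows(self) -> list[tuple[str, int, str]]:
        """(Type, Reads, Percent) rows mirroring the library summary table."""
        pct = self.percentages
        rows = [("Total reads", self.total_reads, ""),
                ("High quality", self.high_quality, "100 %")]
        label = {
            "adapter3_null": "3'adapter null",
            "insert_null": "Insert null",
            "adapter5_contaminant": "5'adapter contaminants",
            "short_lt18": "Smaller than 18 nt",
            "polyA": "PolyA",
        }
        for cat in REMOVAL_CATEGORIES:
            rows.append((label[cat], self.removed[cat], f"{pct[cat]:.2f} %"))
        if "oversize" in self.removed:
            rows.append(("Oversize insertion", self.removed["oversize"],
                         f"{pct['oversize']:.2f} %"))
        rows.append(("Clean reads", self.clean_reads, f"{pct['clean_reads']:.2f} %"))
        return rows


@dataclass(frozen=True)
class UniqueRead:
    sequence: str
    count: int


def tabulate_report(high_quality: int, removed: dict[str, int],
                    total_reads: int | None = None) -> QCReport:
    """Build the accounting report directly from per-category counts.

    Clean reads are whatever the removals leave: clean = high_quality -
    sum(removed).  Used both by :func:`clean_reads` and to recompute the
    published table arithmetic from its printed cells.
    """
    rep = QCReport(
        total_reads=high_quality if total_reads is None else total_reads,
        high_quality=high_quality,
        removed={c: int(removed.get(c, 0)) for c in REMOVAL_CATEGORIES},
    )
    rep.clean_reads = high_quality - sum(rep.removed.values())
    rep.validate()
    return rep


def _mean_phred(qual: str) -> float:
    return sum(ord(c) - 33 for c in qual) / len(qual) if qual else 0.0


def label_read(seq: str, adapter5: str, adapter3: str,
               min_len: int = 18, max_len: int | None = 43) -> tuple[str, str]:
    """(label, insert) for one high-quality read.

    The 5' adapter is stripped when it prefixes the read; the insert is
    the region up to the first 3' adapter occurrence.  Labels follow the
    cascade order documented in the module docstring.
    """
    body = seq[len(adapter5):] if seq.startswith(adapter5) else seq
    cut = body.find(adapter3)
    if cut < 0:
        return "adapter3_null", ""
    insert = body[:cut]
    if not insert:
        return "insert_null", ""
    if adapter5 in insert:
        return "adapter5_contaminant", insert
    if len(insert) < min_len:
        return "short_lt18", insert
    if insert.count("A") / len(insert) >= 0.9:
        return "polyA", insert
    if max_len is not None and len(insert) > max_len:
        return "oversize", insert
    return "clean", insert


def clean_reads(
    raw: list[tuple[str, str, str]],
    adapter5: str = ADAPTER_5P,
    adapter3: str = ADAPTER_3P,
    min_len: int = 18,
    min_qual: float = 20.0,
    max_len: int | None = 43,
) -> tuple[list[UniqueRead], list[str], QCReport]:
    """Filter raw reads and collapse the survivors.

    Parameters
    ----------
    raw
        (id, sequence, quality) triples as returned by ``io.read_fastq``.
    min_qual
        Mean-Phred threshold defining a high-quality read (default 20).
    max_len
        Optional oversize-insert cutoff (default 43 nt, the upper bound of
        the observed length range); oversize removals are folded into the
        short/poly(A)-style accounting only if they occur.

    Returns
    -------
    (unique clean reads, per-read labels, QCReport)
    """
    if not adapter5 or not adapter3:
        raise ValueError("adapters must be non-empty")
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    rep = QCReport(total_reads=len(raw))
    rep.removed = {c: 0 for c in REMOVAL_CATEGORIES}
    labels: list[str] = []
    inserts: list[str] = []
    for idx, rec in enumerate(raw):
        try:
            _, seq, qual = rec
            if not seq or len(qual) != len(seq):
                raise ValueError
        except (ValueError, TypeError):
            raise ValueError(f"malformed FASTQ record at index {idx}") from None
        if _mean_phred(qual) < min_qual:
            labels.append("low_quality")
            continue
        rep.high_quality += 1
        label, insert = label_read(seq, adapter5, adapter3, min_len, max_len)
        if label == "oversize":  # optional max-length filter, own bucket
            rep.removed.setdefault("oversize", 0)
        labels.append(label)
        if label == "clean":
            rep.clean_reads += 1
            inserts.append(insert)
        else:
            rep.removed[label] += 1
    rep.validate()
    return collapse_unique(inserts), labels, rep


def collapse_unique(reads: list[str]) -> list[UniqueRead]:
    """Collapse identical sequences, most abundant first.

    The sum of counts equals the number of input reads; ties are ordered
    by sequence for determinism.
    """
    counts = Counter(reads)
    return [UniqueRead(s, c) for s, c in
            sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]


def redundancy_ratio(total: int, unique: int) -> float:
    """Reads per unique sequence, one decimal (e.g. 6.6)."""
    if unique <= 0:
        raise ValueError("unique count must be > 0")
    return round(total / unique, 1)


def length_distribution(unique: list[UniqueRead], weighted: bool = True) -> dict[int, float]:
    """Fraction of reads (count-weighted) or sequences per length."""
    if not unique:
        raise ValueError("empty read set")
    acc: Counter = Counter()
    for u in unique:
        acc[len(u.sequence)] += u.count if weighted else 1
    total = sum(acc.values())
    return {ln: n / total for ln, n in sorted(acc.items())}
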