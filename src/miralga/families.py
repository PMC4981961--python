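"""miRNA family clustering and cross-species conservation counts.

Two matures belong to the same family when their global alignment shows
at least 98 % identity AND at most one mismatch ("fewer than two"); gaps
count against identity.  Families are the connected components of that
relation (single linkage), so the partition is order-invariant.  A family
inherits the name of its best known-family hit and is `conserved` when
any member came from a homology route, `species_specific` otherwise.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field

import edlib

from .discover import MiRNACandidate

__all__ = ["Family", "linked", "cluster_families", "family_size_table",
           "conservation_matrix", "family_name_of"]


@dataclass
class Family:
    family_id: str
    members: list = field(default_factory=list)  # candidate ids
    type: str = "species_specific"  # or "conserved"
    name: str = ""


def _alignment_stats(a: str, b: str) -> tuple[int, int, int]:
    """(matches, mismatches, gaps) of the global (NW) alignment of a, b."""
    res = edlib.align(a, b, mode="NW", task="path")
    mm = gaps = match = 0
    for n, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        n = int(n)
        if op == "=":
            match += n
        elif op == "X":
            mm += n
        else:
            gaps += n
    return match, mm, gaps


def linked(a: str, b: str, min_identity: float = 0.98, max_mismatch: int = 1) -> bool:
    """Family linkage rule: identity >= 98 % over the global alignment
    (gaps count against identity) and at most `max_mismatch` substitutions."""
    match, mm, gaps = _alignment_stats(a, b)
    cols = match + mm + gaps
    return cols > 0 and (match / cols) >= min_identity and mm <= max_mismatch


def family_name_of(db_hit_id: str) -> str:
    """Strip the species prefix and allele suffix: 'osa-miR156a-5p' -> 'miR156'."""
    m = re.search(r"(miR\d+)", db_hit_id)
    return m.group(1) if m else db_hit_id


def cluster_families(
    candidates: list[MiRNACandidate],
    min_identity: float = 0.98,
    max_mismatch: int = 1,
) -> list[Family]:
    """Single-linkage clustering of candidate matures into families."""
    n = len(candidates)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if linked(candidates[i].mature, candidates[j].mature,
                      min_identity, max_mismatch):
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)
    families = []
    # deterministic ordering: by smallest member candidate id
    for root in sorted(groups, key=lambda r: min(candidates[i].id for i in groups[r])):
        idxs = groups[root]
        members = sorted(candidates[i].id for i in idxs)
        hits = sorted({family_name_of(candidates[i].homolog_family)
                       for i in idxs if candidates[i].homolog_family})
        conserved = any(candidates[i].source in ("reads_known", "est_homolog")
                        for i in idxs)
        families.append(Family(
            family_id=f"fam{len(families) + 1}",
            members=members,
            type="conserved" if conserved else "species_specific",
            name=hits[0] if hits else members[0],
        ))
    total = sum(len(f.members) for f in families)
    assert total == n, "families must partition the candidate set"
    return families


def family_size_table(families: list[Family]) -> dict:
    """Size-distribution summary: per size, family counts split by type.

    Returns {"by_size": {size: {"n": .., "conserved_pct": .., "novel_pct": ..}},
    "n_families": .., "n_members": .., "singleton_pct": ..}; percentages
    are of all families, rounded to 2 decimals.
    """
    by_size: dict[int, dict[str, float]] = {}
    n_fam = len(families)
    for size in sorted({len(f.members) for f in families}):
        of_size = [f for f in families if len(f.members) == size]
        cons = sum(1 for f in of_size if f.type == "conserved")
        by_size[size] = {
            "n": len(of_size),
            "conserved_pct": round(100.0 * cons / n_fam, 2) if n_fam else 0.0,
            "novel_pct": round(100.0 * (len(of_size) - cons) / n_fam, 2) if n_fam else 0.0,
        }
    singles = by_size.get(1, {}).get("n", 0)
    return {
        "by_size": by_size,
        "n_families": n_fam,
        "n_members": sum(len(f.members) for f in families),
        "singleton_pct": round(100.0 * singles / n_fam, 2) if n_fam else 0.0,
    }


def conservation_matrix(
    families: list[Family],
    species_counts: dict[tuple[str, str], int],
    species: list[str] | None = None,
) -> tuple[list[str], list[str], list[list[int]]]:
    """Family x species member-count matrix.

    `species_counts` maps (species, family name) -> member count in that
    species (e.g. parsed from a multi-species mature database).  Cells
    default to zero; a species with no entry for a family still appears
    as a zero column when listed in `species` (default: every species
    seen in the counts).  Returns (family names, species, matrix).
    """
    if species is None:
        species = sorted({sp for sp, _ in species_counts})
    else:
        species = sorted(species)
    fam_names = [f.name for f in families]
    matrix = [[species_counts.get((sp, name), 0) for sp in species]
              for name in fam_names]
    return fam_names, species, matrix


def species_family_counts(mature_db: dict[str, str]) -> dict[tuple[str, str], int]:
    """Count db matures per (species prefix, family name)."""
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for mid in mature_db:
        if "-" not in mid:
            continue
        sp = mid.split("-", 1)[0]
        counts[(sp, family_name_of(mid))] += 1
    return dict(counts)
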