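"""Single-stem RNA secondary-structure prediction.

Hairpin precursors of plant miRNAs are, to first order, one long stem
interrupted by bulges and internal loops and closed by a terminal loop.
This module ships a self-contained nearest-neighbor energy model restricted
to that shape (no multiloops) and an interval dynamic program that finds
the minimum free energy (MFE) structure under it.  All downstream filters
(hairpin count, overhangs, bulge sizes, the −18 kcal/mol cutoff) consume
only the (dot-bracket, MFE) pair, so any external folding engine returning
that pair can be plugged in instead.

Energies are handled internally as integers in deci-kcal/mol so that the
dynamic program and the exhaustive test oracle agree exactly, with no
floating-point ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "FoldResult",
    "DuplexResult",
    "fold",
    "duplex_metrics",
    "structure_metrics",
    "pair_table",
    "PAIR_INDEX",
    "STACK",
    "hairpin_penalty",
    "interior_penalty",
    "MIN_HAIRPIN_LOOP",
    "MAX_INTERIOR_SIDE",
]

# Allowed pairs: Watson-Crick plus G:U wobble.
PAIR_INDEX: dict[tuple[str, str], int] = {
    ("C", "G"): 0,
    ("G", "C"): 1,
    ("A", "U"): 2,
    ("U", "A"): 3,
    ("G", "U"): 4,
    ("U", "G"): 5,
}

# Stacking free energies in deci-kcal/mol, STACK[p][q] for pair p = (i, j)
# stacked on pair q = (i+1, j-1).  Simplified Turner-like values; shipped as
# versioned model data (model version 1).
STACK: tuple[tuple[int, ...], ...] = (
    # on:   CG    GC    AU    UA    GU    UG
    (-33, -24, -21, -21, -14, -21),  # CG
    (-34, -33, -24, -22, -15, -25),  # GC
    (-22, -21, -9, -11, -6, -14),  # AU
    (-24, -21, -13, -9, -10, -13),  # UA
    (-25, -21, -13, -14, -5, -5),  # GU
    (-15, -14, -10, -6, -3, -5),  # UG
)

MIN_HAIRPIN_LOOP = 3
#: largest number of unpaired bases tolerated on one side of an interior
#: loop or bulge within the model (loops beyond this are never formed)
MAX_INTERIOR_SIDE = 10

ENERGY_MODEL_VERSION = 1


def hairpin_penalty(loop_size: int) -> int:
    """Destabilising penalty (deci-kcal/mol) for a terminal loop."""
    if loop_size < MIN_HAIRPIN_LOOP:
        raise ValueError(f"hairpin loop must be >= {MIN_HAIRPIN_LOOP} nt")
    return 54 + round(17.5 * math.log(loop_size / 3.0))


def interior_penalty(l1: int, l2: int) -> int:
    """Penalty for a bulge (one side 0) or internal loop between two pairs.

    No stacking bonus is granted across an interrupted helix.
    """
    total = l1 + l2
    if total <= 0:
        raise ValueError("interior loop must have unpaired bases")
    if l1 == 0 or l2 == 0:  # bulge
        return 38 + (round(17.5 * math.log(total)) if total > 1 else 0)
    return 17 + max(0, round(17.5 * math.log(total / 2.0)))


def _pair_idx(a: str, b: str) -> int:
    return PAIR_INDEX.get((a, b), -1)


@dataclass
class FoldResult:
    sequence: str
    structure: str  # dot-bracket
    mfe: float  # kcal/mol
    n_hairpin_loops: int = 0
    terminal_loop_size: int = 0
    bulge_sizes_5p: list[int] = field(default_factory=list)
    bulge_sizes_3p: list[int] = field(default_factory=list)
    max_bulge_or_loop_per_strand: int = 0
    paired_fraction: float = 0.0
    n_pairs: int = 0


@dataclass
class DuplexResult:
    mature_span: tuple[int, int]  # paired extent of the mature, [start, end)
    star_span: tuple[int, int]
    overhang_5p: int
    overhang_3p: int
    max_bulge_or_loop_mature: int
    max_bulge_or_loop_star: int
    duplex_mfe: float


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 unpaired) for a dot-bracket string."""
    stack: list[int] = []
    table = [-1] * len(structure)
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            j = stack.pop()
            table[i] = j
            table[j] = i
        elif c != ".":
            raise ValueError(f"bad dot-bracket symbol {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return table


def structure_metrics(sequence: str, structure: str, mfe: float) -> FoldResult:
    """Recompute every hairpin metric from the dot-bracket alone.

    Works for any balanced non-crossing structure, including ones produced
    by external engines (which may contain multiloops).
    """
    table = pair_table(structure)
    n = len(structure)
    pairs = [(i, table[i]) for i in range(n) if table[i] > i]
    res = FoldResult(sequence=sequence, structure=structure, mfe=mfe)
    res.n_pairs = len(pairs)
    res.paired_fraction = (2 * len(pairs) / n) if n else 0.0
    # hairpin loops: pairs with no pair nested inside
    loop_sizes = []
    for i, j in pairs:
        if all(table[k] == -1 for k in range(i + 1, j)):
            loop_sizes.append(j - i - 1)
    res.n_hairpin_loops = len(loop_sizes)
    res.terminal_loop_size = loop_sizes[0] if loop_sizes else 0
    # walk each helix chain outermost->innermost collecting interruptions
    inner_of = {}
    for i, j in pairs:
        # nearest enclosed pair
        for k in range(i + 1, j):
            if table[k] > k:
                inner_of[(i, j)] = (k, table[k])
                break
    enclosed = set(inner_of.values())
    b5, b3 = [], []
    for outer in pairs:
        if outer in enclosed:
            continue
        cur = outer
        while cur in inner_of:
            nxt = inner_of[cur]
            l1 = nxt[0] - cur[0] - 1
            l2 = cur[1] - nxt[1] - 1
            if l1:
                b5.append(l1)
            if l2:
                b3.append(l2)
            cur = nxt
    res.bulge_sizes_5p = b5
    res.bulge_sizes_3p = b3
    res.max_bulge_or_loop_per_strand = max(b5 + b3, default=0)
    return res


def _fold_dp(seq: str, enclose: tuple[int, int] | None = None) -> tuple[int, list[tuple[int, int]]]:
    """Minimum-energy single stem.  Returns (energy deci-kcal, pair list).

    V[(i, j)] = best energy of a stem closed on the outside by pair (i, j).
    Transitions either close a hairpin loop or stack/loop onto an inner
    pair with at most MAX_INTERIOR_SIDE unpaired bases per side.  Ties are
    broken toward more pairs, then the 5'-most outer pair.  When `enclose`
    is given, the outer pair must bracket that interval (the stem must
    contain it), which is how a precursor is excised around a read.
    """
    n = len(seq)
    pairable = [
        (i, j)
        for i in range(n)
        for j in range(i + MIN_HAIRPIN_LOOP + 1, n)
        if _pair_idx(seq[i], seq[j]) >= 0
    ]
    by_i: dict[int, list[int]] = {}
    for i, j in pairable:
        by_i.setdefault(i, []).append(j)
    # V keyed by (i, j): (energy, -npairs, inner pair or None)
    V: dict[tuple[int, int], tuple[int, int, tuple[int, int] | None]] = {}
    for i, j in sorted(pairable, key=lambda p: p[1] - p[0]):
        pi = _pair_idx(seq[i], seq[j])
        hairpin_sentinel = (n, n)  # sorts after any real inner pair
        best: tuple[int, int, tuple[int, int]] | None = None
        if j - i - 1 >= MIN_HAIRPIN_LOOP:
            best = (hairpin_penalty(j - i - 1), -1, hairpin_sentinel)
        for i2 in range(i + 1, min(i + MAX_INTERIOR_SIDE + 2, j)):
            for j2 in by_i.get(i2, ()):
                if j2 >= j:
                    break
                l2 = j - j2 - 1
                if l2 > MAX_INTERIOR_SIDE:
                    continue
                sub = V.get((i2, j2))
                if sub is None:
                    continue
                l1 = i2 - i - 1
                if l1 == 0 and l2 == 0:
                    e = STACK[pi][_pair_idx(seq[i2], seq[j2])]
                else:
                    e = interior_penalty(l1, l2)
                cand = (sub[0] + e, sub[1] - 1, (i2, j2))
                if best is None or cand < best:
                    best = cand
        if best is not None:
            V[(i, j)] = best
    # global best over outer pairs; open chain (energy 0) is the fallback
    best_outer = None
    best_key = (0, 0, n, n)
    for (i, j), (e, negp, _) in V.items():
        if enclose is not None and not (i <= enclose[0] and j >= enclose[1] - 1):
            continue
        key = (e, negp, i, j)
        if key < best_key:
            best_key = key
            best_outer = (i, j)
    if best_outer is None:
        return 0, []
    pairs = []
    cur = best_outer
    while True:
        pairs.append(cur)
        nxt = V[cur][2]
        if nxt == (n, n):
            break
        cur = nxt
    return best_key[0], pairs


def fold(sequence: str, engine=None,
         enclose: tuple[int, int] | None = None) -> FoldResult:
    """Fold one sequence and return structure, MFE and hairpin metrics.

    Parameters
    ----------
    sequence
        RNA sequence, 8–600 nt over ACGU (T is accepted and read as U).
    engine
        Optional external engine ``f(seq) -> (dot_bracket, mfe_kcal)``;
        when given, metrics are computed from its output instead of the
        built-in model.
    enclose
        Optional [start, end) interval the stem must contain — used when
        excising a precursor around a mature read, so the reported
        structure is the best hairpin *harbouring* the read rather than
        the globally best stem of the window.
    """
    seq = sequence.upper().replace("T", "U")
    if not seq:
        raise ValueError("empty sequence")
    if not (8 <= len(seq) <= 600):
        raise ValueError(f"sequence length {len(seq)} outside [8, 600]")
    bad = set(seq) - set("ACGU")
    if bad:
        raise ValueError(f"non-ACGU symbols: {sorted(bad)}")
    if engine is not None:
        db, mfe = engine(seq)
        return structure_metrics(seq, db, float(mfe))
    e10, pairs = _fold_dp(seq, enclose)
    db = ["."] * len(seq)
    for i, j in pairs:
        db[i] = "("
        db[j] = ")"
    return structure_metrics(seq, "".join(db), e10 / 10.0)


def duplex_metrics(fr: FoldResult, mature: tuple[int, int]) -> DuplexResult:
    """Metrics of the mature/star duplex implied by a fold.

    The star arm is whatever region pairs with the mature under the given
    structure.  Overhangs are the unpaired terminal runs of the mature
    within its own span; bulge/loop sizes are the longest unpaired runs
    inside the duplex on each strand.

    Raises
    ------
    ValueError
        If the mature interval has no paired base ("mature not in stem").
    """
    a, b = mature
    if not (0 <= a < b <= len(fr.sequence)):
        raise ValueError("mature interval outside sequence")
    table = pair_table(fr.structure)
    paired_pos = [i for i in range(a, b) if table[i] >= 0]
    if not paired_pos:
        raise ValueError("mature not in stem")
    m1, m2 = paired_pos[0], paired_pos[-1]
    partners = sorted(table[i] for i in paired_pos)
    s1, s2 = partners[0], partners[-1]
    over5 = m1 - a
    over3 = (b - 1) - m2

    def max_unpaired_run(lo: int, hi: int) -> int:
        run = best = 0
        for k in range(lo, hi + 1):
            if table[k] == -1:
                run += 1
                best = max(best, run)
            else:
                run = 0
        return best

    # duplex energy from the paired positions of the mature arm
    e10 = 0
    prev = None
    for i in paired_pos:
        j = table[i]
        pi = _pair_idx(fr.sequence[i], fr.sequence[j])
        if prev is not None and i == prev + 1 and table[prev] == j + 1:
            e10 += STACK[_pair_idx(fr.sequence[prev], fr.sequence[table[prev]])][pi]
        prev = i
    return DuplexResult(
        mature_span=(m1, m2 + 1),
        star_span=(s1, s2 + 1),
        overhang_5p=over5,
        overhang_3p=over3,
        max_bulge_or_loop_mature=max_unpaired_run(m1, m2),
        max_bulge_or_loop_star=max_unpaired_run(s1, s2),
        duplex_mfe=e10 / 10.0,
    )
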