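"""Rule-based miRNA target prediction and inhibition-mode classification.

Every transcript window the length of the miRNA is evaluated as a
gapless antiparallel duplex (miRNA position 1 = 5' end pairs the 3' end
of the site).  A window is an accepted target site when all of:

* no insertions or deletions (gapless by construction);
* total mismatch score below 3, counting a G:U wobble 0.5 and a full
  mismatch 1.0, and within the preset's cap (strict 2.0, relaxed 2.5 —
  the two stringency presets stand in for running two external
  predictors whose union is reported);
* positions 8–12 all paired (Watson–Crick or G:U);
* at most one full mismatch within positions 1–7;
* duplex free energy <= −18 kcal/mol under the package energy table.

A site is classified as translational inhibition when any position 9–11
deviates from Watson–Crick pairing (G:U or mismatch); otherwise the
site is a cleavage locus.

The scanner is vectorized over all windows of all transcripts at once;
mismatch scores are held in half-units and energies in deci-kcal/mol so
comparisons are exact.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .fold import PAIR_INDEX, STACK

__all__ = ["TargetSite", "TargetSummary", "PRESETS", "scan_targets",
           "classify_mode", "summarize_targets", "MISMATCH_PENALTY_DECI"]

PRESETS = {"strict": 2.0, "relaxed": 2.5}

#: destabilisation added per full mismatch inside the duplex (deci-kcal/mol)
MISMATCH_PENALTY_DECI = 10

_CODE = {b: i for i, b in enumerate("ACGU")}
# state lookup [mirna_base, site_base]: 0 WC, 1 GU, 2 mismatch
_STATE = np.full((5, 5), 2, dtype=np.int8)
_PTYPE = np.full((5, 5), -1, dtype=np.int8)
for (a, b), idx in PAIR_INDEX.items():
    wc = (a, b) in (("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"))
    _STATE[_CODE[a], _CODE[b]] = 0 if wc else 1
    _PTYPE[_CODE[a], _CODE[b]] = idx
_STACK_ARR = np.array(STACK, dtype=np.int32)

_STATE_CHAR = {0: "|", 1: "o", 2: "x"}


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # site interval on the transcript, 0-based half-open
    end: int
    pairing: str  # per miRNA position 1..L: '|' WC, 'o' G:U, 'x' mismatch
    score: float  # mismatch score (G:U 0.5, mismatch 1.0)
    mfe: float  # duplex energy, kcal/mol
    preset: str
    mode: str  # cleavage | translational_inhibition


@dataclass
class TargetSummary:
    rows: list  # per (class, preset) dicts
    combined_genes: dict  # class -> deduplicated gene count
    total_genes: int
    union: list  # deduplicated TargetSite union over presets


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8).copy()


def _codes(seq: str) -> np.ndarray:
    lut = np.full(256, 4, dtype=np.int8)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    return lut[_encode(seq)]


def classify_mode(pairing: str) -> str:
    """Central-region rule: any non-WC state at miRNA positions 9–11."""
    central = pairing[8:11]
    return "translational_inhibition" if set(central) - {"|"} else "cleavage"


def scan_targets(
    mirna_id: str,
    mirna_seq: str,
    transcripts: dict[str, str],
    preset: str = "strict",
    mfe_cutoff: float = -18.0,
) -> list[TargetSite]:
    """All accepted target sites of one miRNA over a transcript set."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}")
    L = len(mirna_seq)
    if not (18 <= L <= 25):
        raise ValueError("miRNA length must be 18-25 nt")
    return _scan(mirna_id, mirna_seq, transcripts, (preset,), mfe_cutoff)[preset]


def _scan(
    mirna_id: str,
    mirna_seq: str,
    transcripts: dict[str, str],
    presets: tuple[str, ...],
    mfe_cutoff: float,
) -> dict[str, list[TargetSite]]:
    L = len(mirna_seq)
    m = _codes(mirna_seq)
    # concatenate transcripts with 'N' spacers; windows crossing a spacer
    # contain code 4 and can never satisfy the paired-core rule
    ids, offsets, parts = [], [], []
    pos = 0
    for tid in transcripts:
        seq = transcripts[tid]
        if len(seq) < L:
            continue  # transcript shorter than the miRNA: skipped
        ids.append(tid)
        offsets.append(pos)
        parts.append(seq)
        pos += len(seq) + L
    out: dict[str, list[TargetSite]] = {p: [] for p in presets}
    if not ids:
        return out
    cat = ("N" * L).join(parts)
    t = _codes(cat)
    W = np.lib.stride_tricks.sliding_window_view(t, L)  # (n_windows, L)
    n = W.shape[0]
    S = np.empty((n, L), dtype=np.int8)
    P = np.empty((n, L), dtype=np.int8)
    for i in range(L):
        col = W[:, L - 1 - i]
        S[:, i] = _STATE[m[i], col]
        P[:, i] = _PTYPE[m[i], col]
    n_mm = (S == 2).sum(axis=1)
    n_gu = (S == 1).sum(axis=1)
    score2 = 2 * n_mm + n_gu  # half-units
    core_ok = (S[:, 7:12] != 2).all(axis=1)
    seed_ok = (S[:, 0:7] == 2).sum(axis=1) <= 1
    # duplex energy: stacks over adjacent paired positions + mismatch penalty
    e10 = np.zeros(n, dtype=np.int32)
    for i in range(L - 1):
        both = (P[:, i] >= 0) & (P[:, i + 1] >= 0)
        e10[both] += _STACK_ARR[P[both, i], P[both, i + 1]]
    e10 += MISMATCH_PENALTY_DECI * n_mm.astype(np.int32)
    mfe_ok = e10 <= int(round(mfe_cutoff * 10))
    base_ok = core_ok & seed_ok & mfe_ok & (score2 < 6)
    bounds = np.array(offsets + [pos])
    for preset in presets:
        cap2 = int(round(PRESETS[preset] * 2))
        acc = np.flatnonzero(base_ok & (score2 <= cap2))
        for w in acc:
            k = np.searchsorted(bounds, w, side="right") - 1
            tid = ids[k]
            start = int(w - offsets[k])
            if start + L > len(transcripts[tid]):
                continue  # spans a spacer
            pairing = "".join(_STATE_CHAR[s] for s in S[w])
            out[preset].append(TargetSite(
                mirna_id=mirna_id, transcript_id=tid, start=start,
                end=start + L, pairing=pairing, score=score2[w] / 2.0,
                mfe=e10[w] / 10.0, preset=preset, mode=classify_mode(pairing),
            ))
    return out


def scan_all(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    mfe_cutoff: float = -18.0,
) -> dict[str, list[TargetSite]]:
    """Both presets for every miRNA; returns {preset: [sites...]}."""
    out: dict[str, list[TargetSite]] = {p: [] for p in PRESETS}
    for mid in sorted(mirnas):
        res = _scan(mid, mirnas[mid], transcripts, tuple(PRESETS), mfe_cutoff)
        for p, sites in res.items():
            out[p].extend(sites)
    return out


def summarize_targets(
    sites_by_preset: dict[str, list[TargetSite]],
    mirna_class: dict[str, str],
) -> TargetSummary:
    """Per-(class, preset) accounting plus the deduplicated union.

    `mirna_class` maps miRNA id -> "conserved" | "novel".  The union is
    deduplicated by (miRNA, gene) pair, keeping the first site seen in
    preset order; gene counts are deduplicated per class.
    """
    rows = []
    for cls in ("conserved", "novel"):
        for preset, sites in sites_by_preset.items():
            sub = [s for s in sites if mirna_class.get(s.mirna_id) == cls]
            ti = sum(1 for s in sub if s.mode == "translational_inhibition")
            cleav = len(sub) - ti
            rows.append({
                "class": cls,
                "preset": preset,
                "n_mirnas": len({s.mirna_id for s in sub}),
                "n_target_genes": len({s.transcript_id for s in sub}),
                "ti_loci": ti,
                "cleavage_loci": cleav,
                "ti_pct": ti_fraction(cleav, ti),
            })
    union: dict[tuple[str, str], TargetSite] = {}
    for preset in sites_by_preset:
        for s in sites_by_preset[preset]:
            union.setdefault((s.mirna_id, s.transcript_id), s)
    combined = {
        cls: len({g for (mid, g) in union if mirna_class.get(mid) == cls})
        for cls in ("conserved", "novel")
    }
    total = len({g for (_, g) in union})
    return TargetSummary(rows=rows, combined_genes=combined,
                         total_genes=total, union=list(union.values()))


def ti_fraction(cleavage: int, ti: int) -> float:
    """Translational-inhibition share of accepted loci, percent."""
    tot = cleavage + ti
    return round(100.0 * ti / tot, 2) if tot else 0.0


def network_edges(union: list[TargetSite]) -> list[tuple[str, str]]:
    """Unique (miRNA, gene) edges from a deduplicated site union."""
    return sorted({(s.mirna_id, s.transcript_id) for s in union})


def node_degrees(edges: list[tuple[str, str]]) -> dict[str, int]:
    deg: dict[str, int] = defaultdict(int)
    for mid, _gene in edges:
        deg[mid] += 1
    return dict(deg)
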