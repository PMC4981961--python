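"""Synthetic small-RNA-seq study generator.

Emulates the inputs of a miRNA-discovery experiment in a unicellular red
alga at desk scale: genome contigs with planted miRNA precursors, a raw
small-RNA library contaminated at configurable per-category rates, a
miRBase-like mature/precursor database, ncRNA reference sets, ESTs with
planted conserved-miRNA homologs, transcripts with planted target sites,
and GO/KEGG term maps with one deliberately enriched term.

Everything derives from one root seed through named child streams
(`numpy.random.SeedSequence` spawn keys), so the three generator entry
points can be called independently and still agree on the planted
material.  Identical config -> byte-identical files.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fold import PAIR_INDEX
from .io import revcomp, write_fasta, write_fastq, write_tsv

__all__ = [
    "SimConfig",
    "PlantedTruth",
    "References",
    "make_genome",
    "simulate_reads",
    "make_references",
    "write_all",
    "ADAPTER_5P",
    "ADAPTER_3P",
    "CONTAMINATION_CATEGORIES",
]

# Illumina TruSeq small-RNA adapters (RNA space); the kit is named in the
# library-prep protocol, the sequences are the kit's published defaults.
ADAPTER_5P = "GUUCAGAGUUCUACAGUCCGACGAUC"
ADAPTER_3P = "UGGAAUUCUCGGGUGCCAAGG"

CONTAMINATION_CATEGORIES = (
    "low_quality",
    "adapter3_null",
    "insert_null",
    "adapter5_contaminant",
    "short_lt18",
    "polyA",
)

BASES = np.array(list("ACGU"))
_WOBBLE_PARTNER = {"G": "U", "U": "G"}  # mature base -> star base forming G:U

#: plant species prefixes used for the miRBase-like database (19 species,
#: gymnosperms/angiosperms/bryophytes)
SPECIES = (
    "ath", "osa", "mtr", "mes", "ppt", "pta", "zma", "gma", "sbi", "vvi",
    "ptc", "stu", "sly", "bdi", "csi", "cme", "aly", "pab", "smo",
)


@dataclass
class SimConfig:
    """Study-scale parameters for the synthetic experiment.

    Defaults are the package's scaled-down rendition of the original
    study: a contig-level genome, a single small-RNA library whose
    contamination fractions equal the observed per-category rates of the
    real library, and planted conserved/novel precursors at counts small
    enough to fold interactively.
    """

    seed: int = 1
    n_contigs: int = 30
    contig_len: int = 5000
    n_planted_precursors: int = 50  # novel (species-specific) precursors
    n_planted_known: int = 20  # precursors whose mature copies a db entry
    n_reads: int = 20000
    contamination_rates: dict = field(
        default_factory=lambda: {
            "low_quality": 0.0027,
            "adapter3_null": 0.0001,
            "insert_null": 0.0003,
            "adapter5_contaminant": 0.0158,
            "short_lt18": 0.0262,
            "polyA": 0.0001,
        }
    )
    read_len_range: tuple = (18, 25)
    n_transcripts: int = 300
    transcript_len: int = 600
    n_planted_targets: int = 60
    n_ests: int = 120
    est_len: int = 400
    n_planted_est_homologs: int = 9
    gu_rate: float = 0.1
    gc_fraction: float | None = None
    mature_len: int = 21
    #: composition of the clean-read mixture (fractions of clean reads)
    clean_mix: dict = field(
        default_factory=lambda: {
            "novel_mature": 0.20,
            "known_mature": 0.04,
            "ncrna": 0.10,
            "genome_background": 0.26,
            "random": 0.40,
        }
    )

    def validate(self) -> None:
        unknown = set(self.contamination_rates) - set(CONTAMINATION_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown contamination categories: {sorted(unknown)}")
        if any(r < 0 for r in self.contamination_rates.values()):
            raise ValueError("contamination rates must be >= 0")
        if sum(self.contamination_rates.values()) >= 1:
            raise ValueError("contamination fractions must sum to < 1")
        for name in (
            "n_contigs", "contig_len", "n_planted_precursors", "n_planted_known",
            "n_reads", "n_transcripts", "n_planted_targets", "n_ests",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.gu_rate <= 1):
            raise ValueError("gu_rate must lie in [0, 1]")
        if abs(sum(self.clean_mix.values()) - 1.0) > 1e-9:
            raise ValueError("clean_mix fractions must sum to 1")


@dataclass
class PrecursorRecord:
    name: str
    contig: str
    start: int  # precursor start, 0-based
    end: int
    strand: str
    kind: str  # "known" | "novel"
    mature: str
    star: str
    mature_start: int  # genomic start of the mature
    loop_len: int
    family: str = ""  # known-family name when kind == "known"


@dataclass
class TargetSiteRecord:
    mirna_id: str
    mirna_seq: str
    transcript_id: str
    site_start: int  # 0-based on the transcript
    pattern: str  # per-miRNA-position states, 5'->3': '|' WC, 'o' GU, 'x' mismatch
    intended_mode: str  # "cleavage" | "translational_inhibition"
    compliant: bool


@dataclass
class EstHomologRecord:
    est_id: str
    mature: str  # the homolog as planted in the EST
    source_family: str
    edits: int
    compliant: bool  # edits <= 3 -> part of the conserved truth set


@dataclass
class PlantedTruth:
    precursors: list = field(default_factory=list)
    read_categories: list = field(default_factory=list)  # per simulated read
    read_inserts: list = field(default_factory=list)  # intended insert or ""
    target_sites: list = field(default_factory=list)
    est_homologs: list = field(default_factory=list)
    enriched_term: str = ""
    enriched_term_kegg: str = ""


@dataclass
class References:
    mature_db: dict = field(default_factory=dict)  # id -> sequence
    precursor_db: dict = field(default_factory=dict)
    ncrna: dict = field(default_factory=dict)  # class -> {id: seq}
    ests: dict = field(default_factory=dict)
    transcripts: dict = field(default_factory=dict)
    go_map: list = field(default_factory=list)  # (term_id, gene_id, term_name)
    kegg_map: list = field(default_factory=list)
    go_categories: dict = field(default_factory=dict)  # term_id -> BP/CC/MF


def _rng(cfg: SimConfig, *key: str) -> np.random.Generator:
    """Named child RNG so generator entry points agree without sharing state."""
    digest = hashlib.sha256(("/".join(key)).encode()).digest()
    spawn = int.from_bytes(digest[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, spawn]))


def _rand_seq(rng: np.random.Generator, n: int, gc: float | None = None) -> str:
    if gc is None:
        return "".join(rng.choice(BASES, size=n))
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=n, p=p))


def _mature_seq(rng: np.random.Generator, length: int, u_bias: float = 0.5) -> str:
    seq = _rand_seq(rng, length)
    if rng.random() < u_bias:
        seq = "U" + seq[1:]
    return seq


def _star_with_wobbles(rng: np.random.Generator, mature: str, gu_rate: float) -> str:
    """Star arm: reverse complement with G:U wobbles at rate gu_rate."""
    star = list(revcomp(mature))
    n = len(mature)
    n_wob = 0
    for k, mb in enumerate(mature):
        if mb in _WOBBLE_PARTNER and n_wob < 3 and rng.random() < gu_rate:
            star[n - 1 - k] = _WOBBLE_PARTNER[mb]
            n_wob += 1
    return "".join(star)


def _known_families(cfg: SimConfig) -> list[tuple[str, str]]:
    """Deterministic (family name, base mature) list shared by genome and db."""
    rng = _rng(cfg, "known_matures")
    fam_numbers = list(rng.choice(np.arange(150, 9900), size=cfg.n_planted_known, replace=False))
    out = []
    for num in sorted(int(x) for x in fam_numbers):
        out.append((f"miR{num}", _mature_seq(rng, cfg.mature_len, u_bias=0.6)))
    return out


def _novel_matures(cfg: SimConfig) -> list[str]:
    rng = _rng(cfg, "novel_matures")
    return [_mature_seq(rng, cfg.mature_len, u_bias=0.5) for _ in range(cfg.n_planted_precursors)]


def _build_precursor(rng: np.random.Generator, mature: str, gu_rate: float) -> tuple[str, str, int, int]:
    """(precursor, star, mature offset, loop_len); mature on the 5' arm."""
    star = _star_with_wobbles(rng, mature, gu_rate)
    loop_len = int(rng.integers(4, 9))
    loop = _rand_seq(rng, loop_len)
    return mature + loop + star, star, 0, loop_len


def make_genome(cfg: SimConfig) -> tuple[dict[str, str], PlantedTruth]:
    """Contigs with planted precursors plus the truth table.

    Contigs are i.i.d. uniform over ACGU (or GC-adjusted); precursors are
    near-palindromic stem constructs (stem >= 18 bp, loop 4-8 nt) embedded
    at recorded coordinates with a 250 nt exclusion margin between loci.
    """
    cfg.validate()
    if cfg.mature_len < 18:
        raise ValueError("mature length must give a stem >= 18 bp")
    rng = _rng(cfg, "genome")
    contigs = {
        f"contig{i + 1}": list(_rand_seq(rng, cfg.contig_len, cfg.gc_fraction))
        for i in range(cfg.n_contigs)
    }
    truth = PlantedTruth()

    known = [("known", f"kno-{fam}", fam, mat) for fam, mat in _known_families(cfg)]
    novel = [("novel", f"ppu-nov{i + 1}", "", m) for i, m in enumerate(_novel_matures(cfg))]
    to_plant = known + novel
    pre_len_max = 2 * cfg.mature_len + 8
    if cfg.contig_len < pre_len_max + 80 and to_plant:
        raise ValueError(
            f"contig_len={cfg.contig_len} too short to host a precursor "
            f"(needs >= {pre_len_max + 80} nt)"
        )
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    margin = 250
    for kind, name, family, mature in to_plant:
        pre, star, moff, loop_len = _build_precursor(rng, mature, cfg.gu_rate)
        for _attempt in range(200):
            contig = f"contig{int(rng.integers(1, cfg.n_contigs + 1))}"
            start = int(rng.integers(40, cfg.contig_len - len(pre) - 40))
            span = (start - margin, start + len(pre) + margin)
            if all(e <= span[0] or s >= span[1] for s, e in occupied[contig]):
                break
        else:
            raise ValueError("could not place precursor; genome too small for the requested count")
        occupied[contig].append(span)
        contigs[contig][start : start + len(pre)] = list(pre)
        truth.precursors.append(
            PrecursorRecord(
                name=name, contig=contig, start=start, end=start + len(pre),
                strand="+", kind=kind, mature=mature, star=star,
                mature_start=start + moff, loop_len=loop_len, family=family,
            )
        )
    return {c: "".join(s) for c, s in contigs.items()}, truth


def _ncrna_sets(cfg: SimConfig) -> dict[str, dict[str, str]]:
    rng = _rng(cfg, "ncrna")
    sizes = {"rRNA": 15, "tRNA": 15, "snRNA": 10, "snoRNA": 10}
    out: dict[str, dict[str, str]] = {}
    for cls, n in sizes.items():
        out[cls] = {
            f"{cls}_{i + 1}": _rand_seq(rng, int(rng.integers(70, 151)))
            for i in range(n)
        }
    return out


def simulate_reads(
    contigs: dict[str, str], truth: PlantedTruth, cfg: SimConfig
) -> list[tuple[str, str, str]]:
    """Raw FASTQ reads: adapter-wrapped inserts plus per-category contaminants.

    Clean inserts are planted matures (novel and known), ncRNA fragments,
    genome background windows and unmappable random sequence, each wrapped
    as 5'adapter + insert + 3'adapter.  Contaminated reads are built per
    category; the category of every read is recorded in the truth table.
    """
    cfg.validate()
    rng = _rng(cfg, "reads")
    cats = list(CONTAMINATION_CATEGORIES)
    probs = np.array([cfg.contamination_rates.get(c, 0.0) for c in cats])
    probs = np.append(probs, 1.0 - probs.sum())
    draw = rng.choice(len(cats) + 1, size=cfg.n_reads, p=probs)

    mix_names = list(cfg.clean_mix)
    mix_p = np.array([cfg.clean_mix[k] for k in mix_names])
    novel_matures = [p.mature for p in truth.precursors if p.kind == "novel"]
    known_matures = [p.mature for p in truth.precursors if p.kind == "known"]
    ncrna = _ncrna_sets(cfg)
    ncrna_seqs = [s for cls in ncrna.values() for s in cls.values()]
    contig_ids = list(contigs)
    lo, hi = cfg.read_len_range

    def clean_insert() -> str:
        kind = mix_names[int(rng.choice(len(mix_names), p=mix_p))]
        if kind == "novel_mature" and novel_matures:
            return novel_matures[int(rng.integers(len(novel_matures)))]
        if kind == "known_mature" and known_matures:
            return known_matures[int(rng.integers(len(known_matures)))]
        if kind == "ncrna" and ncrna_seqs:
            src = ncrna_seqs[int(rng.integers(len(ncrna_seqs)))]
            ln = int(rng.integers(lo, min(hi, len(src)) + 1))
            st = int(rng.integers(0, len(src) - ln + 1))
            return src[st : st + ln]
        if kind == "genome_background" and contig_ids:
            c = contigs[contig_ids[int(rng.integers(len(contig_ids)))]]
            ln = int(rng.integers(lo, hi + 1))
            st = int(rng.integers(0, len(c) - ln))
            win = c[st : st + ln]
            return win if rng.random() < 0.5 else revcomp(win)
        return _rand_seq(rng, int(rng.integers(lo, hi + 1)))

    reads = []
    hi_q, lo_q = "I", "#"
    for idx in range(cfg.n_reads):
        cat = cats[draw[idx]] if draw[idx] < len(cats) else "clean"
        qual_char = hi_q
        if cat == "clean":
            insert = clean_insert()
            seq = ADAPTER_5P + insert + ADAPTER_3P
        elif cat == "low_quality":
            insert = clean_insert()
            seq = ADAPTER_5P + insert + ADAPTER_3P
            qual_char = lo_q
        elif cat == "adapter3_null":
            insert = clean_insert()
            seq = ADAPTER_5P + insert + _rand_seq(rng, 10)
        elif cat == "insert_null":
            insert = ""
            seq = ADAPTER_5P + ADAPTER_3P
        elif cat == "adapter5_contaminant":
            w1 = _rand_seq(rng, int(rng.integers(4, 9)))
            w2 = _rand_seq(rng, int(rng.integers(10, 16)))
            insert = w1 + ADAPTER_5P + w2
            seq = ADAPTER_5P + insert + ADAPTER_3P
        elif cat == "short_lt18":
            insert = _rand_seq(rng, int(rng.integers(10, 18)))
            seq = ADAPTER_5P + insert + ADAPTER_3P
        elif cat == "polyA":
            n = int(rng.integers(20, 26))
            ins = ["A"] * n
            ins[int(rng.integers(n))] = str(rng.choice(["A", "C", "G"]))
            insert = "".join(ins)
            seq = ADAPTER_5P + insert + ADAPTER_3P
        truth.read_categories.append(cat)
        truth.read_inserts.append(insert)
        reads.append((f"read{idx + 1}", seq, qual_char * len(seq)))
    return reads


def _apply_edits(rng: np.random.Generator, seq: str, n_edits: int) -> str:
    """n_edits single-base substitutions/insertions/deletions, positions distinct."""
    s = list(seq)
    for _ in range(n_edits):
        op = rng.choice(["sub", "ins", "del"], p=[0.6, 0.2, 0.2])
        pos = int(rng.integers(1, len(s) - 1))
        if op == "sub":
            choices = [b for b in "ACGU" if b != s[pos]]
            s[pos] = choices[int(rng.integers(3))]
        elif op == "ins":
            s.insert(pos, str(rng.choice(list("ACGU"))))
        else:
            del s[pos]
    return "".join(s)


def _min_nw_distance(seq: str, others: list[str]) -> int:
    import edlib

    return min(edlib.align(seq, o, mode="NW")["editDistance"] for o in others)


def make_references(cfg: SimConfig, truth: PlantedTruth | None = None) -> References:
    """miRBase-like db, ncRNA sets, ESTs, transcripts and GO/KEGG maps.

    The database carries every planted known family under several plant
    species prefixes; some ESTs embed a planted mature homolog within <= 3
    edits flanked by a foldable hairpin; transcripts embed target sites
    for planted miRNAs; the GO map contains one term deliberately enriched
    among targeted genes.  When a truth object from :func:`make_genome` is
    given, the EST/target records are appended to it.
    """
    cfg.validate()
    rng = _rng(cfg, "references")
    truth = truth if truth is not None else PlantedTruth()
    refs = References()

    # --- miRBase-like mature + precursor database ------------------------
    families = _known_families(cfg)
    for fam, base in families:
        n_species = int(rng.integers(3, 8))
        for sp in rng.choice(np.array(SPECIES), size=n_species, replace=False):
            seq = list(base)
            if rng.random() < 0.4:  # one cross-species substitution
                p = int(rng.integers(len(seq)))
                seq[p] = [b for b in "ACGU" if b != seq[p]][int(rng.integers(3))]
            mat = "".join(seq)
            mid = f"{sp}-{fam}"
            refs.mature_db[mid] = mat
            pre, _, _, _ = _build_precursor(rng, mat, cfg.gu_rate)
            flank = _rand_seq(rng, 15)
            refs.precursor_db[f"{mid}-pre"] = flank + pre + _rand_seq(rng, 15)

    refs.ncrna = _ncrna_sets(cfg)

    # --- ESTs with planted conserved homologs ----------------------------
    est_rng = _rng(cfg, "ests")
    ests = {
        f"EST{i + 1:04d}": list(_rand_seq(est_rng, cfg.est_len))
        for i in range(cfg.n_ests)
    }
    est_ids = list(ests)
    n_decoys = 2 if cfg.n_planted_est_homologs else 0
    chosen = est_rng.choice(len(est_ids), size=cfg.n_planted_est_homologs + n_decoys, replace=False)
    # compliant homologs come from distinct families so their matures are
    # distinct after merging; decoys sit at edit distance 4 (just past the
    # budget of 3) from every database mature, verified below
    fam_order = [families[i] for i in est_rng.permutation(len(families))]
    db_matures = list(refs.mature_db.values())
    seen_homologs: set[str] = set()
    for k, ei in enumerate(chosen):
        compliant = k < cfg.n_planted_est_homologs
        fam, base = (fam_order[k % len(fam_order)] if compliant
                     else families[int(est_rng.integers(len(families)))])
        edits = int(est_rng.integers(0, 4)) if compliant else 4
        for _retry in range(100):
            homolog = _apply_edits(est_rng, base, edits)
            if homolog in seen_homologs:
                continue
            if compliant or _min_nw_distance(homolog, db_matures) >= 4:
                break
        seen_homologs.add(homolog)
        pre, _, _, _ = _build_precursor(est_rng, homolog, cfg.gu_rate)
        est_id = est_ids[int(ei)]
        start = int(est_rng.integers(30, cfg.est_len - len(pre) - 30))
        ests[est_id][start : start + len(pre)] = list(pre)
        truth.est_homologs.append(
            EstHomologRecord(est_id=est_id, mature=homolog, source_family=fam,
                             edits=edits, compliant=compliant)
        )
    refs.ests = {k: "".join(v) for k, v in ests.items()}

    # --- transcripts with planted target sites ---------------------------
    t_rng = _rng(cfg, "targets")
    transcripts = {
        f"gene{i + 1:04d}": list(_rand_seq(t_rng, cfg.transcript_len))
        for i in range(cfg.n_transcripts)
    }
    mirnas = [(p.name, p.mature) for p in truth.precursors] or [
        (f"mir{i}", _mature_seq(t_rng, cfg.mature_len)) for i in range(10)
    ]
    gene_ids = list(transcripts)
    used: dict[str, list[tuple[int, int]]] = {g: [] for g in gene_ids}
    for _ in range(cfg.n_planted_targets):
        mid, mseq = mirnas[int(t_rng.integers(len(mirnas)))]
        L = len(mseq)
        site = list(revcomp(mseq))  # perfect complement, 5'->3' on transcript
        pattern = ["|"] * L
        mode = "cleavage"
        style = t_rng.choice(["perfect", "central_gu", "edge_mm"], p=[0.4, 0.3, 0.3])
        if style == "central_gu":
            # wobble at miRNA position 9-11: still paired, flips the mode
            for pos in t_rng.permutation([9, 10, 11]):
                mb = mseq[pos - 1]
                if mb in _WOBBLE_PARTNER:
                    site[L - pos] = _WOBBLE_PARTNER[mb]
                    pattern[pos - 1] = "o"
                    mode = "translational_inhibition"
                    break
        elif style == "edge_mm":
            # one full mismatch outside positions 8-12
            pos = int(t_rng.choice([2, 3, 4, 5, 6, 7, 14, 16, 18]))
            mb = mseq[pos - 1]
            bad = [b for b in "ACGU" if (mb, b) not in PAIR_INDEX]
            site[L - pos] = bad[int(t_rng.integers(len(bad)))]
            pattern[pos - 1] = "x"
        for _attempt in range(50):
            gid = gene_ids[int(t_rng.integers(len(gene_ids)))]
            start = int(t_rng.integers(0, cfg.transcript_len - L))
            if all(e <= start or s >= start + L for s, e in used[gid]):
                break
        used[gid].append((start, start + L))
        transcripts[gid][start : start + L] = site
        truth.target_sites.append(
            TargetSiteRecord(mirna_id=mid, mirna_seq=mseq, transcript_id=gid,
                             site_start=start, pattern="".join(pattern),
                             intended_mode=mode, compliant=True)
        )
    refs.transcripts = {k: "".join(v) for k, v in transcripts.items()}

    # --- GO / KEGG maps with one enriched term ---------------------------
    g_rng = _rng(cfg, "terms")
    targeted = sorted({s.transcript_id for s in truth.target_sites})
    background = gene_ids
    n_terms = 40
    cat_names = ["BP", "CC", "MF"]
    go_rows, kegg_rows = [], []
    for t in range(n_terms):
        term = f"GO:{7000000 + t}"
        refs.go_categories[term] = cat_names[t % 3]
        for g in background:
            if g_rng.random() < 0.06:
                go_rows.append((term, g, f"synthetic process {t}"))
    enr = "GO:7009999"
    refs.go_categories[enr] = "BP"
    for g in targeted:
        if g_rng.random() < 0.8:
            go_rows.append((enr, g, "planted enriched process"))
    for g in background:
        if g not in set(targeted) and g_rng.random() < 0.04:
            go_rows.append((enr, g, "planted enriched process"))
    truth.enriched_term = enr
    for t in range(12):
        term = f"ko{3000 + t}"
        for g in background:
            if g_rng.random() < 0.05:
                kegg_rows.append((term, g, f"synthetic pathway {t}"))
    kenr = "ko3999"
    for g in targeted:
        if g_rng.random() < 0.7:
            kegg_rows.append((kenr, g, "planted enriched pathway"))
    truth.enriched_term_kegg = kenr
    refs.go_map = sorted(set(go_rows))
    refs.kegg_map = sorted(set(kegg_rows))
    return refs


def write_all(outdir: str | Path, cfg: SimConfig) -> tuple[dict, PlantedTruth, References]:
    """Run the whole generator and write every artifact under `outdir`."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    contigs, truth = make_genome(cfg)
    reads = simulate_reads(contigs, truth, cfg)
    refs = make_references(cfg, truth)

    write_fasta(out / "genome.fasta", contigs)
    write_fastq(out / "reads.fastq", reads)
    write_fasta(out / "mature_db.fasta", refs.mature_db)
    write_fasta(out / "precursor_db.fasta", refs.precursor_db)
    for cls, seqs in refs.ncrna.items():
        write_fasta(out / f"{cls}.fasta", seqs)
    write_fasta(out / "ests.fasta", refs.ests)
    write_fasta(out / "transcripts.fasta", refs.transcripts)
    write_tsv(out / "go_map.tsv", ["term_id", "gene_id", "term_name"], refs.go_map)
    write_tsv(out / "kegg_map.tsv", ["term_id", "gene_id", "term_name"], refs.kegg_map)
    write_tsv(out / "go_categories.tsv", ["term_id", "category"],
              sorted(refs.go_categories.items()))
    write_tsv(
        out / "truth_precursors.tsv",
        ["name", "contig", "start", "end", "strand", "kind", "mature", "star",
         "mature_start", "loop_len", "family"],
        [(p.name, p.contig, p.start, p.end, p.strand, p.kind, p.mature, p.star,
          p.mature_start, p.loop_len, p.family) for p in truth.precursors],
    )
    write_tsv(out / "truth_reads.tsv", ["read", "category", "insert"],
              [(f"read{i + 1}", c, s) for i, (c, s) in
               enumerate(zip(truth.read_categories, truth.read_inserts))])
    write_tsv(
        out / "truth_targets.tsv",
        ["mirna_id", "mirna_seq", "transcript_id", "site_start", "pattern",
         "intended_mode", "compliant"],
        [(s.mirna_id, s.mirna_seq, s.transcript_id, s.site_start, s.pattern,
          s.intended_mode, s.compliant) for s in truth.target_sites],
    )
    write_tsv(
        out / "truth_est_homologs.tsv",
        ["est_id", "mature", "source_family", "edits", "compliant"],
        [(e.est_id, e.mature, e.source_family, e.edits, e.compliant)
         for e in truth.est_homologs],
    )
    return contigs, truth, refs
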