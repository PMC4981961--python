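"""Fold a miRNA precursor and read off the hairpin metrics.

The built-in model folds single stems (one terminal loop, bulges and
internal loops allowed, no multiloops) by energy minimisation.  The
metrics printed here — hairpin-loop count, overhangs, largest bulge,
minimum free energy — are exactly what the discovery filters consume.
"""

from miralga.fold import duplex_metrics, fold
from miralga.io import revcomp

mature = "UGAGGUAGUAGGUUGUAUAGU"  # a classic 21-nt plant-style mature
precursor = mature + "GCAAUC" + revcomp(mature)

r = fold(precursor)
print("sequence: ", r.sequence)
print("structure:", r.structure)
print(f"MFE: {r.mfe:.1f} kcal/mol "
      f"({r.n_pairs} pairs, {r.n_hairpin_loops} hairpin loop, "
      f"terminal loop {r.terminal_loop_size} nt)")

d = duplex_metrics(r, (0, len(mature)))
print(f"mature/star duplex: overhangs ({d.overhang_5p}, {d.overhang_3p}) nt, "
      f"largest bulge {max(d.max_bulge_or_loop_mature, d.max_bulge_or_loop_star)} nt")
# A perfect stem gives a blunt duplex (0, 0) and an MFE far below the
# -18 kcal/mol acceptance threshold; a random sequence of the same
# length usually fails one of the two.

random_seq = "AGUCAUGCAUGGAUCGAUAGCUAGCAUGGCAUCGAUUAGCGAUCGAUA"
r2 = fold(random_seq)
print(f"\nrandom 48-mer MFE: {r2.mfe:.1f} kcal/mol -> "
      f"{'passes' if r2.mfe <= -18 else 'fails'} the -18 kcal/mol cutoff")
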