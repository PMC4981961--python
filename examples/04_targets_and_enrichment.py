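"""Predict target sites for one miRNA and test GO-term enrichment.

Shows the complementarity rules in action (a G:U wobble in the central
region flips the repression mode to translational inhibition), then
runs a hypergeometric enrichment on a toy gene set.
"""

from miralga.enrich import hypergeom_enrich
from miralga.io import revcomp
from miralga.targets import scan_targets

mirna = "UGGACGGAGUACUGAUAAGGG"
site = revcomp(mirna)

# plant one perfect site and one with a central G:U wobble (position 10)
wobbled = list(site)
wobbled[len(mirna) - 10] = "G"  # miRNA position 10 is U: U:G wobble instead of U:A
transcripts = {
    "geneA": "GCAU" * 10 + site + "AUGC" * 10,
    "geneB": "CAUG" * 10 + "".join(wobbled) + "UGCA" * 10,
}

for s in scan_targets("miR-x", mirna, transcripts, preset="strict"):
    print(f"{s.transcript_id}: site {s.start}-{s.end}, score {s.score}, "
          f"duplex {s.mfe:.1f} kcal/mol, mode {s.mode}")
    print(f"  pairing (miRNA 5'->3'): {s.pairing}")
# geneA is a cleavage site (all Watson-Crick); geneB becomes
# translational inhibition because of the wobble at position 10.

background = [f"g{i:03d}" for i in range(200)]
selected = background[:30]
term_map = (
    [("GO:0001", g, "planted process") for g in background[:20]]      # 20/30 hit
    + [("GO:0002", g, "indifferent process") for g in background[50:90]]
)
for r in hypergeom_enrich(selected, term_map, background):
    flag = "significant" if r.significant_go else "not significant"
    print(f"{r.term_id} ({r.term_name}): k={r.k}/{r.K}, "
          f"p={r.p:.2e}, BH-adjusted={r.p_adj:.2e} -> {flag}")
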