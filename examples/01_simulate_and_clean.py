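"""Simulate a small-RNA library and run the cleaning cascade.

Builds a miniature study (genome with planted miRNA precursors, a
contaminated read library), then cleans the reads and prints the
per-category accounting table.  Every removed read belongs to exactly
one category, and the percentages are shares of the high-quality pool.
"""

from miralga.qc import clean_reads, length_distribution, redundancy_ratio
from miralga.synthio import SimConfig, make_genome, make_references, simulate_reads

cfg = SimConfig(seed=1, n_reads=4000)
contigs, truth = make_genome(cfg)
reads = simulate_reads(contigs, truth, cfg)

unique, labels, report = clean_reads(reads)

print("Read accounting (Type / Reads / Percent of high-quality):")
for row in report.rows():
    print(f"  {row[0]:<24}{row[1]:>8}  {row[2]}")

ratio = redundancy_ratio(report.clean_reads, len(unique))
print(f"\n{len(unique)} unique sequences; {ratio} reads per unique sequence")

dist = length_distribution(unique, weighted=True)
mode = max(dist, key=dist.get)
print(f"most abundant insert length: {mode} nt "
      f"({100 * dist[mode]:.1f} % of read mass)")
# The mode sits at the planted mature length (21 nt): the expressed
# miRNAs dominate the clean-read mass.
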