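"""Per-isolate mutation accounting, substitution spectrum, hotspot enrichment.

Isolates are sampled from a simulated subculture-5 population (the point at
which degenerate variants were characterized); their mutation catalogue is
summarized, and the four genomic hotspot regions are tested for enrichment
against a length-proportional binomial null with BH correction.
"""

import numpy as np

from degensim import (
    hotspot_test,
    mean_mutations_per_isolate,
    sample_isolates,
    simulate_series,
    spectrum_summary,
)
from degensim.mutstats import GeneModel, region_counts
from degensim.popsim import DEFAULT_GENOME, RegimeConfig

rng = np.random.default_rng(3)
series = simulate_series(regime=RegimeConfig(n_subcultures=5), seed=3)
catalogue = sample_isolates(series, 5, 71, rng)

mean = mean_mutations_per_isolate(catalogue, 71)
print(f"{len(catalogue)} mutations across 71 isolates: {mean:.2f} per isolate")

spectrum = spectrum_summary(catalogue)
gc_ta = spectrum.loc["G:C>T:A"]
print(f"G:C>T:A transversions: {gc_ta['count']} of {spectrum.attrs['n_snps']} SNPs "
      f"({100 * gc_ta['fraction']:.0f}%)")

# treat the four hotspot regions as the gene models of interest; everything
# between them forms the (huge) intergenic background
genes = [
    GeneModel(r.region_id, DEFAULT_GENOME.chrom, r.start, r.end)
    for r in DEFAULT_GENOME.regions
]
counts = region_counts(catalogue, genes, DEFAULT_GENOME.length)
results = hotspot_test(counts, genes, DEFAULT_GENOME.length, len(catalogue), fdr=0.05)
print("\nregion-level enrichment (q <= 0.05 marked *):")
for h in results:
    if h.observed == 0:
        continue
    mark = "*" if h.enriched else " "
    print(f" {mark} {h.region_id:<34} {h.observed:>3} observed vs "
          f"{h.expected:6.2f} expected  q={h.q_value:.3g}")
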