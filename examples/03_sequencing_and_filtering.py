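"""Ultra-deep population sequencing of a subculture series, then variant filtering.

True allele frequencies from a simulated series are turned into per-site,
per-orientation pileups (~368x depth), and the filter cascade is applied:
site scoring, caller consensus, the both-orientations AF > 4% rule, and the
trajectory rules (AF > 8% in >= 3 subcultures, no starter background, no
depth-tracking artifacts).
"""

import numpy as np

from degensim import simulate_series, run_filter_cascade
from degensim.seqsim import SeqParams, simulate_series_pileups

series = simulate_series(seed=11)
truth = series.truth_table(min_af=0.02)  # variants that ever reach 2%
params = SeqParams(seed=5)
pileups = simulate_series_pileups(truth, params, n_background=100)
print(f"{truth.mut_id.nunique()} variants sequenced over {len(pileups)} pileup sites")

result = run_filter_cascade(pileups, error_rate=params.error_rate)
kept = result.variants[result.variants.keep]
print(f"{int(result.calls.site_pass.sum())} site-level calls pass; "
      f"{len(kept)} variants survive the trajectory rules:")
print(kept[["chrom", "pos", "ref", "alt"]].to_string(index=False))

# how well do the surviving calls track the truth?
spo0a = kept[(kept.pos >= 1_900_001) & (kept.pos <= 1_901_700)]
print(f"\n{len(spo0a)} kept variants fall in the spo0A hotspot "
      "(the sweep the heatmap rules are designed to expose).")
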