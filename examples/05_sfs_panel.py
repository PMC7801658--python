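"""Site-frequency spectrum of the alleles a consensus employs.

Votes a consensus from three haploids, compares it with the external
(ancestral) reference, looks each employed allele up in the population
AF panel, and summarizes how many of the panel's near-fixed sites the
consensus captures. The spectrum should lean right: majority voting
favours common alleles.
"""

import numpy as np

from popref.consensus import apply_variants, vote_major_alleles
from popref.sfs import (build_sfs, employed_allele_freq,
                        panel_threshold_totals, representativeness_summary)
from popref.simulate import SimParams, sample_haploid_assembly, simulate_population

truth = simulate_population(
    SimParams(n_chrom=2, chrom_len=100_000, indel_rate=0, sv_rate=0), seed=7)
panel = truth.af_panel()

per_assembly = {}
for i in range(3):
    _, carried = sample_haploid_assembly(truth, seed=70 + i, name=f"h{i}")
    per_assembly[f"h{i}"] = [e.variant for e in carried]
vote = vote_major_alleles(per_assembly, n_assemblies=3)

per_site = employed_allele_freq(vote.major, panel)
sfs = build_sfs(per_site)
found = [s.af for s in per_site if s.status == "found"]
print(f"{len(vote.major)} employed alleles; "
      f"median panel AF = {np.median(found):.2f} "
      f"(the backbone draw would centre near 0.5)")

hist, edges = np.histogram(found, bins=np.arange(0, 1.1, 0.1))
for lo, n in zip(edges[:-1], hist):
    print(f"  AF [{lo:.1f},{lo + 0.1:.1f}): {'#' * (60 * n // max(hist.max(), 1))}")

totals = panel_threshold_totals(panel, thresholds=(0.99, 0.90))
summary = representativeness_summary(per_site, totals, thresholds=(0.99, 0.90))
print("\ncapture of the panel's high-frequency sites:")
print(summary.to_string(index=False))
# pct_of_panel = employed alleles meeting the AF threshold as a share of
# all panel sites at that threshold.
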