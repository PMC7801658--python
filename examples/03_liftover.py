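"""Generate a chain file from a consensus build and lift annotations.

The coordinate map produced when variants are applied to the backbone
becomes a UCSC chain; a toy 3-exon gene is lifted backbone -> consensus
and positions downstream of indels shift by the summed indel lengths.
"""

from popref.consensus import apply_variants
from popref.io import Gff3Feature
from popref.liftover import blocks_to_chain, lift_annotation, lift_interval
from popref.io import GenomeInterval
from popref.simulate import SimParams, sample_haploid_assembly, simulate_population

truth = simulate_population(SimParams(n_chrom=1, chrom_len=50_000), seed=4)
_, carried = sample_haploid_assembly(truth, seed=5, name="hap")
consensus, cmap, _ = apply_variants(truth.ancestral,
                                    [e.variant for e in carried])
chains = blocks_to_chain(coordinate_map=cmap)
print(f"{len(chains)} chain(s); consensus is "
      f"{consensus.total_length() - truth.ancestral.total_length():+d} bp "
      f"vs the backbone")

gene = [
    Gff3Feature("chr1", "toy", "gene", 20_001, 30_000, ".", "+", ".", "ID=g1"),
    Gff3Feature("chr1", "toy", "exon", 20_001, 20_400, ".", "+", ".",
                "ID=e1;Parent=g1"),
    Gff3Feature("chr1", "toy", "exon", 29_500, 30_000, ".", "+", ".",
                "ID=e2;Parent=g1"),
]
lifted, rejects = lift_annotation(gene, chains, policy="strict")
for f in lifted:
    shift = f.start - dict(g1=20_001, e1=20_001, e2=29_500)[f.attr["ID"]]
    print(f"{f.attr['ID']:3s} {f.ftype:5s} {f.start}-{f.end} "
          f"(shifted {shift:+d} bp by upstream indels)")
print(f"rejected: {len(rejects)}")

status, iv = lift_interval(chains, GenomeInterval("chr1", 40_000, 40_100))
print(f"\npoint lift of chr1:40000-40100 -> {status} "
      f"{iv.contig}:{iv.start}-{iv.end}")
# 'exact' means the whole interval sits inside aligned chain blocks.
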