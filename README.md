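# popref

Build and evaluate **population-consensus reference genomes**: integrate N
haploid de novo assemblies into a single reference that carries, at every
variable site, the allele a majority of the donors share.

A reference genome assembled from one individual inevitably carries that
individual's rare alleles, which inflate spurious variant calls for every
other sample mapped against it. One remedy is to sequence a few members of
the target population, align their assemblies to a common backbone, and
*vote*: wherever at least ⌊N/2⌋+1 of the N assemblies agree on an allele
that differs from the backbone, substitute it. `popref` implements that
construction end to end at library scale, together with the classical
evaluation battery for such a reference:

* **Majority-vote allele substitution** — pairwise whole-genome alignment
  (anchor–chain–extend; external PAF with `cs` tags accepted), variant
  calling, left-align/parsimony normalization, per-site voting with
  seeded random resolution of tied (e.g. tri-allelic) sites, and
  consensus application with an exact coordinate map.
* **Scaffold anchoring** — in-silico STS PCR (primer pairs, mismatch
  tolerance, exact 3′ seed), chimera flagging, and chromosome
  assignment/ordering/orientation from genetic (cM) and radiation-hybrid
  (cR) marker maps, genetic maps weighted 5 : 1 over RH maps;
  pseudo-molecules are concatenated with 10 kb N gaps and described in
  AGP 2.1. Finishing edits: interval masking (e.g. a pseudo-autosomal
  region), circular rotation (mitochondria), named N-gap resizing.
* **Liftover** — UCSC chain files generated from alignments or from the
  consensus coordinate map; interval and BED/GFF3 annotation lifting with
  strict or permissive policies.
* **SV statistics** — indels ≥ 51 bp, type-aware single-linkage merging
  with both breakpoints within 1000 bp (the SURVIVOR `1000 1 1 0 0 1`
  convention), support rates, per-chromosome depth accessibility
  ([5, mean + 2 SD]), the **Δ average depth** statistic (most deviant
  depth inside an SV window minus the mean of an equal-length upstream
  window) and paired two-sided Wilcoxon signed-rank tests.
* **Representativeness SFS** — look up each employed allele in a
  population allele-frequency panel, build the unfolded site-frequency
  spectrum, and report capture of the panel's AF = 1.0, ≥ 0.99 and
  ≥ 0.90 sites.
* **Synthetic data** — a fully seeded simulator for every stage:
  population variant catalogues (SNVs, indels, SVs with ~300 bp and
  ~6 kb insertion modes), haploid assemblies, fragmented scaffolds,
  noisy marker maps, and per-sample depth tracks, each with truth tables.

The key quantity behind the design: if the population-major allele at a
site has frequency *p*, a 2-of-3 vote recovers it with probability
*p*³ + 3*p*²(1 − *p*) — already 0.972 at *p* = 0.9. The test suite holds
the implementation to that law, and to exact round-trip recovery of every
applied allele.

## Worked example

`examples/01_build_consensus.py` simulates a 60 kb population, samples
three haploids, and votes a consensus against the ancestral backbone:

```
hap_a: 34 variants vs backbone
hap_b: 28 variants vs backbone
hap_c: 31 variants vs backbone

major alleles applied: 32 (0 tie sites resolved randomly)
consensus length shift: +9 bp

support breakdown (how many haploids carried each applied allele):
 support  count  pct
       1      0  0.0
       2     16 50.0
       3     16 50.0
```

Half the applied alleles were carried by all three haploids and half by
exactly two — no allele below the 2-of-3 share is ever applied, and the
+9 bp length shift equals the summed indel lengths of the applied set.
The other scripts in `examples/` walk through anchoring, liftover, the
Δ-depth contrast and the representativeness SFS the same way.

A thin CLI mirrors the library (`popref simulate | build-consensus |
epcr | anchor | chain | lift | sv-merge | delta-depth | sfs | report`);
every subcommand writes a manifest JSON with the seed and config hash so
outputs are reproducible byte for byte.

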