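# haplosweep

Haplotype-based SNP marker discovery and genotyping for allopolyploids.

## The problem

An allopolyploid (peanut, wheat, strawberry, ...) carries two or more
diverged subgenomes inherited from different progenitor species. Short
reads from homeologous copies of a locus frequently align to the same
reference coordinates, so a position where the subgenomes differ looks
exactly like a SNP between accessions — in every accession. Because read
sampling is noisy, filtering such sites by expected sequencing depth does
not protect against these false positives: a homeologous site whose
combined depth happens to fall inside the expected-coverage band is
indistinguishable, site by site, from a real polymorphism.

The haplotype-based approach (HaploSWEEP) resolves this with two-site
haplotypes read directly off the alignments. For every pair of candidate
polymorphic sites within a base window, the ordered pair of bases each
single read shows at the two sites is collected per accession. A site
where the subgenomes differ in all accessions acts as an **anchor**: it
splits each accession's reads into subgenome-of-origin groups, and
variation at the partner site can then be attributed to a true allelic
difference on one subgenome rather than to subgenome mixing.

Collected haplotypes are filtered with four counting rules. For a site
pair to become a marker:

1. at least two accessions must show more than one haplotype;
2. every haplotype an accession contributes must be observed ≥ 2 times;
3. within an accession, the least observed haplotype must be at least 25%
   as frequent as the most observed one (inclusive), excluding rare
   error-driven haplotypes;
4. in at least one — but not all — of those accessions, the haplotypes
   must agree at one site and differ at the other. The within-accession
   invariant site is the inter-accession polymorphic marker site; the
   varying site is the homeolog anchor. If *every* accession shows this
   pattern the pair is a pure subgenome difference and is rejected.

Three run modes scope the collection: **default** (haplotypes within a
single contiguous read), **longrange** (haplotypes spanning properly
paired mates, reaching up to the insert size), and **diploid** (haplotypes
of 2..N consecutive sites, for long reads or diploid genomes). Given
discovered markers, a population of individuals can be genotyped into an
m × n matrix of categorical calls (individuals × markers).

A truth-tabled allotetraploid read simulator is part of the package: it
draws an ancestor sequence, a diverged second subgenome, accession-specific
subgenome-A SNPs, and error-bearing (paired) reads mapped back to the
collapsed ancestor coordinates, so the whole pipeline is verifiable
end-to-end without any external data.

## Worked example

Simulate three accessions of a 20 kb allotetraploid locus (1% subgenome
divergence, forty accession SNPs near anchors, 2×150 bp reads at 20× per
subgenome, 0.2% base error), then discover and score markers:

```sh
haplosweep simulate --seed 1 --out-dir sim
# INFO haplosweep.simulate: simulated 3 accessions, 185 anchors, 40 SNPs, 402 candidate sites

printf 'acc1\tsim/acc1.bam\nacc2\tsim/acc2.bam\nacc3\tsim/acc3.bam\n' > bams.tsv
haplosweep discover --vcf sim/candidates.vcf --bam-list bams.tsv \
    --out-prefix run --window 150
# INFO haplosweep: candidate sites: 402
# INFO haplosweep: site pairs within 150 bp window: 1335
# INFO haplosweep: haplotype table entries: 1316
# INFO haplosweep: polymorphic haplotype markers: 154

haplosweep evaluate --markers run.polymorphic_haplotypes.tsv \
    --truth-dir sim --vcf sim/candidates.vcf --window 150
# {"tpr": 1.0, "fpr": 0.0, "n_discoverable": 40, "n_recovered": 40,
#  "n_negative": 257, "n_false_positive": 0}
```

Of 402 candidate sites, most are homeologous subgenome differences; the
filters keep 154 site pairs, which cover all 40 discoverable spiked SNPs
(TPR 1.0) and none of the 257 pure-homeolog candidate pairs (FPR 0.0).
The marker file records, per pair, the anchor / polymorphic site
designation and each accession's haplotypes:

```
chrom  pos1  pos2  ref1  alt1  ref2  alt2  anchor_site  polymorphic_site  pattern_accessions  haplotypes
chr1   127   163   A     G     A     T     1            2                 acc1,acc2           acc1=AA|GA;acc2=AA|GA;acc3=AT|GA
```

Here site 127 is the anchor (all accessions show both A and G there, one
per subgenome) and site 163 the polymorphism: acc3's subgenome-A
haplotype carries T while acc1/acc2 carry A. Re-genotyping the founders
at the discovered markers recovers their alleles:

```sh
haplosweep genotype --markers run.polymorphic_haplotypes.tsv \
    --bam-list bams.tsv --out matrix.tsv
# INFO haplosweep: wrote 3 individuals x 154 markers to matrix.tsv
```

```
individual  chr1_127_163  chr1_127_191  chr1_143_163
acc1        A             A             A
acc2        A             A             A
acc3        B             B             B
```

The library API mirrors the CLI (`read_candidate_sites`,
`enumerate_site_pairs`, `build_table`, `call_markers`,
`genotype_population`, `simulate`, `evaluate`, ...); see the module
docstrings and `docs/methods.md`.

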