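# Methods

## Model and procedure

The package targets allopolyploids whose subgenomes are similar enough
that short reads from homeologous loci co-align on one reference
("collapsed mapping"). In that regime a per-site variant caller reports
three kinds of candidate sites: true inter-accession polymorphisms,
homeologous subgenome differences (present in every accession, typically
at ~50/50 allele balance in an allotetraploid), and error artifacts.
Depth-based filtering cannot separate the first two because depth at
collapsed loci is itself noisy.

Discovery works on **two-site haplotypes**. For every ordered pair of
candidate sites on the same chromosome at most `window` bases apart, and
for every accession, the pipeline counts each distinct base pair observed
at the two sites *within one contiguous read* (default mode). Collection
is allele-agnostic — whatever base a read resolves at a candidate site is
recorded literally, including bases outside the VCF's REF/ALT set, so
that the filters rather than the collector decide relevance.

Filtering applies, in order:

* **Retention (rules 2–3).** Per accession, keep a haplotype iff its
  count ≥ `min_obs` (default 2) *and* ≥ `minor_ratio` (default 0.25,
  inclusive — "at least 25% as frequent" is read literally) times the
  count of that accession's most observed haplotype. Retention is applied
  haplotype-wise, so an accession showing three or more haplotypes (via
  error or residual heterozygosity) degrades gracefully.
* **Rule 1.** At least two accessions must retain ≥ 2 haplotypes.
* **Rule 4.** Among the multi-haplotype accessions, at least one but not
  all must show the anchor pattern: all retained haplotypes agree at one
  site and differ pairwise at the other. The invariant site within the
  pattern accessions is designated the inter-accession **polymorphic
  site**; the varying site is the **homeolog anchor**. The designation
  convention is deliberate and documented rather than silently chosen:
  in an allotetraploid, an accession *without* the allelic variant shows
  one haplotype per subgenome, differing only at the anchor, while the
  variant-carrying accession's haplotypes differ at both sites (and so
  shows no pattern). If both site indices qualify, the designation with
  the polymorphic site at index 1 is chosen deterministically. An
  accession with ≥ 3 retained haplotypes shows the pattern only if one
  site is invariant across all of them and the other site is pairwise
  distinct (conservative extension of the two-haplotype rule).

### Run modes

* **default** — within-read collection only; mates of a pair are two
  independent reads. Overlapping mates covering the same pair therefore
  contribute two observations; users wanting fragment-level
  deduplication in this mode should deduplicate upstream or use
  longrange mode.
* **longrange** — fragment-scoped: properly paired same-name mates form
  one fragment, and a haplotype may take its two bases from different
  mates. Each fragment contributes at most one observation per pair.
  When both mates resolve a queried base and disagree, the position
  resolves to missing and the observation is discarded (safer than an
  arbitrary mate preference; a base failing the quality floor simply
  defers to the other mate). Reads that are not properly paired are kept
  as single-mate fragments, which makes the observed-pair set of
  longrange mode a superset of default mode on any input, not only on
  fully proper-paired libraries.
* **diploid** — haplotypes over 2..N consecutive candidate sites.
  `max_len = 2` is *defined* as the two-site collector and reproduces
  default-mode counts exactly. For `max_len ≥ 3` each read contributes
  maximal runs of the sites it resolves (a run is emitted only when it
  extends past the previously emitted run), so sub-haplotypes of an
  emitted haplotype are not double-counted, while window- or
  read-truncated shorter haplotypes still appear. A defensible
  alternative semantics would emit, per starting site, the maximal run
  from that site even when contained in an earlier run; we chose
  containment suppression because it keeps counts interpretable (one
  observation per read per locus region) and keeps N = 2 consistent
  with the default mode. Filtering generalizes position-wise: an
  accession shows the pattern when its retained equal-length haplotypes
  share ≥ 1 invariant position and ≥ 1 varying position.

### Genotyping

Founder accessions recorded on a marker are grouped by identical retained
haplotype sets. A haplotype appearing in more than one group is
**non-diagnostic**: this covers the homeolog-shared haplotype (present in
all founders) and, under partial sampling, haplotypes retained by some
but not all founders, which cannot separate them. Each group's remaining
group-unique haplotypes form an allele class ("A"/"B" for two classes,
ordered by lexicographically smallest founder; class indices otherwise).
An individual is re-collected at the marker's site pair (same mode as
discovery), retained with `min_depth`/`minor_ratio`, and called by which
classes its diagnostic haplotypes hit: one class → that code, several →
"H", none → ".". Retained haplotypes matching no class (e.g. error
haplotypes) are ignored rather than forcing a missing call; this keeps
missingness monotone in `min_depth`. Reported depth is the number of
retained observations supporting the hit classes, so every non-missing
call is backed by ≥ `min_depth` observations. The heterozygous ("H")
handling is a documented package choice; biparental inbred populations
should see it rarely.

## Simulator

The generator emulates the collapsed-mapping biology directly in the
coordinate system of the ancestor:

* ancestor sequence uniform over A/C/G/T of length `ancestor_length`;
* subgenome B differs from the ancestor by per-base substitutions at
  `homeolog_divergence` (these positions are the anchors);
* per accession, subgenome A carries accession-specific spiked SNPs —
  either `n_snps` placed uniformly within `snp_anchor_dist` of a random
  anchor (each assigned to one random accession), or per-base at
  `snp_rate`;
* paired 2×`read_length` reads per subgenome at `coverage` fold each,
  insert ~ Normal(`insert_mean`, `insert_sd`) clipped to [2·read_length,
  L], per-base substitution errors at `error_rate`, constant base quality
  40, MAPQ 60;
* alignment is positional (substitution-only, all-match CIGARs at the
  true origin), so every downstream observation is attributable to the
  truth table rather than to a mapper's decisions;
* candidate sites: any position where ≥ 2 distinct bases are each seen
  ≥ 2 times summed over all accessions' reads — a deliberately unfiltered
  stand-in for an mpileup call set (the CLI accepts real mpileup VCFs).

Defaults are the package's reference study conditions: 20 kb ancestor,
divergence 0.01, 3 accessions, 40 anchored SNPs within 140 bp, 2×150 bp
paired reads at 20× per subgenome, error 0.002, insert 500 ± 50 bp (a
typical WGS library; neither condition set specifies one). All draws
come from one `numpy` generator seeded by the mandatory `seed`, and
outputs are byte-identical across runs of the same configuration.

What the simulator does **not** model: indels and structural variation
(and hence CIGAR complexity and realignment ambiguity), mapping errors
and repeat-induced mismapping, quality-score variation along reads, GC or
coverage bias, residual heterozygosity, and more than two subgenomes.
Passing tests on simulated data therefore demonstrate the counting and
filtering logic under controlled truth, not robustness to real-data
mapping artifacts — on real data the dominant failure mode is repetitive
or mismapped probes, which no within-pipeline filter can fully detect.

### Evaluation

For marker calls: a spiked SNP is *discoverable* when its position is in
the candidate set and at least one candidate anchor lies within the
window; it is *recovered* when a called marker pairs it with an anchor.
TPR = recovered / discoverable (vacuously 1 when nothing is
discoverable). FPR = called fraction of pure-homeolog candidate pairs
(both sites anchors, neither a SNP, within the window). For the naive
coverage-filter straw man (per-accession site calls with ≥ 2 alternate
reads and depth inside `[low_x, high_x] ×` expected coverage — the
default multipliers reproduce the 4–15 read band at 10×), TPR is the
fraction of spiked SNP records called in their carrier and FPR the
fraction of anchors called anywhere.

## Numerical and design choices

* Coordinates are 1-based everywhere user-facing (VCF convention);
  0-based arithmetic is internal to the pysam layer.
* Quality floors default to MAPQ ≥ 20 and base quality ≥ 13 (common
  mpileup practice; the filters' source description states none), both
  configurable. Duplicate/secondary/supplementary/QC-fail alignments are
  excluded.
* VCF records with a non-single-base REF are skipped; non-single-base
  ALT alleles are dropped and the record kept if a SNP allele remains.
  Duplicate (chrom, pos) records collapse with an allele union.
  Multiallelic sites flow through unchanged (haplotype strings are
  base-literal).
* The ratio threshold comparison is `count ≥ minor_ratio · max_count`
  with floats; at the default 0.25 both sides are exact in binary.
* Ties and orderings (output rows, marker sort, allele-class codes) are
  all resolved lexicographically/deterministically; a rerun on identical
  inputs is byte-identical.
* `--threads` is accepted for interface stability but execution is
  serial: work partitions cleanly by chromosome and a merge would
  preserve sort order, so parallel output would be identical by
  construction; at the problem sizes this package targets in testing
  (tens of kilobases to small genomes) serial execution is not the
  bottleneck.
* Test and acceptance problem sizes (20 kb locus, 3 accessions, 10–20
  seeds) were chosen as the smallest scale at which anchor density,
  window geometry and sampling noise all act at realistic strength.

## Known limitations

* Threshold monotonicity ("stricter thresholds never create markers")
  holds in the two-haplotype regime but **not** universally once an
  accession retains ≥ 3 haplotypes: pruning a third haplotype can turn a
  patternless accession into a pattern-showing one. The property test
  asserts monotonicity in the two-haplotype regime only.
* Autopolyploids are out of scope (no dosage model); higher-order
  allopolyploids work only insofar as one contrasting haplotype exists
  while the remaining subgenomes agree.
* No statistical genotype likelihoods or error-model estimation: the
  filters are exact counting rules, which is what makes them auditable.
* Discovery requires a polymorphism to lie within the window of an
  anchor; genome fraction within reach scales with anchor count times
  twice the read length (see `anchor_reach`), an upper bound that
  ignores window overlap.
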