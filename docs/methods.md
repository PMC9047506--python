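# Methods

This note documents the models behind `bulkscan`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Experimental design being modelled

Two fully homozygous inbred parents (labelled XAP1 and AYP1) differ at a
set of biallelic SNPs. Their F2 progeny segregate 3:1 for a fully
penetrant recessive sterility allele at a single locus. From an F2 of 200
plants, the 30 most clearly sterile (bulk BY) and 30 fertile (bulk KY)
plants are pooled and whole-genome sequenced to ~30x per bulk, the parents
to ~10x; spike RNA of the four groups (both parents, both bulks) is
sequenced in three replicates each. The analysis starts from per-sample
allelic depths (VCF `AD` fields) and a gene-level count matrix — upstream
read alignment and variant calling are out of scope.

## Synthetic data generator

* **Genome.** Uniform-random reference sequence per chromosome; default a
  single 5 Mb chromosome. Protein-coding genes (default 40 per
  chromosome) are laid on a slot grid on both strands, each with UTRs, an
  optional single intron, and a CDS that starts with ATG, ends with a stop
  and contains no internal stop — so full-protein retranslation is a valid
  oracle for the annotator. The causal locus (default 2.5 Mb) is hosted
  inside a gene whose reference codon is engineered so the alternate
  allele creates a premature stop.
* **SNPs.** Poisson-placed at `snp_density` (default 4e-4/bp, ~2,000 on
  the default genome); at every SNP the two parents are homozygous for
  opposite alleles, with the alt-carrying parent drawn at random. The
  causal SNP's sterile allele comes from `causal_origin` (default AYP1 —
  which parent donates it is a free design choice, not a data fact).
* **Meiosis.** Haldane model: crossovers per gamete per chromosome are
  Poisson(map length in Morgans) with uniform positions and no
  interference — the simplest model consistent with an F2 design. The
  default `recomb_rate` of 20 cM/Mb is a desk-scale choice: it gives the
  5 Mb chromosome a realistic *whole-chromosome* map length (100 cM)
  rather than a realistic per-Mb rate, so linkage decays within the
  simulated chromosome the way it decays within a real one.
* **Phenotype.** Sterile iff both chromosomes carry the causal-origin
  allele at the causal position; a `phenotype_error` rate (default 0) is
  exposed because bulk contamination by misphenotyped plants is the
  realistic failure mode. With no causal locus configured, phenotypes are
  independent Bernoulli(1/4) draws, making the bulks random subsets — the
  no-QTL null used for calibration.
* **Sequencing.** Per sample and site, depth ~ Poisson(mean depth) and
  alt reads ~ Binomial(depth, f') where f is the sample's true alt
  frequency and f' = f(1-e) + (1-f)e applies the per-read miscall rate e
  (default 1e-3). Allelic depths are the terminal output — no read-level
  or BAM synthesis — because that is where the analysed pipeline's own
  computation begins.
* **Expression.** Counts are negative binomial with lognormal baseline
  means, gene-level dispersion (default 0.1, typical for inbred-line
  RNA-seq), and a signed log2 fold change applied to the BY group for DE
  genes. The default truth concentrates DE near the causal locus: the
  causal gene itself at -2.5 (silenced by the premature stop), ~6 linked
  neighbours and ~20 background genes at |lfc| 1.5-3.
* **Determinism.** One integer seed, split per stage with
  `SeedSequence(seed, spawn_key=(stage,))`; identical seeds give
  byte-identical outputs.

What the generator does *not* emulate: mapping bias and paralogy,
indels/structural variants, base-quality structure, multi-locus or
quantitative sterility, library-preparation batch effects, and real
linkage-disequilibrium/annotation structure. Passing tests therefore
demonstrate the *procedure* is correct and calibrated under the stated
model, not that any particular real-genome result is reproduced.

## SNP index and filters

The SNP index is computed relative to a configurable *high parent*'s
allele, resolved from the parents' own read counts — not from VCF ref/alt
identity, since the reference line is neither parent. Filters, applied in
a fixed order with a rejection tally:

1. **parent** — both parents covered, effectively homozygous (minor-read
   fraction <= 0.1, a read-level stand-in for genotype calls) and carrying
   different alleles. An alternative `progeny` reading (drop sites looking
   heterozygous in both bulks instead) is available behind a flag because
   the underlying filtering convention is genuinely ambiguous; the parent
   rule is the default as the standard QTL-seq practice.
2. **depth** — fewer than 7 reads in either bulk.
3. **low-index-both** — SNP index < 0.3 in *both* bulks (such sites are
   likely shared artifacts; an index < 0.3 in only one bulk is signal,
   not noise). Thresholds are strict inequalities.
4. **no-coverage** — any remaining undefined index. An index at zero
   depth is `None` and flagged, never coerced to 0.

## The null band

"Permutation" screening of delta(SNP index) is implemented as the
depth-conditional simulated null of the QTL-seq tradition, because a
label permutation of two pooled samples is undefined at a single site:
each of the 1,000 replicates draws an F2 bulk allele frequency
(Binomial(2·30, 1/2)/60) and then reads at the site's observed depth, per
bulk independently. Bands are cached per distinct (depth_BY, depth_KY)
pair — low-coverage sites get appropriately wider bands — with a
deterministic per-pair RNG stream so results are independent of scan
order. Quantiles use the `inverted_cdf` rule: the band endpoints are
always points of the discrete null support, the band is conservative by
construction, and the Monte-Carlo band is exactly comparable to
brute-force enumeration (which the tests do for n_bulk <= 2, depth <= 3).
A per-site read-permutation null (hypergeometric redeal of the pooled
reads) is available as an alternative.

Merging: candidate sites closer than `merge_gap` (1 Mb) on a chromosome
form a region; regions with fewer than `min_sites` (3) members are
dropped. Both values are exposed — region-boundary rules are a reporting
convention, not an estimand. A sliding-window mean of delta (1 Mb window,
10 kb step) is provided for plotting only; calling is site-wise.

## Variant-effect annotation

Coordinates are 1-based inclusive on disk (GFF3, VCF) and converted to
0-based offsets only inside the genome module. For a CDS hit the
alternate base (complemented on minus-strand genes) is substituted into
the spliced CDS and the affected codon retranslated with the standard
genetic code; stop-gain means the mutant amino acid is a stop and the
reference is not, stop-loss the reverse. Exonic sites outside the CDS are
reported as `utr`, kept distinct from coding categories. Splice-site
disruption is not modelled (intron edge bases stay `intronic`), and only
one transcript per gene is supported. Classification is total: every site
receives exactly one category, and a reference-allele mismatch is a hard
data-integrity error rather than a silent skip.

## Differential expression

A from-scratch moments/Wald negative-binomial test, chosen over wrapping
a shrinkage estimator: with three replicates per group the
method-of-moments dispersion (pooled *within-group* variance over the two
groups of a contrast, floored at 1e-8) is transparent, fast, and directly
checkable against simulation truth. The Wald statistic compares
median-of-ratios-normalized group means under NB variance mu + alpha·mu²,
two-sided normal p-value; log2 fold changes use a 0.5 pseudocount per
mean so zero-mean genes stay finite; all-zero genes are marked
untestable with p = 1. The raw Wald p is anticonservative at n = 3
(~10% below 0.05 under the null in our simulations) — which is why calls
are made on BH-adjusted p < 0.05 *and* |log2FC| > 1, a combination that
is well controlled in the calibration tests. A raw-p mode exists behind a
flag since the underlying thresholding convention is ambiguous; adjusted
is the default because BH correction is explicitly part of the modelled
workflow. "Up" means higher in the sterile bulk BY. Shared DEGs are the
three-way intersection of same-direction calls, which makes the empirical
false-discovery rate of the shared sets far stricter than any single
contrast. FPKM = count·1e9/(length·library total) is computed from
spliced exon lengths and used for reporting per-group expression.

## Enrichment

Flat one-sided hypergeometric over user-supplied term→gene maps:
p = P(X >= k) with X ~ Hypergeom(N, K, n), BH across terms. This is a
deliberate desk-scale simplification — no ontology-graph propagation and
no gene-length bias weighting, both of which depend on external resources
the package does not ship. Query genes outside the universe are dropped
with a warning.

## Integration and reporting

The chi-square segregation test is plain Pearson with df = 1 and no
continuity correction (the conventional form for a 3:1 comparison against
the 3.84 critical value); Yates correction is available behind a flag,
and the critical value is computed from the chi-square quantile function,
never hard-coded. The conjunctive candidate set is the intersection of
region-gated consequential-variant genes with the shared DEGs, each row
carrying direction, worst variant effect and per-group mean FPKM.
2^-ddCt relative expression is provided for qPCR follow-up arithmetic.
The pipeline writes machine-readable TSVs plus a human-readable text
report, with no timestamps, so fixed seeds reproduce byte-identical runs.

## Problem sizes used in validation

The test suite and acceptance script run entirely on generated data at
desk scale, chosen to keep every stage's statistics interpretable: null
band coverage on no-QTL genomes of ~2,000 SNPs spread over nine 5 Mb
chromosomes (nine independent linkage groups decorrelate the
chromosome-level allele-frequency drift that dominates single-chromosome
variability); causal-locus recovery over 50 independent single-chromosome
experiments at the default design; DE calibration on 2,000-gene null and
50-gene spiked matrices. Tolerances on stochastic checks are three
Monte-Carlo standard errors estimated from the replicates themselves.

## Known limitations

* The window between "every site linked" and "no site flagged" depends on
  total map length; very short chromosomes make the candidate region span
  most of the chromosome, which is faithful to the genetics but blunt.
* The moments dispersion is noisy at n = 3 and the Wald raw p-values are
  anticonservative; inference should always go through the adjusted
  calls, as the defaults do.
* One transcript per gene; no indel, splice-site or regulatory-variant
  effects.
* The enrichment stage treats annotations as flat and exchangeable.
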