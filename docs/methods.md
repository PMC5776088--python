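# Methods

## Problem and model

RNA editing — most commonly adenosine-to-inosine (A-to-I) deamination by
ADAR enzymes, read as guanosine by sequencers — produces sites where a
transcript differs from the genome that encoded it (RNA–DNA differences,
RDDs). `editomescan` detects such sites from matched whole-genome and
transcriptome evidence of the same individual, then characterizes the
editome across four samples representing stages of liver-cancer
progression: non-cancerous liver (NL), primary tumor (PT), intrahepatic
metastasis (IM), and portal vein tumor thrombus (PTVV).

The detection cascade, per sample:

1. **Caller merging.** Variants come from two callers per modality. DNA
   call sets are merged by *union* (germline variants should not be missed,
   or they masquerade as editing); RNA call sets by *intersection* (an RNA
   variant must be reproducible across callers). When both callers report a
   site, depth and support take the maximum and the genotype comes from the
   deeper caller.
2. **RDD identification.** An RNA variant is a candidate iff its genotype
   differs from the DNA genotype at that position. Where no DNA variant was
   called, the DNA genotype is homozygous reference — but only if DNA
   coverage at the position reaches the minimum depth; otherwise the
   genotype is unknown and the site is discarded as DNA-uncovered. Sites
   whose RNA evidence displays more than one non-reference base type are
   removed.
3. **Evidence filters.** A candidate survives iff (a) the minimum Phred
   quality among variant-supporting observations is ≥ 20, (b) covered depth
   ≥ 5 reads, (c) the minimum over supporting observations of the nearer
   read-end distance is ≥ 15 bases, and (d) there are ≥ 2 supporting reads.
   Removal is charged to the first failed filter in that order for audit
   purposes; survival itself is a conjunction and order-independent.
4. **Germline subtraction.** Any surviving site whose position appears in a
   known-polymorphism table (dbSNP-style VCF or position list) is removed,
   allele-agnostically.

Detected sites are then annotated against gene models (a site must overlap
transcripts of exactly one strand; strand-ambiguous and intergenic sites
are discarded), typed on the transcribed strand (a genomic T-to-C on a
minus-strand transcript is an A-to-G event), given a gene-region label and
a repeat context (Alu / repetitive non-Alu / non-repetitive), and
classified by their presence across the four samples into seven patterns:
ALL (all four), STN (NL plus some but not all tumors), ST (two or three
tumor samples, no NL), and the four sample-unique labels. The fifteen
non-empty presence subsets partition exactly into these seven labels; a
site is *stage-specific* when its pattern is not ALL.

Functional impact:

- **miRNA-target enrichment.** For 3′UTR sites, a one-sided hypergeometric
  test at base resolution: the universe N is the union length of all
  3′UTR intervals, K the target-covered bases within it, n the number of
  3′UTR sites, k those inside targets; p = P[X ≥ k]. Base resolution is the
  natural null for positional overlap: each 3′UTR base is a trial. miRNAs
  are additionally ranked by the number of distinct edited target sites
  (ties broken lexicographically); a site hitting targets of several miRNAs
  counts once toward k but once per miRNA in the ranking.
- **Recoding.** CDS sites are mapped to spliced CDS coordinates honoring
  strand, the codon is substituted and translated with the standard genetic
  code; an amino-acid change makes the site non-synonymous. Transcripts
  whose spliced CDS length is not divisible by three are flagged and
  skipped. External damaging/tolerated annotations are joined, never
  computed.
- **Expression change.** For each tumor sample, transcripts edited there
  but not in NL are grouped by category (UTR5, CDS, miRNA-target 3′UTR,
  non-target 3′UTR, intron); each category's distribution of
  log2((FPKM_tumor + ε)/(FPKM_NL + ε)) is compared with the background of
  all expressed transcripts by a two-sample Kolmogorov–Smirnov test
  (two-sided, asymptotic p-value). ε = 0.01 FPKM admits zero-expression
  transcripts.
- **Gene lists.** Per sample, genes carrying ≥ 1 damaging non-synonymous
  site present in that sample are emitted one-per-line for external GO /
  pathway tools.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| min_base_qual | 20 | Phred | supporting bases must be confident calls |
| min_depth | 5 | reads | genotypes below 5x are unreliable |
| min_end_distance | 15 | bases | read ends are alignment-error prone |
| min_alt_reads | 2 | reads | a single read is indistinguishable from error |
| FPKM ε | 0.01 | FPKM | pseudo-count for the log-ratio |

## Synthetic data generator

The generator emulates the statistical structure of the four-sample design
with full ground truth: a random toy genome (2 × 100 kb by default),
36 non-overlapping stranded multi-exon transcripts (75% coding, with
frame-consistent CDS and derived UTRs), Alu-like and non-Alu repeats
(Alus preferentially placed inside transcripts, where A-to-I editing
concentrates), 60 germline SNPs (70% heterozygous), and 300 editing events
with per-sample presence patterns drawn from a seven-pattern prior
dominated by stage-specific events (ALL weight 0.07), editing rates
uniform on (0.3, 0.6), and 80% A-to-I on the transcribed strand
(minus-strand events are written as T-to-C in genome coordinates).

Evidence is generated directly as pileups, not reads: each observation
carries a base, a Phred quality (97% in 30–40, 3% in 10–19), and a uniform
read placement along a 90-bp read, so end-distance filtering has real
effect. Sequencing errors replace the true base uniformly at rate 0.005.
RNA coverage of a position scales with a per-(transcript, sample)
expression factor (lognormal, mean 1, σ = 0.9) that also produces the FPKM
table — as in real RNA-seq, lowly expressed transcripts are shallowly
covered. DNA coverage is uniform at its mean (30×). Two caller VCF pairs
are derived from the same pileup by a naive threshold caller with
different sensitivity knobs (minimum allele fraction 0.02 vs 0.10;
homozygous call at fraction ≥ 0.85), so the union/intersection merge rules
have observable consequences.

What the generator does *not* emulate: alignment and mapping artifacts,
strand-specific library errors, indels, quality-score correlation along
reads, hyper-edited clusters, and overlapping gene models (transcripts are
placed disjointly, so strand-ambiguity discards are exercised by dedicated
unit fixtures, not by the default dataset). Passing tests therefore
demonstrate the correctness of the decision logic on clean evidence, not
robustness to alignment noise.

## Ground-truth evaluation

Under the strict end-distance rule, a planted event is only recoverable
when *every* supporting read lies ≥ 15 bases from both read ends; with
uniform placement the chance of that decays as (2/3)^k in the number of
supporting reads. Sensitivity is therefore measured over *eligible*
(site, sample) pairs: planted present, RNA pileup passing all four filters
for the planted allele, and DNA covered at the minimum depth — the same
predicate the pipeline applies, validated independently against a
brute-force oracle. Precision counts detected (site, sample) pairs that are
planted present; germline leakage counts detected positions that coincide
with planted SNPs (expected: zero, since the SNP table lists every planted
SNP). Pattern assignments are a deterministic function of detected
presence; for sites whose full planted presence set is recovered, the
assigned pattern must equal the planted pattern.

## Numerical and design choices

- Coordinates are 1-based inclusive internally (VCF/GTF convention); BED is
  converted on read.
- Site identity across samples is (chrom, pos, ref, alt, strand): two
  different substitutions at one position are distinct events.
- Region precedence across same-strand overlapping transcripts is
  CDS > UTR3 > UTR5 > Exon > Intron, then coding over lncRNA at equal
  labels, then lexicographic transcript id; a site is counted once, never
  per isoform.
- The multi-alternate rule counts alternate alleles with ≥ min_alt_reads
  supporting observations, so one stray error read cannot kill a true site.
- A candidate with zero supporting observations passes the (vacuous)
  quality and end-distance minima and is charged to the support filter.
- Every RNG stream is seeded from the dataset seed plus a per-component
  tag (CRC32), so regeneration is reproducible per file and byte-identical
  across processes.
- Default problem sizes (2 × 100 kb genome, 300 events, 30× depth) keep a
  full run around two seconds while every stage still receives non-trivial
  input.

## Known limitations

- The naive internal caller is a stand-in for exercising merge semantics;
  it is not a reimplementation of GATK or VarScan, and real caller VCFs
  will differ in genotype quality modeling.
- The seven-pattern classification reflects detected presence; shallow
  coverage in one sample can demote an omnipresent site to a partial
  pattern. This mirrors the behavior of any presence/absence editome
  analysis at finite depth.
- The hypergeometric universe assumes uniform site placement over 3′UTR
  bases; sequence-composition biases (A-richness of editable contexts) are
  not modeled.
- KS p-values are asymptotic and approximate for very small categories;
  categories below two transcripts are skipped outright.
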