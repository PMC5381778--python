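# Methods

## Gene model and coordinate arithmetic

A gene is a single transcript on one strand of a contig: 1-based inclusive
exon intervals (VCF/GFF3 convention) plus a CDS span.  Internally the
spliced CDS is addressed by 0-based offsets in transcript orientation; for
a minus-strand gene, offset 0 is the highest-coordinate CDS base and every
base is complemented.  `genomic_to_cds` / `cds_to_genomic` are exact mutual
inverses on the CDS domain and are tested exhaustively on fixture-sized
genes.  Translation uses the standard genetic code (Biopython); residues
are numbered with the initiator Met as residue 1 — the convention under
which the sickle mutation is written Glu7Val (classically Glu6Val).

Splice windows follow the convention of mainstream effect annotators and
are configurable: intronic bases 1–2 after an exon (transcript
orientation) are the donor site, the last 2 intronic bases before an exon
the acceptor site, and exonic bases 1–3 or intronic bases 3–8 from a
junction the splice region.  Donor/acceptor sites are always intronic and
never double-counted as splice region.

## The bundled HBB-like locus

The bundled cohort reconstructs a published survey of *HBB* variation in
the 1000 Genomes phase-3 call set.  The survey gives hg19 variant
positions and their consequence labels but no exon boundaries, so the
fixture's exon layout is reverse-engineered from the splice labels, which
pin it uniquely and agree with the real *HBB* annotation:

* exon 1 CDS 5,248,160–5,248,251 (c.1–92: codons 1–30 plus two bases of 31),
* exon 2     5,247,807–5,248,029 (c.93–315),
* exon 3     5,246,831–5,246,956 (c.316–441),

on the minus strand — 441 coding bases, 146 residues + terminator.  All 20
variant-to-codon assignments are then forced (e.g. 5,248,232 → c.20,
codon 7; 5,248,029 → c.93, codon 31 with splice-region overlap; donor
5,248,159 and acceptor 5,248,030 flank intron 1).

The reference contig is synthetic.  Only what the survey pins down is
fixed: REF alleles at variant positions, the residues/codons of variant-hit
codons (codon 31 is pinned to AGG specifically, since the equally Arg
codon CGG would make the published Arg31Ser change synonymous), and
canonical GT/AG intron dinucleotides.  All other bases are seeded-random,
so the fixture protein is *not* β-globin outside the constrained sites —
deliberate, to avoid shipping or reconstructing the real sequence while
still making every published consequence derivable.  One published label
is internally contradictory ("Glu30Gly" for a change the survey itself
calls synonymous, at a site no Glu codon fits); the fixture encodes the
synonymous Gly30Gly and keeps the published text only as metadata.

## Consequence annotation

SNVs in the CDS are classified by comparing reference and alternate codons
after strand adjustment (same residue ⇒ synonymous; terminator ⇒
stop_gained; else missense).  A length-changing variant whose net length
difference is not a multiple of 3 is a frameshift, labelled at the first
CDS codon containing a changed base — the rule that renders the anchored
deletion CAAAG→C as Phe42fs.  Splice-window membership of any changed base
adds the corresponding splice terms; wholly intronic variants get
{intron} plus any window terms; variants outside the gene are intergenic.

Degenerate inputs: REF alleles are verified against the contig and a
mismatch raises (corrupted input); in-frame (multiple-of-3) indels raise a
clear error — the consequence vocabulary deliberately has no in-frame
term and residue-level indel naming is out of scope.  A substitution that
destroys the terminator is reported as missense (no stop_lost term), and
identically by both classification routes.  Variants spanning an
exon–intron junction collect all windows they touch.

The test-oracle route (`classify_by_full_translation`) applies the edit to
the whole contig, shifts the model's coordinates across the edit,
re-splices and re-translates both alleles, and reads the consequence off
the whole-protein diff — no shared codon arithmetic.  The suite checks
agreement on all bundled variants and on ≥1,000 seeded random gene/variant
pairs across strands, plus strand-mirror invariance (reflecting gene,
contig and variant onto the opposite strand changes nothing).

## Pathogenicity consensus

Sources form two classes: clinical databases (ClinVar, dbSNP, HbVar) and
predictors (PolyPhen, PROVEAN, SIFT, PANTHER, MutPred).  Raw labels
normalize as Damaging / Probably damaging → damaging, Benign → benign,
Other → uninformative, not-evaluated → absent.  "Other" counts as
uninformative rather than benign because rows carrying it resolve on their
remaining labels.

The survey names its four evidence pieces but not the combination rule.
The default rule here is class-wise strict majority over informative
labels (tie or no informative label ⇒ NoCall), then: agreement or one
silent class ⇒ that call; both silent ⇒ NotEvaluated; disagreement ⇒
Conflict.  This reproduces 15 of the 16 published conclusions; the single
residual row (rs33912272, computed Benign, published Conflict) ships as an
explicit, flagged override rather than a guessed rule change — no single
rule can reproduce both that row and rs1135071's published Damaging (which
tolerates one benign database).  The Damaging-variant count (11) does not
depend on the override.  A stricter `unanimous` strategy (any informative
disagreement ⇒ Conflict) is available for sensitivity analysis.
Pure-synonymous variants are excluded from evaluation entirely.

Invariants under test: verdicts are stable under source permutation within
a class and under insertion of uninformative/absent labels, and flipping a
benign predictor to damaging never moves a Damaging verdict to Benign.

## Cohort statistics and display conventions

Allele counts take 1 per heterozygote and 2 per homozygous-alternate
sample (the bundled cohort contains only heterozygotes, but dosage 2 is
supported).  Frequencies are exact integer ratios.  Two printing
conventions coexist in the survey tables and are reproduced separately,
with exact values always available: per-variant allele frequencies and
cohort percentages are *truncated* (floored) — 137/5008 = 0.027356 prints
0.02735, 209/2504 = 8.346% prints 8.34% — using integer arithmetic, never
binary floats; the pooled gene frequency and its square are *rounded*
(209/5008 = 0.04173 prints 0.042).

The Hardy–Weinberg projection pools all mutant alleles into one frequency
q = (total mutant alleles)/(2N); under random mating the probability that
an offspring draws two mutant alleles — homozygous or compound
heterozygous for the class — is q².  Restricted to Damaging-verdict
alleles, q_d² × 10,000 ≈ 14 is the projected hemoglobinopathy rate per
10,000 births.  A per-variant Σq_i² refinement would exclude
cross-variant compound heterozygotes; the pooled model is the one the
survey's headline uses and is what the package reports.  A Monte-Carlo
random-mating simulation (10⁵ offspring drawn from the cohort allele
pool) agrees with q² within 3 standard errors in the suite.

## Synthetic cohort generator

`simulate_cohort` assigns carriers by cutting a seeded permutation of each
population into consecutive blocks, one per variant — every carrier gets
exactly one variant, matching the survey where per-variant carrier counts
sum exactly to the carrier total.  Genotypes are unphased 0/1 (phase is
never used).  Default population sizes are 661/347/504/503/489
(AFR/AMR/EAS/EUR/SAS, the 1000 Genomes phase-3 super-population sizes,
summing to 2,504); they are configurable.  The same seed yields
byte-identical files.

What the generator does *not* emulate: linkage disequilibrium, realistic
site-frequency spectra, mutation/recombination processes, genotyping
error, missing genotypes, or multi-variant carriers.  Passing tests
therefore demonstrate the correctness of the arithmetic and the pipeline
plumbing on survey-exact inputs, not robustness to the noise structure of
real call sets.

## Numerical and design choices

* Coordinates 1-based inclusive externally, 0-based CDS offsets
  internally; all I/O through standard formats (FASTA/GFF3/VCF v4.2 via
  Biopython, gffutils and pysam; TSV via csv/pandas).
* Truncation via integer arithmetic (`n * 10^k // d`), immune to float
  representation at the printed precision.
* The constrained-reference solver enumerates the 64 codons per position,
  filters by amino-acid/codon constraint and per-base REF constraints,
  forbids internal stops, and picks among survivors with the seeded RNG;
  unsatisfiable combinations raise immediately.
* Problem sizes in the suite: the full 2,504-sample cohort for all
  cohort-level numbers (it is desk-scale); toy genes of 10–30 codons for
  the ~1,000-pair annotator/oracle cross-check; 10⁵ offspring for the
  mating simulation.

## Known limitations

Single transcript per gene; no UTR, promoter or regulatory annotation
(gene models are expected with exons == CDS); no stop_lost/start_lost or
in-frame-indel terms; no confidence intervals on frequencies; no
inbreeding correction (the q² projection assumes random mating and
panmixia — continental substructure makes it an underestimate for
geographically clustered alleles like HbS); predictor scores themselves
are consumed as labels, never computed.
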