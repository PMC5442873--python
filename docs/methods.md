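# Methods

`msikit` re-implements, as a tested pipeline, the computational analysis
of deeply sequenced microsatellite-unstable (MSI+) colorectal tumors:
somatic-call filtering, MSI scoring, homopolymer hotspot genotyping,
mutation-signature exposure fitting, allele-specific copy-number/LOH
harmonisation, VAF-based clonality classification, and patient-specific
neoantigen enumeration.  Because the kind of matched tumor-normal exomes
this analysis runs on are controlled-access, the package ships a
synthetic cohort generator with complete ground truth; every stage is
validated by parameter recovery against that truth and by brute-force
oracles, not against patient data.

## Somatic-call filtering (`msikit.variants`)

A call is retained when all of the following hold, evaluated in order
(the first failing rule is recorded as the rejection reason):

1. normal coverage >= 10 reads,
2. tumor coverage >= 15 reads (zero tumor depth is reported as
   `no_coverage`, never a division error),
3. tumor VAF >= 5% — the threshold is inclusive: the filter removes
   loci where *fewer than* 5% of reads support the mutation, so exactly
   5% is a keep,
4. at most one mutated read in the normal (allowing minute contamination
   or circulating tumor DNA).

Coverage is defined as ref + alt reads at the locus.  Multi-allelic VCF
records are decomposed into bi-allelic variants sharing the reference
depth, and indels are left-aligned before classification, since VCF
dialects differ.  Effects are classified against one canonical,
intron-less transcript per gene (strand-aware codon translation; indel
length mod 3 distinguishes frameshift from in-frame).  The mutation load
partitions retained calls into amino-acid-affecting (nonsynonymous,
stopgain, frameshift, splice), silent (synonymous, in-frame indel) and
noncoding classes; splice SNVs are counted as affecting but tallied
separately so the opposite convention is recoverable.  The
affecting:silent ratio is reported as missing when the denominator is
zero.

## MSI scoring (`msikit.msi`)

The microsatellite catalogue contains every maximal tandem repeat with
primitive unit length 1–5: homopolymers need >= 5 bases, longer units
need >= 2 complete units and a span of >= 5 bases.  Runs are reported
once, under their primitive unit and leftmost start, so `AA` never
appears as a unit and rotated duplicates are impossible.  The scanner is
vectorised (per-period equality arrays); tests compare it against an
independent regex oracle.

Per locus, paired tumor/normal read histograms over observed repeat
lengths are compared with a chi-square test on pooled length categories
(categories with expected count < 5 are merged into their smaller
neighbour), following the approach of repeat-length-distribution MSI
callers; Fisher's exact test on a 2x2 collapse (modal normal length vs
other) is available as an alternative backend.  A locus needs >= 20
reads in both tissues to be scored.  Because the original description
says only "significantly different", the significance machinery is an
explicit knob: Benjamini–Hochberg FDR control at 0.05 across the scored
loci of a sample is the default.  The MSI score is
100 x unstable / scored; zero scored loci yield a missing score with a
warning, never 0.

## Hotspot indels (`msikit.hotspots`)

Coding homopolymers of >= 6 bp are scanned per CDS with codon-interval
mapping in the annotated reading frame.  A site is scorable in a sample
only with >= 7 spanning reads; it is called mutated when
indel-supporting reads reach both noise knobs (>= 3 reads and >= 10% of
spanning reads — these two cutoffs are this package's choice, exposed as
configuration, since the original screen genotyped hotspots by pileup
inspection without stating one).  Per-gene cohort frequency counts a
sample as mutated if any site in the gene is mutated, over samples with
at least one scorable site.

## Mutation signatures (`msikit.signatures`)

SNVs are tabulated into the 96 trinucleotide classes (pyrimidine-frame
substitution x 5'/3' flanks; purine-reference changes are
reverse-complemented).  Exposures are fitted by non-negative least
squares on the normalised spectrum against a user-supplied catalogue and
renormalised to fractions, with reconstruction cosine similarity
reported; nearest-signature cosine assignment is a secondary mode.  A
small synthetic catalogue (`synthetic_catalogue()`) ships in code so no
download is needed: `mmr_like` mimics the *shape* of the MMR-deficiency
signature (C>T dominated, 5'-G enriched), plus `clock_like`, `flat` and
`transversion` entries.  These are stand-ins with the right geometry for
recovery experiments, not COSMIC profiles.

## Copy number and LOH (`msikit.cna`)

Sample profiles are harmonised by splitting at the union of all samples'
breakpoints (smallest regions of overlap); each region inherits the copy
numbers of its enclosing original segment, and merging equal adjacent
regions reconstructs every input profile exactly (tested).  LOH is
called when the minor allele is at zero copies and the retained allele
has >= 1 copy; copy-number-neutral LOH additionally requires the
retained allele to equal the sample ploidy rounded to the nearest
integer.  The bound on the retained allele is ambiguous in prose
descriptions of this analysis, so it is a flag (`min_retained=2` gives
the stricter reading under which hemizygous deletions are not LOH).
Fraction of genome altered is the percentage of covered base pairs whose
total copy number differs from the rounded ploidy; the denominator is
the covered genome, not a fixed genome length.  Coordinates are 1-based
inclusive internally, 0-based half-open in BED exports.

## Clonality (`msikit.clonality`)

Variants eligible for clustering lie in copy-number-neutral, LOH-free
diploid segments (total 2, minor > 0) and have >= 50 total reads.
Clustering is a binomial mixture on (alt, depth) pairs fitted by EM —
the binomial family is chosen over a beta mixture because read counts
are the observable; both the family and the BIC model-selection
criterion are stated knobs.  Fits are deterministic for a fixed seed
(quantile initialisation plus one seeded restart); clusters holding
< 5% of variants are merged into their nearest neighbour as a
stabiliser.  With aberrant cell fraction ACF (tumor purity, taken from
the segment-profile input rather than re-estimated), a heterozygous
truncal mutation in a diploid region is expected at VAF = ACF/2.
"Approximately ACF/2" is implemented as |mean − ACF/2| <= 0.1 x ACF
(configurable).  The qualifying cluster closest to the target is
truncal; clusters below are subclonal, above homozygous; the clone count
is the number of truncal plus subclonal clusters.  When no cluster
qualifies, the nearest cluster below the target is flagged as the
truncal candidate with a warning — a documented fallback, since the
original analysis does not say how such tumors were handled.

## Neoantigens (`msikit.neoantigen`)

The cascade runs in the stated order: (1) expression filter — keep
mutations whose gene is *strictly* above the per-tumor median expression
across all genes; (2) enumeration of all 8–11mer windows containing a
novel residue (one residue for nonsynonymous SNVs; the frameshifted
stretch to the first stop for frameshift indels), clipped at protein
termini and at the new stop; (3) binding filter — IC50 < 500 nM and a
percentile rank < 2, the rank computed over the pooled set of
(peptide x allele) predictions for the tumor, defined as
100 x (strictly lower predictions)/(pool size) with ties sharing the
lower rank (a per-allele rank mode is a flag, since the pooling wording
is ambiguous); (4) self-proteome exclusion of any peptide occurring
verbatim in the reference proteome; (5) C-terminal cleavage filter
(inclusive at the threshold).  Peptides binding several alleles count
once.  Self and cleavage act on independent per-peptide predicates, so
their order cannot change the survivors (asserted in tests).  The
percentile-rank rule, by contrast, depends on the whole pool: adding
mutations can push a borderline peptide's rank past the cutoff, so the
cascade is monotone only in its per-peptide predicates.

The bundled binding and cleavage predictors are deterministic
position-weight scorers seeded from the allele name and a fixed table
respectively.  They carry no immunological meaning; they exist so the
cascade's logic (pooling, ranking, deduplication, provenance) is exactly
testable offline.  Adapters for external predictors only need the same
`ic50(peptide, allele)` / `predict(batch, allele)` contract.

## Synthetic cohorts (`msikit.simulate`)

The generator emulates, on a scaled-down reference, the data a deeply
sequenced MSI+ cohort provides:

- **Reference**: a 200 kb "concatenated exome" of 120 intron-less
  single-CDS genes built from sense codons, so every wild-type protein
  is stop-free and well defined; homopolymers are planted at 2/kb
  ('C' runs inside CDS — no stop codon contains C, so planting cannot
  truncate a protein — and 'A' runs intergenically), alongside the runs
  that arise naturally in random sequence.
- **Mutation process**: SNV contexts are drawn from the configured
  signature mixture (default 0.8 `mmr_like` + 0.2 `flat`) and placed at
  matching reference trinucleotides; slippage indels of ±1 unit
  (deletion:insertion odds 3:1, as MSI deletions dominate) occur at
  microsatellite loci with probability increasing in run length.  The
  default SNV rate (2,200 per tumor with lognormal dispersion 0.35) is
  calibrated only so that per-tumor amino-acid-affecting loads land in
  the ~1,000–4,600 range such cohorts report; no per-base rate is
  published to match.
- **MSI intensity**: each tumor draws an intensity from U(0.08, 0.35)
  that scales the slippage map (nominal value 0.2), giving cohort MSI
  scores spanning the high-teens on average and coupling the MSI score
  to the indel count, as observed in real MSI+ cohorts.  Instability
  events are truncal with probability 0.85 — MSI arises early, with
  mismatch-repair loss — and otherwise belong to the largest subclone.
- **Clonal architecture**: a linear chain of 2–5 nested clones; the
  truncal clone has prevalence 1.0 and subclones draw well-separated
  prevalences in (0.10, 0.85).  70% of SNVs are truncal.  A heterozygous
  variant in a diploid region has true VAF = 0.5 x purity x prevalence;
  copy-number events rescale it by allele dosage.
- **Reads**: per-variant depths are Poisson around 273x (tumor) and
  109x (normal) with binomial alt counts; histograms add 1.5% per-read
  polymerase stutter (2:1 contraction:expansion).  Normal-tissue mutant
  reads occur at rate 5e-4, so the single-read allowance is exercised.
- **Copy number**: diploid-dominant profiles with 0–2 aberrant segments
  (CN-neutral LOH, hemizygous deletion, or single-copy gain) covering
  2–6% of the genome each, matching the low CNA burden of MSI+ tumors.
- **Expression and HLA**: log-normal per-gene expression independent of
  mutation status (no stronger assumption is warranted), and six class-I
  alleles drawn uniformly from 20 common four-digit alleles.

What the generator does **not** emulate: sequencing error and mapping
artifacts, germline variation, read-level data (no FASTQ/BAM),
subclonal copy number, branching phylogenies (available but not
default), and any real linkage between expression and mutation.
Passing recovery tests therefore demonstrates the correctness of the
analysis logic under the stated statistical model, not performance on
real exomes.

## Problem sizes and numerics

The test suite and the acceptance script run cohorts of 30 tumors on the
200 kb reference with ~2,000 retained mutations per tumor, ~800 scored
microsatellite loci per sample, and clonality recovery over 1-, 2- and
3-clone architectures at 200x with 500 variants per clone — sizes chosen
so that every recovery experiment has comfortable statistical power
while a full run completes in minutes on one CPU.  EM uses a relative
log-likelihood tolerance of 1e-7 with component probabilities clipped to
[1e-6, 1-1e-6]; chi-square pooling merges categories below an expected
count of 5; NNLS is the reference solver from SciPy; ranks, BH
correction and Spearman/Welch statistics come from statsmodels/SciPy.
Degenerate inputs (all-identical VAFs, zero-count spectra, empty
candidate pools, zero scored loci) return single clusters or missing
values with warnings, never exceptions.

## Known limitations

- One canonical transcript per gene; no splice-site modeling (the
  synthetic genes are intron-less, so `splice` never arises there).
- The surrogate predictors make absolute neoantigen counts meaningful
  only relative to each other, not immunologically.
- The chi-square instability test assumes independent reads; real
  pileups have correlated errors, so real-data FDR may differ from the
  nominal 0.05.
- Aberrant cell fraction is consumed, not estimated; a biased upstream
  purity estimate shifts the truncal/homozygous boundary accordingly.
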