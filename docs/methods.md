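# Methods

## The problem

Class I HLA genes (HLA-A, -B, -C) are among the most polymorphic loci in
the human genome. Standard allele-specific copy-number tools work on a
linear reference and routinely mis-handle the HLA region: reads from a
patient's two homologous alleles differ from the reference at dozens to
hundreds of positions, so coverage and B-allele-frequency signals there
are unreliable. `hlaloh` sidesteps the reference by re-aligning reads to
the patient's *own* two allele sequences per gene, cataloguing the
positions where the homologs differ, and reading the copy-number state of
each homolog off the resulting coverage evidence.

## The model

A tumor sample of purity ρ is a mixture of tumor cells carrying
(n₁, n₂) copies of the two homologs and 1−ρ diploid stromal cells
carrying one copy of each. With tumor ploidy ψ normalizing overall
coverage, the model-expected observables at a discriminating site are

    BAF  = (1 − ρ + ρ n₁) / (2(1 − ρ) + ρ(n₁ + n₂))
    2^logR = (2(1 − ρ) + ρ(n₁ + n₂)) / (2(1 − ρ) + ρ ψ)

and the caller inverts these exactly:

    n₁ = (ρ − 1 + BAF · 2^logR · (2(1 − ρ) + ρψ)) / ρ
    n₂ = (ρ − 1 − (BAF − 1) · 2^logR · (2(1 − ρ) + ρψ)) / ρ

The inversion is an algebraic identity; the test suite checks it to
1e-9 over (n₁, n₂) ∈ {0..3}², ρ ∈ {0.2..1.0}, ψ ∈ {1.5, 2, 3}. ρ and ψ
are inputs from an external allele-specific CN tool and are never
re-estimated. The printed form of the n₂ equation in the source
literature is typographically flattened; the form above is the one that
satisfies both the inversion identity and the BAF-independence of
n₁ + n₂, which we treat as the defining properties.

## Procedure

1. **Extraction.** Reads overlapping the three class I windows of GRCh37
   chr6 (29909037–29913661, 31321649–31324964, 31236526–31239869) or
   mapped to the six alternate MHC haplotype contigs are pulled from the
   coordinate-sorted tumor and germline files; reads whose mates were not
   extracted are dropped.
2. **Re-alignment.** Each read is aligned to each of the patient's
   allele sequences. Placement is by bit-parallel edit distance (edlib,
   glocal mode); paths containing gaps are re-aligned under the affine
   scheme (match +1, mismatch −1, gap open −5, extend −1) so a contiguous
   gap counts as one event. Alignments scoring below 80% of read length
   are dropped. Filters then remove reads with more than one
   mismatch/insertion/deletion event and reads whose mate's best
   alignment is on the other homolog (ties are not discarded; a read
   tied between homologs stays in both coverage tracks but carries no
   site-level evidence).
3. **Mismatch catalog.** The two homologs of each heterozygous gene are
   locally aligned (same affine scheme, via Biopython) and every
   substitution column becomes a discriminating site; gap columns do
   not. Genes with fewer than 5 sites are reported insufficiently
   polymorphic. Because local alignment clips terminal mismatch columns,
   a discriminating position at the very end of an allele sequence is
   unrecoverable in principle; the synthetic generator therefore plants
   sites at least 10 bp from the ends.
4. **logR and BAF.** Coverage over both homologs is summed in 150-bp
   bins; per bin, logR = log₂(M · tumor/germline), where the
   multiplication factor M is the germline/tumor unique-read-count ratio
   over the *whole extracted region* — it is a library-size normalizer,
   so the universe behind it must be much larger than any one gene (see
   below). Bins with mean germline depth < 10 are excluded. BAF at each
   site is the homolog-1 share of plain pileup depth from
   homolog-resolved reads.
5. **Copy number and verdict.** Each site's (BAF, bin logR) pair is
   inverted to (n₁, n₂); per-bin medians over sites, then the median
   across bins, give the gene-level homolog copy numbers. Allelic
   imbalance is a two-sided paired t-test on per-site differences
   log₂(t₁/g₁) − log₂(t₂/g₂) using once-per-template depths. A gene is
   called LOH iff the smaller copy number is below 0.5 *and* p < 0.01;
   p < 0.01 alone is imbalance without LOH.

## Counting each template once

The imbalance test assumes the per-site observations are independent.
Two implementation choices follow from that and differ from the naive
reading of "count each read once at its leftmost site":

- **Unit = sequencing template.** A fragment's two mates are one
  molecule of evidence. Counting both mates makes site counts
  overdispersed (variance ≈ 2× Poisson) and correlated, which we
  measured as a null t-statistic with standard deviation 1.5 and a 5–20×
  inflated type-I error. Each template is therefore represented by its
  lowest-numbered mate present — a deterministic choice whose start
  position remains uniformly distributed (representing a template by
  whichever mate comes first in the coordinate order would skew
  representative starts toward the gene start and starve downstream
  sites).
- **Positional partition with even catchments.** Leftmost-site
  assignment gives a site whose predecessor is a few bases away a
  catchment of a handful of reads; such sites have wildly noisy
  log-ratios (killing t-test power) and small-count allele fractions
  whose medians are biased. Instead the read-start axis is cut into one
  contiguous catchment per site. Cuts are confined to the feasible band
  `[site − read_length, previous site]` (so an assigned read always
  covers its site) and relaxed toward equal widths; reads that still
  miss their site fall back to the leftmost covered site. Disjoint
  catchments keep per-site counts independent Poisson; even widths keep
  them comparable. With this construction the null rejection rate at
  α = 0.01 is 0.5–2% over 200 simulated balanced replicates.

## What M normalizes, and the background emulation

M is defined as a ratio of unique mapped read counts over the extracted
region. If the read universe were a single gene, M would cancel that
gene's own copy-number signal (the numerator scales with the gene's
tumor copy number), biasing balanced-but-imbalanced states such as
(1, 2) toward the 0.5 loss cliff. In real data the extraction windows
span 11,285 bp plus the alternate haplotype contigs, so one gene's state
barely moves M. Synthetic patients therefore include copy-number-neutral
background reads covering the non-gene portion of the printed windows;
they align to no allele and only enter the unique-read counts. The
residual self-normalization (a three-gene + background universe is still
finite) shifts, e.g., true (1, 2) at ρ = 0.3 from 1.0 to ≈ 0.96 expected
minor copy number — verdict-preserving in all simulated conditions.

## Tree placement and enrichment

A regional lost-allele copy-number profile c is assigned to a clone-tree
branch by trying every branch: the tree splits into the subtree at the
branch and the remainder, summarized by per-region CCF sums (the 2×n
matrix F), and the best two-component mixture solves
min ‖c − Fᵀb‖² subject to b ≥ 0 and remainder copy number ≥ 0.5 — a
box-constrained least squares (scipy `lsq_linear`; the equivalent QP
form is Dmat = FFᵀ, dvec = Fc). Least error wins; ties go to the more
ancestral branch; a best fit leaving > 25% of ‖c‖² unexplained is
flagged as not fitting the tree rather than patched with extra nodes.
An event is clonal iff detected in every analyzable region.

Focal vs arm-level: minor-allele segments are merged when adjacent with
identical copy number, then a segment spanning ≥ 75% of its arm is
arm-level. Segments use half-open [start, end) coordinates. Cohort
enrichment at a locus is a permutation test: each tumor's genome-wide
probability of (focal or arm-level) loss drives an independent Bernoulli
draw; the p-value is the fraction of 10,000 replicate cohorts with a
loss proportion at least the observed one, floored at 1/10,000.

## Synthetic data: what it does and does not emulate

The generator draws Poisson read-pair counts per homolog (germline:
equal depth per homolog; tumor: weight (1−ρ) + ρnᵢ, total scaled by the
model coverage ratio), uniform start positions, i.i.d. substitution
errors, and plants substitutions/deletions at recorded positions. Mates
of one template come from the same homolog. Defaults describe a
well-powered exome-like experiment: 1 kb genes, 25 discriminating
sites, 100 bp reads, 100× germline depth per homolog, error rate 0.

Not emulated: insert-size structure (mate starts are independent),
quality-score models, GC and mappability bias, alignment ambiguity with
off-target paralogs, and genotype-calling errors upstream. Passing the
recovery grid therefore demonstrates the estimator and filters are
correct under the stated mixture model, not that the caller is robust to
every artifact of real capture sequencing.

## Performance under the study conditions

At the defaults, over a grid of ρ ∈ {0.3, 0.6, 0.9} × states
{(1,1), (0,1), (0,2), (1,2)} with 20 replicates per cell (seed 1):
verdict recovery on the loss states is 95.8%, with zero false LOH calls
in 120 balanced-state runs; every miss is a p-value (power) failure in
the hardest cell, ρ = 0.3 with state (0, 1), where the realized
sampling imbalance of ~1,000 informative templates is of the same order
as the biological signal. The equation inversion is exact to ~3e-15;
solver and 0.01-grid oracle agree on all 50 random trees; the
three-tumor permutation toy reproduces the analytic 0.125 within Monte
Carlo error. These numbers are recomputed, not asserted, by
`scripts/acceptance.py` and the test suite.

## Numerical and degenerate-input choices

- logR uses base 2 throughout; any other base breaks the inversion.
- A t-test difference vector that is identically zero gives p = 1;
  zero variance around a non-zero mean returns a 1e-16 sentinel with a
  warning; fewer than 5 usable sites is indeterminate, never p = 1.
- Sites with any zero once-per-template depth are dropped from the
  t-test (log undefined); sites with zero combined tumor pileup are
  omitted from BAF.
- Homozygous genes are reported as flagged rows, never called.
- Child CCF may exceed its parent by at most 0.05 (pigeonhole
  tolerance); larger violations warn but do not fail.
- All simulation randomness flows through explicit integer seeds; no
  global random state is touched.
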