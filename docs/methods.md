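# Methods

## The generative model

A simulated run is built in three layers.

**Reference** (`simulate.build_reference`).  mRNA lengths are lognormal with
mean 2700 nt (the typical mammalian transcript) and log-sd 0.7, floored at
400 nt; each transcript is annotated 10% 5'UTR / 60% CDS / 30% 3'UTR and
carries a 50 nt polyA tail in the reference sequence.  The spike-in set has
92 species, 250–2000 nt, with known relative concentrations log2-spaced over
a 2²⁰ dynamic range (the order of the commercial mix).  One 4.5 kb rRNA
species without a polyA tail represents ribosomal background.  The default
transcriptome holds 2000 mRNA genes — small enough for desk-scale runs,
large enough that no single gene dominates summary statistics.

**Expression and counts** (`simulate.simulate_expression`).  Baseline mRNA
abundances are lognormal (log-sd 1.5) shared across samples; spike-ins take
a fixed 3% of molecules split proportionally to concentration and are
*identical in expectation across samples before bias* — that exchangeability
is what the plate diagnostic later exploits; rRNA takes 2×10⁻⁵ (the
order observed for oligo-dT-primed libraries).  Condition fold-changes
multiply baseline abundance by 2^log2FC.  Two bias layers follow the plate
workflow: a per-i7-index (per-column) scalar efficiency factor, lognormal
with log-sd `sigma_col` = 0.2, applied before pooling; and a per-(pool,
transcript) factor, lognormal with log-sd `sigma_row` = 0.5, shared by every
sample of a pool.  The row factor perturbs *composition*, not just depth —
a depth-only pool effect would vanish after TPM normalisation and could
never reproduce the PC1 row separation the diagnostic is built to detect.
Neither sigma is an empirically measured quantity; both are calibration
choices.  Counts are gamma-Poisson (negative binomial) around the biased
means with dispersion α = 0.1 by default; α = 0 degrades exactly to Poisson.

**Reads** (`simulate.simulate_reads`).  Each counted molecule yields one
3'-terminal fragment: the insert (tagmentation breakpoint → polyA anchor) is
lognormal with mean 550 − 136 = 414 bp and log-sd 0.7, clamped to
[26 nt, transcript length].  The 136 bp adapter overhead is a single
constant (Nextera i5 side + TruSeq i7 side) so that the 550 bp mean library
molecule identifies the insert mean.  The log-sd 0.7 reflects the broad
smear tagmentation produces and puts ~1.5% of molecules below the 70 nt
read length — the polyA read-through regime the trimmer exists for.  The
read is 70 nt of sense strand from the breakpoint toward the 3' end; any
remainder past the polyA junction is emitted as 'A' (the tail is treated as
unbounded — no adapter read-through is modelled).  Substitution errors hit
read bases at 10⁻³ per base and index bases at 10⁻³; qualities are constant
Q30 and ignored downstream.  rRNA molecules, having no polyA anchor, are
fragmented at a uniform random position.  All draws come from one seeded
generator in a fixed order, so outputs are bit-reproducible per version.

Because truncation at transcript ends only removes mass from the upper
insert tail, the realised mean molecule length sits slightly below the
drawn mean — about 547 bp against the 550 bp target, within the protocol's
own measurement tolerance.

### What the simulator does not emulate

PCR duplicates, UMIs, indels, paired ends, per-cycle quality decay,
sequence-composition (GC) bias, and genome-level structure (introns,
overlapping genes, paralogy beyond chance k-mer sharing).  Random reference
sequences make multi-mapping far rarer than in a real transcriptome, so the
uniquely-mapped fractions here are optimistic; passing tests demonstrate
the correctness of the pipeline's logic on the model, not its mapping rates
on real 3' libraries.

## Processing pipeline choices

**Demultiplexing** matches each index independently (index reads come off
the instrument separately): a read is assigned iff exactly one well is
within Hamming distance 1 (default) on i5 *and* i7; zero hits → no-match,
several → ambiguous.  The bundled pools (12 six-mers, 8 eight-mers) keep
pairwise distance ≥ 3 within each pool, which provably excludes ambiguity at
a 1-mismatch budget; they are synthetic stand-ins, not vendor sequences.

**PolyA trimming** removes the read suffix from the leftmost A-run of
length ≥ 12 whose *start* lies at 1-based position ≥ 26.  "After the 25th
position" is ambiguous for runs that straddle the cutoff; this
implementation ignores such runs (protecting genuinely A-rich 5' sequence)
and exposes both knobs (`min_start`, `max_non_a`; pure-A runs by default).
The operation is idempotent.

**Alignment** is a deliberately transparent seed-and-extend over the
transcriptome: exact 25-mer seeds at read offsets 0/22/44 (fallbacks
tolerate 5' errors), ungapped extension counting mismatches, overhangs
scored as mismatches, k-mers with more than 64 locations dropped as seeds
(this silently removes the pure-A tail k-mer every transcript shares).  A
read is `unique` iff a single location attains the best score and passes
mismatches ≤ floor(0.1 × read length); exact ties are `multi` and never
counted.  Splice-aware genome alignment is out of scope: simulated reads
are transcript-born, so a transcriptome target loses nothing.  The
reference carries a 50 nt polyA anchor — at least the worst-case 44 nt of
A-fill an untrimmed read can contain — so the rare read-through read whose
A-run straddles the trimming cutoff still aligns to its transcript.

**Counting and TPM.**  Only unique sense alignments are counted; the
feature class of an alignment is the class covering the majority of its
bases (ties → 3'-most segment).  TPM is length-free: counts scaled to 10⁶
per sample, no gene-length division, because every transcript contributes
exactly one 3' fragment regardless of length.

**Gene-body profile.**  Each unique mRNA alignment contributes its midpoint
as a percentile of its transcript.  The expected 3' concentration (≥ 80% of
mass in the 3'-most fifth) is only geometrically well-posed for genes long
relative to the ~400 bp insert — a 1 kb transcript's single 3' fragment
already spans 40% of its body — so the property is asserted on genes
≥ 2 kb; over the whole transcriptome roughly 70% of mass falls in the last
fifth under defaults.

## Spike-in QC

Accuracy is the per-sample Pearson r between log2(TPM + 1) and log2(known
concentration) over all 92 species; zeros are retained via the pseudocount.
This censors species below ~1 TPM at the pseudocount floor, which imposes a
**deterministic ceiling** on r of about 0.95–0.97 for a 2¹⁸–2²⁰ dynamic
range at desk-scale depths — a property of the metric, not noise; deeper
sequencing moves it only marginally because the bottom of the mix stays
below one expected count.  (Observed accuracy on real libraries of this
design sits at ~0.97, consistent with that ceiling.)  Values like r ≥ 0.99
are unreachable under these conditions; the acceptance test asserting it is
kept and fails, documenting the bound rather than hiding it.

The pooling diagnostic centres the samples × species log matrix by species
(no variance scaling — concentration-driven variance is signal), takes PC1
from an SVD, and computes R² = SS_between/SS_total of PC1 scores grouped by
plate row and by plate column.  The decision rule is a label permutation
test (default 1000 permutations, seeded): p = fraction of relabellings with
R² at least the observed value (with the standard +1 correction).  A design
with one sample per group yields R² = 1 trivially and triggers a
degenerate-design warning instead of a verdict.

## Differential expression

Size factors are median-of-ratios against the geometric-mean reference
(total-count ratios as fallback when no gene is positive everywhere).
Per-gene dispersions are within-group moment estimates (groups = distinct
design rows), pooled across groups by residual df, shrunk 50/50 on the log
scale toward a trend (median raw dispersion in 20 log-mean bins, linearly
interpolated); non-positive raw moments fall back to the trend; floor 10⁻⁸.
The NB log-link GLM is fit by IRLS vectorised across genes (shared design;
tolerance 10⁻⁸ on coefficients, 100 iterations max, a 10⁻¹⁰ ridge keeps
degenerate genes solvable).  The Wald statistic on the condition
coefficient is referred to a **t distribution with n − p degrees of
freedom**: with moment dispersions at plate-scale n (a dozen samples), the
normal reference is measurably anticonservative (global-null p < 0.05
fraction ≈ 0.074 at n = 6 + 6 versus ≈ 0.046 with the t reference), and
finite-sample t calibration is the standard remedy.  There is no outlier
refitting, no independent filtering, and no fold-change shrinkage — this is
a transparent NB-GLM, not a clone of any particular DE package.  DEGs are
called at q < 0.05 (Benjamini–Hochberg) and |log2FC| > 1, both strict.
ROC/AUC against a truth set ranks genes by ascending p-value and computes
AUC by the Mann–Whitney rank-sum identity with mid-ranks for ties.

## Problem sizes and numerical notes

Test and acceptance workloads use desk-scale sizes chosen so the whole
suite runs in about a minute: reference transcriptomes of 60–2000 genes,
runs of 10⁴–10⁵ reads per sample across 6–96 samples, 10–20 seeded
replicates for stochastic properties, 200 null plates for permutation
calibration, 500–1000 permutations per test.  Degenerate inputs are handled
explicitly: zero-depth profiles simulate nothing, all-zero samples emit
zero TPM with a warning, all-zero genes get NaN statistics, constant
vectors make correlations an error rather than NaN propagation, and
confounded designs (condition aliased with pool) raise an error naming the
aliased terms.
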