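# Methods

This note documents the models, defaults and design decisions behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Coordinate and identity conventions

VCF positions and protein positions are 1-based inclusive at every external
interface; all internal interval arithmetic (exon geometry, CDS slicing) is
0-based half-open. Peptide identity throughout the immunopeptidome stages is
the bare amino-acid sequence — modifications are ignored for set algebra and
unique-peptide counting, matching common practice; `modified_identity=True`
switches to peptidoform identity where supported. Missing values in
quantitative tables are encoded as empty fields (NaN in memory), never 0,
because 0 is a legal abundance.

## Variant context databases (`variant_db`)

Somatic variants are consumed as Strelka-dialect VCF (read mapping and
calling are out of scope). Filtering keeps `FILTER == PASS` records with
read depth ≥ 10, taking depth from DP for SNVs and DPI for indels; FORMAT
fields are preferred over INFO when both are present, and a variant with no
recorded depth is rejected (not treated as 0). Population-frequency
filtering keeps variants with no recorded population AF (the common case
for true somatic variants) or a highest observed AF strictly below 1%.

Consequence calling edits the spliced CDS (strand- and splice-aware) and
re-translates, so SNVs, MNVs and indels share one code path; the
consequence class falls out of the protein diff (synonymous, missense,
stop_gained, stop_lost, frameshift, in-frame indel). Transcripts whose gene
biotype is not `protein_coding`, or that carry the `NMD_mediated_decay`
transcript biotype, yield `non_coding` and are excluded — only the label is
honored; no rule-based NMD prediction is attempted. A REF-allele mismatch
against the contig raises an error rather than skipping, to surface
coordinate bugs immediately.

Context windows: the 31-residue default is interpreted as a centered
15+1+15 window around the substituted residue, truncated without padding at
protein termini (a substitution at protein position 3 yields a 18-mer: two
left-flank residues, the site, 15 right). Frameshift and stop-lost contexts
run from 15 residues of wild-type left flank through the new stop;
stop-gained contexts keep the left flank up to the new C terminus and are
emitted only if at least 8 mutant residues remain (the minimum MHC ligand
length). MNVs with equal REF/ALT length are treated as substitutions.
Paired FASTA output writes the normal entry first with headers
`>{variant_id}|{gene}|{aa_change}|{normal|mutant}`.

## Label-free quantitation and differential expression (`proteome`)

**Roll-up.** Protein abundance per sample is the sum of its three largest
unique-peptide abundances ("Hi-3"; a flag switches to the mean, which
differs only by a constant when exactly three peptides are present).
Peptides mapping to more than one protein are excluded entirely; proteins
left without unique peptides are omitted and logged. The immunopeptidome
roll-up deliberately differs: there, *all* associated peptides contribute,
and ambiguous peptides count toward each source protein (flagged).

**Normalization.** Each sample is multiplied by a single scalar
`exp(median_f(log ref_f − log x_fs))`, where the reference is the
feature-wise geometric mean over samples, computed on features observed in
all samples (≥ 10 required). After scaling, the median log-ratio of every
sample to that reference is 0 to machine precision. Because recomputing a
reference from renormalized data shifts all samples by one common constant,
strict idempotence (re-derived factors all 1) holds exactly for
pure per-sample scaling distortions, which is what the procedure corrects.

**Imputation.** Maximum likelihood under a per-feature Gaussian across the
samples of each condition × timepoint group: for independent samples the EM
fixed point sets each missing entry to the observed within-group mean.
Imputation is within groups, not global, so genuine treatment effects are
not shrunk toward zero. Features entirely missing within a group stay
missing and are flagged. A heuristic warns when the input's maximum exceeds
50, which suggests a linear-scale matrix was passed where log2 is expected.

**Moderated test.** Per-feature pooled residual variances (df = nA+nB−2)
are shrunk toward a scaled-inverse-chi-square prior whose degrees of
freedom d0 and scale s0² are fitted by method of moments on log variances
(trigamma inversion by Newton iteration). The moderated t statistic uses
df = d0 + residual df, capped at the pooled residual df across features
(the prior cannot contribute more information than the data it came from);
when observed variances are no more dispersed than chi-square sampling
explains, d0 = ∞ and the common variance is the arithmetic mean of the
sample variances. These choices agree with Bioconductor limma to numerical
precision, which a cross-check test enforces on a small matrix. Volcano
classification uses raw p-values at the stated cutoffs (−log10 p > 5,
|log2FC| > 1); BH q-values are reported alongside for completeness.
Differential expression is fitted per time point (irradiated vs control),
with the two-way-ANOVA interaction p appended across the full design.

**Two-way ANOVA.** Balanced fixed-effects treatment × time ANOVA,
vectorized across features via the cell-mean decomposition; verified
against `statsmodels` `anova_lm` per feature. Features with a missing cell
value, or designs with one replicate per cell (no residual df), return NaN
with a flag rather than an error.

**Over-representation.** A generic stand-in for commercial pathway
software: one-sided Fisher exact tests of each gene set against the
background universe, BH-adjusted; the conventional foreground selection is
|log2FC| > 0.58 (fold change 1.5) at p < 0.05.

## Immunopeptidome (`immunopeptidome`)

**FDR.** Peptide-level target-decoy estimation: scores collapse to the
best per distinct sequence (targets and decoys separately); the accepted
threshold is the smallest score at which decoys/targets among peptides at
or above it is strictly below α. The strict inequality is the conservative
resolution of ties exactly at the boundary. Decoy records never appear in
the output, and shrinking α can only shrink the accepted set.

**Allele assignment.** Each sequence gets its minimum-%rank allele; class
boundaries are strict (< 0.5 strong binder, < 2 binder), and a peptide at
or above 2 on every allele is a non-binder with no best allele. Ranks come
either from a precomputed table (an external predictor's output carried on
the records) or from the built-in mock scorer: a position-weight log-odds
score (one unit per matched anchor residue plus a tiny fixed residue
background to break ties) converted to a %rank as the empirical quantile
among 100,000 random uniform-residue peptides per allele per length. The
scorer exists so that synthetic tests exercise calibrated ranks; it is not
a binding predictor.

**Set algebra.** The radiation-specific set contains sequences observed in
at least one irradiated sample and in no control sample, including the
expanded control pool; enlarging the pool is therefore monotone
(non-increasing). The antigen table keeps radiation-specific peptides with
best rank strictly below 0.5, sorted ascending, and flags source proteins
carrying two or more distinct peptides.

## PTM analysis (`ptm`)

Modification burden is the ratio of unique modified peptidoforms to unique
unmodified peptides per sample; the denominator is the global unmodified
count of the relevant length class (not per-position). Positional analysis
restricts to 9-mers, pairs control and irradiated replicates in
timepoint/replicate order, applies two-sided paired t-tests per position
and BH across the nine positions. Zero cells in per-PTM comparisons get a
0.5 pseudocount and are flagged. Paired differences with exactly zero
variance (degenerate for a t-test) map to p = 1 when the groups are
identical and p = 0 otherwise, with the case flagged by construction in
tests.

## PRM quantitation (`prm`)

The standard curve is an unweighted OLS fit of light/heavy ratio against
light femtomoles (a 1/x-weighted fit is available by flag); at least three
points with non-degenerate spread are required, and a flat response is
rejected. Back-calculation is `(ratio − intercept)/slope`, flagging values
outside the calibrated range as extrapolated. Copies per cell =
fmol × 10⁻¹⁵ × N_A / n_cells with N_A fixed at the exact 2019 SI value
6.02214076×10²³, assuming 100% recovery; results carry both the exact and
a rounded display value. Note that per-fit OLS standard errors understate
the slope's sampling variance under the series' multiplicative noise
(error proportional to the ratio), so recovery checks judge the slope
against its Monte-Carlo sampling spread.

Fragment masses use monoisotopic residue masses (pyteomics) with
b_i = Σ residues(1..i) + charge·proton and y_i = Σ residues(n−i+1..n) +
water + charge·proton, i = 1..n−1. Heavy isotope labels are named
modifications with exact mass offsets (K(13C6,15N2) = +8.01420 Da), never
sequence changes, so every fragment containing the labelled residue shifts
by exactly the label mass. For equal-length peptides the distinguishing-ion
list contains every b/y index whose theoretical m/z differs; for a
single-residue substitution all of them share one Δmass (the residue mass
difference).

## Synthetic data (`simulate`)

All generators draw from named substreams of a single seed, so stages
re-run independently are byte-identical. Defaults encode the study design
the analyses assume: triplicate biological replicates; immunopeptidome
time points 24/48 h with summed-intensity boosts of 1.49× and 3.17× under
irradiation; proteome time points 0/24/48/72 h; lengths 8–12 with a 9-mer
mode; H-2-Kd/Dd/Ld-like anchor motifs (Tyr-P2 for Kd-like, Gly/Pro for
Dd-like, Pro-P2 for Ld-like, aliphatic C-terminal anchors); a seven-point
0–150 fmol PRM series against a 100 fmol heavy spike with 5% multiplicative
ratio noise; and endogenous PRM amounts of 51.31/99.63 fmol so that 3×10⁸
cells sit at the ~100/~200 copies-per-cell scale. Differential proteins
(40 of 400 by default — a scaled-down matrix that keeps test runtimes in
seconds) receive log2 effects with random sign and magnitude uniform on
[0.5, 2.5], ramping with time (none at 0 h, half at 24 h, full at 48/72 h):
real regulated proteins span a wide fold-change range, and a degenerate
single-magnitude truth would make rank-recovery metrics meaningless.
Peptide and protein intensities are log-normal because LFQ areas are
dominated by multiplicative noise; proteome missingness follows a logistic
curve in log-abundance (low-abundance values are more often missing).
Decoys are sequence reversals keeping the terminal residue, mirroring
common search-engine practice. PTM annotations are drawn at a configurable
per-observation rate with an odds multiplier on position 7 of irradiated
9-mers, so positional recovery is testable. The expanded control pool size
is a parameter (default 2 extra samples).

What the generator does *not* emulate: spectra and search-engine scoring
beyond two Gaussian score distributions, retention time and chromatographic
alignment, allele-specific detection biases, correlated peptide
intensities within a protein, and real population allele-frequency
structure. Passing tests therefore demonstrate that the statistical
machinery recovers known truth under the assumed noise model — not that the
pipeline is robust to every artifact of real LC-MS/MS data.

## Problem sizes

Tests and the acceptance script run the generators at deliberately modest
sizes — a dozen transcripts, ~400 proteins, a few hundred catalog peptides,
100 FDR simulations, 5000 null ANOVA features — chosen so the full suite
completes in well under a minute while keeping Monte-Carlo error small
relative to the asserted tolerances.

## Known limitations

- Indels spanning splice junctions are rejected rather than resolved.
- The consequence caller reports the first overlapping transcript per
  variant in database builds; per-transcript multi-annotation is available
  through `call_consequence` directly.
- The mock %rank scorer's anchor-match score is deliberately coarse; its
  strong-binder calibration is only as fine as the anchor-match probability
  of its motif (~top 0.5% for two-anchor motifs).
- `impute_mle` assumes within-group Gaussian log-abundances; it does not
  model left-censoring, so imputation under missing-not-at-random
  truncation is biased toward the observed mean (flagged as a known gap,
  consistent with the high alignment scores the design assumes).
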