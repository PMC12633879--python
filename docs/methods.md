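# Methods

This note records the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic data does and does not emulate,
and the numerical conventions that matter for reproducing results.

## Coordinate and window conventions

CDS codons are 1-based (codon 1 = ATG; the stop codon is counted, so a gene
of length 3n nt has n codons). Each gene's count vector covers an extended
window of whole codons: 24 upstream codons (−72 nt from the ATG), the CDS,
and 20 downstream codons (+60 nt past the stop). The *gene body* — the
normalization denominator and filtering unit — is CDS codons 21..n−20
inclusive, so genes need ≥ 41 codons to have a body. The inclusive boundary
(codon 21 and codon n−20 both inside the body) is a fixed convention;
`occupancy.BODY_TRIM` documents it in one place.

P sites are assigned at a single +12 nt offset from the footprint 5′ end for
all read lengths (configurable via `offset_nt`): on the plus strand the
P-site genomic position is 5′ + 12, on the minus strand 5′ − 12. A read
whose P site falls inside several genes' extended windows is counted for
each of them; with yeast-like intergenic spacing the duplicated mass is
negligible, and the per-run assignment report (`n_assigned` vs
`n_reads_assigned`) quantifies it. Reads are assumed to be primary
alignments; `read_starts_from_sam` skips secondary/supplementary records.

## Occupancy normalization and gene filtering

Occupancy at codon c is (count + 1) / mean over body codons of (count + 1).
The +1 pseudocount keeps zero-count codons finite and makes the body mean
exactly 1 by construction (asserted to 1e−9 in tests). Genes are retained
for differential testing only when the raw body read sum is ≥ 50 in *every*
sample of a comparison (the analysis set is the intersection of per-sample
retained sets), which bounds the noise of the per-codon Fisher tests.

## Chromosome dosage

Per gene the dosage ratio is the aneuploid body-read share divided by the
euploid body-read share. Because a duplicated chromosome adds read mass,
raw shares are compositional: a 2.0× duplication depresses every ratio by
1/(1 + s), where s is the duplicated chromosome's expression share. The
reported per-chromosome medians therefore re-centre the per-gene ratios by
the genome-wide median ratio (`center=True`), which is robust as long as
duplicated genes are a minority; after centring a k-fold duplication reads
out at median ≈ k and unaffected chromosomes at ≈ 1. The raw compositional
ratio is available with `center=False`.

## Differential pause calling

For every CDS codon of every retained gene, a two-sided Fisher exact test
compares (reads at the codon, reads in the gene body excluding that codon)
between euploid and aneuploid, separately per replicate pair; BH correction
runs over all tested codons within the replicate (one family per
comparison, not per gene). The body column excludes the tested codon so the
table columns are disjoint; with body ≫ codon the difference from the
inclusive variant is negligible, and `exclude_codon=False` restores it.
Only CDS codons are tested — the UTR-window codons are normalized for
display but would only inflate the test count. `min_total` (default 0)
can skip codons with no reads in either condition; the gene filter already
bounds noise, so everything is tested by default.

Significant codons (FDR < 0.05) are labelled by the pseudocounted
normalized occupancy ratio (aneuploid/euploid): > 1 is aneuploid-higher.
A codon whose ratio is exactly 1 has no direction and is never reported.
Replicates are combined by union; codons significant in multiple replicates
with conflicting directions are discarded and reported separately.
Union (rather than intersection) was chosen because replicate-level calls
at moderate coverage are individually conservative; intersection is a
one-line change on the combined table (`replicates_supporting == n`).

The Fisher p-value is the sum of conditional-hypergeometric probabilities
of tables as or less probable than the observed one, computed vectorised
via log-gamma with a 1e−7 relative tie tolerance; tests pin it to an
exact-rational enumeration oracle at 1e−9 and cross-check
`scipy.stats.fisher_exact`. The Wilcoxon rank-sum position test uses exact
enumeration when both groups have ≤ 20 tieless observations and the
tie-corrected normal approximation otherwise.

## Stall motifs

Residues at positions −10..+10 around each peak codon (0 = P site, +1 = A
site; ±10 interprets "ten flanking residues" symmetrically) are counted
over a 21-symbol alphabet (20 amino acids + stop). Positions that run off a
protein end contribute nothing to that position's denominator, so each
position's frequencies divide by the number of peaks actually scored there.
Each (position, symbol) cell is a two-sided Fisher test of the flank counts
against the proteome background occurrence counts, BH-corrected over the
whole matrix; enrichment is log2(observed frequency / background
frequency), so depletion is negative and a symbol absent from the
background but present in flanks flags itself as +inf. The background
defaults to all included gene models; a measured-genes-only scope is
available since either reading of "the proteome" is defensible.

## Spike-in normalization and the silencing rule

Each sample's scale factor is 1/slope of a through-origin fit of its
spike-gene counts against the reference sample's; applying the factors and
refitting gives slopes of exactly 1 for any ratio-equivariant fit (tested
to 1e−6). The default fit is a 10%-trimmed mean of log ratios: spike noise
is multiplicative, and in log space all spike genes are equally informative,
so the trimmed log-mean is near-efficient while still discarding outliers.
A pilot comparison showed the through-origin least-absolute-deviation fit
(equivalently the count-weighted median of ratios, available as
`method="lad"`) has ~1.6× the sampling error under lognormal noise because
large spikes dominate its weights; ordinary least squares (`"ols"`) is
worse still. At the default 50 spike genes and 10% noise the factor
standard error is ≈ 1.4%.

Silencing-defect genes are selected by pure set logic on per-gene contrast
statistics: significantly repressed (negative log2FC, FDR < α) in the
euploid relative to euploid log phase at some timepoint, AND significantly
higher than the euploid (positive log2FC, FDR < α) in every aneuploid
strain at at least one timepoint. Note that requiring fewer aneuploid
strains can only grow the selected set (fewer constraints), and a strain
listed as required but absent from the statistics table is an error — the
rule never silently skips a missing contrast.

The built-in contrast engine is a stand-in: a two-sample t-test on
log2(normalized counts + 0.5) whose per-gene variances are shrunk toward a
prior fitted by matching the spread of log-variances to a scaled-F
distribution (the standard empirical-Bayes treatment; the prior degrees of
freedom are estimated, not fixed). Externally computed per-gene statistics
in the same long format are accepted by the selection rule, which is the
intended path for real data analysed with a count-GLM engine.

## Screen cascade

TMM factors are computed natively: M-values (log2 ratio of library-scaled
counts to a reference sample) trimmed 30% on M and 5% on average abundance,
averaged with precision weights, rescaled to geometric mean 1; the
reference defaults to the sample whose upper quartile is closest to the
mean upper quartile. The implementation matches edgeR's `calcNormFactors`
to ~1e−13 on random tables (cross-checked in the test suite via Rscript).

Enrichment is the moderated-t contrast of log2 TMM-CPM (pseudocount 0.5)
between a timepoint and the starting pool within a strain, BH across genes.
Hits are genes with significantly positive aneuploid day-28 enrichment
(FDR < 0.1 by default; 0.05 available) whose linear differential
2^(log2FC_aneuploid − log2FC_euploid) is ≥ 2. "Average strain difference"
is implemented as the difference of replicate-mean log2FCs, linearised for
the 2-fold rule; comparing linear fold-changes by subtraction instead is a
trivial variant the tables support. Hits with 2^(log2FC_d28 − log2FC_d1) >
2 in the aneuploid are classed lifespan-specific, the rest early-benefit.

## Synthetic data: what it emulates, and what it does not

`generate_genome` builds intronless, single-exon genes (ATG … stop, no
internal stops) of 150–450 codons on 8 chromosomes with random strands and
80–200 nt spacers; stall sites are planted one per gene inside the gene
body, with P-site residues drawn K/N and A-site residues G/E by default —
the residue classes associated with ribosome stalling — and positions drawn
from a Beta distribution over relative body position (symmetric by default;
5′-skewed Beta(1, 3) scenarios reproduce a positional shift of
aneuploid-enhanced peaks). Exclusion-rule paths (introns, missing ATG)
are exercised with hand-written annotation fixtures instead, since the
generator never produces them.

`simulate_footprints` draws each gene's codon profile once from a Dirichlet
(concentration = `dispersion` × a base weight of 1 per CDS codon and 0.05
per UTR-window codon; default dispersion 5 gives ragged, overdispersed
profiles) and shares that profile across samples and conditions — the
profile is a property of the gene's sequence. Stalls multiply the profile
weight at the stalled codon by `fold` (default 8) in the affected condition
only. Gene-level read mass is lognormal expression (sd 1 log2) × length,
with `dosage_fold` (default 2.0 — a true duplication; the observed
attenuation to ~1.7× in real aneuploids is a configurable alternative)
applied to duplicated-chromosome genes in aneuploid samples; total depth is
multinomial-exact. Because replicates share profiles, the null for the
per-codon Fisher test holds exactly, which is what makes the FDR-control
simulation meaningful. The optional read emitter places 5′ ends exactly
12 nt from the true P site on the correct strand (fixed 28 nt footprints
are implied but only 5′ positions matter downstream). Not modelled:
sequence-dependent ligation bias, rRNA contamination, UTR biology, read
length variation, codon dwell-time kinetics. Passing tests therefore show
the *inference machinery* is correct at realistic counting noise, not that
real libraries are free of these artefacts.

`simulate_spikein` scales all counts of a sample by its true factor; spike
counts are base × factor × lognormal(cv), with the reference sample's
spikes equal to their base abundances — the noise model is relative to the
reference, consistent with the factor of the reference being exactly 1.
The silencing design is one euploid + four aneuploids × (log, day 1) × two
replicates; 500 of 2000 genes are repressed 32-fold on quiescence entry,
and the 100 planted defect genes instead stay 16-fold above the euploid
level in aneuploids only. `simulate_screen` draws negative-binomial counts
(dispersion 0.1) around library proportions for euploid/aneuploid ×
pool/d1/d28 × triplicate at 2M reads; planted hits multiply aneuploid
proportions 8-fold at their class timepoints. Colony-bottleneck effects
beyond NB dispersion are not modelled.

## Problem sizes and seeds

All generators are deterministic given a seed (byte-identical outputs).
The acceptance checks use: 100,000 reads for P-site accuracy; ~120,000
tested codons (200 genes × 2 replicates, depth 6×10⁵) for the null
FDR-control run; 250 genes / 200 stalls at ~10 reads per body codon for
recovery; 300 genes with 150 + 150 direction-specific stalls for the
position shift; 500 genes for the trace-correlation contrast; 240 genes at
depth 10⁶ for dosage; and the generator defaults for the spike-in and
screen cascades. These sizes give each statistic comfortable resolution
while keeping a full run to seconds.

## Known limitations

* The built-in differential engine is deliberately simple; for real data
  the selection rules should be fed externally computed per-gene
  statistics.
* The per-codon Fisher test treats counts as multinomial given the gene
  body; extra-multinomial biological variation between paired samples
  would inflate calls, which is why replicate-level calling plus
  cross-replicate combination (and the direction-conflict filter) matters
  on real data.
* Reads overlapping two genes are double-counted rather than
  fractionally assigned.
* The motif analysis is residue-level only; codon-level enrichment and
  tRNA-abundance covariates are out of scope.
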