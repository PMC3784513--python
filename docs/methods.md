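# Methods

## Canonical contexts

A substitution at a G•C pair is assigned the 4-mer written 5′→3′ on the
strand whose guanine occupies position 2 (P2). For a forward-strand G at
1-based position *p* this is the forward 4-mer over [*p*−1, *p*+2]; for a C
(a reverse-strand G) it is the reverse complement of the forward 4-mer over
[*p*−2, *p*+1]. The 64 resulting classes partition as CGNN (16) ∪ DGNN (48),
with DGNN further split by P3 into DGRN (24) / DGYN (24) and DGAN (12) /
DGBN (36). Substitutions at A•T pairs, 4-mers running off a sequence end,
and windows containing N are excluded from numerators and denominators
alike.

Genome-wide denominators *t_i* count every scorable G and C site. Because a
double-stranded occurrence of a self-complementary tetramer (AGCT, CGCG,
GGCC, TGCA) contains two mutable guanines, per-site counting automatically
reproduces occurrence counting with the self-complementary doubling rule;
the package ships both routes (`count_genome_motifs`, per site, and
`count_motifs_tetramerwise`, occurrence scan with explicit doubling) and the
test suite asserts their exact agreement on random sequences.

**Mask semantics.** Only the mutated-base position, not the whole 4-mer, has
to fall inside the mappability mask, matching per-site variant calling. A
whole-tetramer requirement would shrink every *t_i* near mask boundaries and
could be added by intersecting the mask with itself shifted ±2; the
single-position rule was chosen as the less assumption-laden reading and is
applied identically to numerators and denominators, so fractions are
unbiased either way up to boundary effects of order (4/mask-segment length).

**Coordinates.** All inputs and reports are 1-based (VCF convention); BED
masks are 0-based half-open per the BED standard; internal arithmetic is
0-based half-open. Chromosome names tolerate a "chr" prefix mismatch.

## Deduplication and fractions

Within a dataset, repeated hits of one genomic coordinate collapse to a
single count regardless of alt allele or zygosity (`deduplicate`, keyed on
(chrom, pos); a `within_sample` switch restricts collapsing to within one
sample). The undeduplicated records are retained for recurrence analysis,
which needs per-sample hits. *f_i* = *m_i*/*t_i* is undefined (flagged, not
zero) when *t_i* = 0; *t_i* = 0 with *m_i* > 0 is an impossible observation
and raises.

The G•C mutation fraction is tested two-sided against a binomial null at the
background GC content, 0.41 for genome-wide and 0.55 for exome-wide
catalogs, via the exact test in `scipy.stats.binomtest`.

## Contrast statistics

The default contrast across motif subsets is a two-tailed Welch (unequal
variance) *t*-test on the per-motif *f_i*. For sparse catalogs in which some
motif class has no observed mutation, a pooled two-proportion *z*-test is
used instead: *m* and *t* are summed within each group and the standard
normal deviate of the difference of proportions under the pooled null is
evaluated. `test="auto"` switches to the *z*-test whenever any defined group
member has *m_i* = 0; the exact construction of the *z* fallback is a design
choice of this package (a pooled-variance two-proportion test is the
textbook form). −log10 P is capped at 308 with an underflow flag. Undefined
*f_i* are excluded pairwise.

The P4-adenine ratio is computed per purine-P3 stem (P1, G, P3) as
*f*(P1·G·P3·A) / mean{*f*(P1·G·P3·C/G/T)}, with 8 stems (4 P1 × 2 purine
P3), summarized as mean ± SD. It is computed on fractions *f_i*, not raw
counts, so unequal motif abundances cancel.

## Physicochemical descriptors

The vertical ionization potentials of the 12 guanine-centered DGN
double-stranded trimers are embedded as package data (eV; GGG lowest at
5.39, TGC highest at 5.97, free guanine 8.02, experimental band maximum
8.26). Three ranking properties of the table are asserted as tests: GGG is
the global minimum; every trimer containing a GG doublet lies below every
single-G trimer; and a 3′ purine always lies below a 3′ pyrimidine at fixed
5′ base. Tetramer-level VIPs are out of scope: trimers preserve the
sequence-dependent ranking at a fraction of the cost.

The stacking descriptor of a DGNN motif is the mean absolute stacking free
energy over its three ordered steps, (P1pG + GpP3 + P3pP4)/3. Published
step values are not bundled; the shipped default table
(`data/stacking_steps_synthetic.tsv`) is a clearly labelled synthetic
placeholder that honors only the qualitative class ordering purine-purine ≫
purine-pyrimidine > pyrimidine-purine > pyrimidine-pyrimidine, with distinct
per-step values to avoid ties. Users supply a published table via
`StackingStepTable.from_tsv` to reproduce literature axes.

Correlations are ordinary least squares of ln *f* on the descriptor
(natural log; motifs with *f* = 0 excluded with a warning — a class with no
observed mutations carries no information about its log rate). P(α)₀.₀₅ is
implemented as nonparametric bootstrap significance persistence: the
fraction of B (default 1000) case resamples, points drawn with replacement
under a fixed seed, whose refit slope has p < 0.05. Trimer aggregation sums
*m* and *t* over P4 within each NGN stem before dividing.

When several datasets are combined for one regression, each dataset is
normalized first and the normalized fractions are then averaged (a flag
switches to averaging raw fractions before normalization).

## Recurrence, tissue shares, pathways

A coordinate is recurrent when hit by at least `min_samples` (default 2)
distinct samples — across samples and datasets, with repeated hits by one
sample counting once and the alt allele ignored. *d_i* counts distinct
recurrent coordinates per motif, and *E_i* = (*d_i*/∑*d*)/(*t_i*/∑*t*); the
d-weighted mean of *E_i* is ≈1 + (K−1)/∑*d* under context independence
(K = number of motif classes), a bias negligible at the simulated scales.
Tissue shares use *s_n* = *t_n*/*c_n* (recurrent hits at the chosen motif
set over the tissue's total substitution count) normalized to ∑*S_n* = 1.
Pathway ranking scores each (pathway, tissue) as the percentage of that
tissue's samples with ≥1 mutated member gene; the cross-tissue combination
is the unweighted mean of per-tissue percentages — the combination rule is
underdetermined in the literature this mirrors, and the unweighted mean was
chosen so small tissues are not swamped by large ones.

## Transcription orientation and splice junctions

A record's canonical context fixes the strand of the mutated guanine
(ref G → forward, ref C → reverse). Inside a gene whose overlapping
transcripts agree on strand, the site is NT when the guanine strand equals
the gene strand (the non-transcribed strand carries the mRNA sequence) and
T otherwise; opposite-strand overlaps are ambiguous and excluded from the
ratio. Flipping every gene strand swaps NT and T exactly, an invariant under
test.

Splice positions are transcription-oriented with no position 0. Donor
windows place the last exonic base at −1 and the first intronic base at +1,
so the canonical GT occupies +1,+2; acceptor windows index intronic bases as
negative approaching the junction (canonical AG at −2,−1) and exonic bases
as positive. A mutation within the window of two junctions (short exons or
introns) is assigned to the nearer one; exact ties increment both and are
counted separately. Junction conservation matrices report per-position base
fractions over unique junctions in the same orientation, with windows
truncated by a sequence end skipped.

## Clustering

Context spectra (tetramer or trimer level) are scaled to unit row sums and
compared by Manhattan (city-block) distance. The merge tree uses average
linkage by default (single/complete available; the linkage underlying the
analyses this mirrors is unreported, and average linkage is the common
default for profile data). Cluster confidence is an ordinary bootstrap
support: columns are resampled with replacement B times, the tree is
recomputed, and a node's support is the fraction of replicates reproducing
its exact leaf membership; memberships with support ≥0.90 are flagged. This
is deliberately the plain bootstrap, not multiscale bootstrap; supports are
bit-reproducible for fixed (B, seed). Trees export as Newick with supports
as internal node labels.

## Synthetic-data generator

The generator emulates the statistical structure the analyses assume, not
real genomes. Defaults: 1 Mb i.i.d. genome at GC 0.41 (the genome-wide
background), 90% mappable in 1 kb tiles, 40 genes (3–8 exons of 80–300 bp,
introns 200–2000 bp) with canonical GT..AG junctions written strand-aware
into the sequence, baseline per-site rate μ = 10⁻⁴ per sample, κ_CpG = 5
(mid-range of the several-fold CpG excess typical of somatic catalogs),
κ_GpR = 2 (a moderate purine-P3 effect), κ_P4A = 1 (the ~2.2-fold P4-A
effect is melanoma-specific and enabled per scenario), no VIP term, no
strand bias, 10 samples. Mutations are site-wise independent Bernoulli
draws; the per-site rate is μ times the product of applicable context
multipliers (evaluated through the same canonical-context code the analyses
use), times β for guanines on the non-transcribed strand inside genes,
times optional signed-position splice weights; alt alleles are uniform over
the three alternatives. A clustered-burst variant (kataegis-like) exists
but defaults off. Rates are validated ≤1 before sampling. All stages draw
from independent streams spawned from one integer seed and are
deterministic across runs.

What the generator does *not* emulate — and hence what passing recovery
tests do not show about real data: CpG depletion and isochore structure of
real genomes, methylation state, replication timing and chromatin
covariates, mutational-signature mixtures with specific substitution
spectra, sample-size imbalance across datasets, and A•T substitutions (the
generator draws only at G•C sites, so the G•C-fraction statistic is 1 by
construction on synthetic catalogs and is meaningful only for external
data).

## Problem sizes and numerical choices

The test suite runs its recovery analyses on 0.3–0.5 Mb genomes with ~10³
mutations per catalog, sizes at which the injected parameters (κ_CpG = 5,
κ_GpR = 2, κ_P4A = 2.2, VIP slope b = 1, β = 2) are recovered within two
standard errors with comfortable power while the whole suite stays fast;
the acceptance script uses a 1 Mb genome and 5,000 recurrent sites. Type-I
calibration of the Welch contrast uses 1,000 null catalogs on a fixed 50 kb
genome. Ties and degenerate cases: bootstrap resamples with constant
descriptor count as non-significant; all-zero spectrum rows are excluded
from clustering with a warning; empty genomes yield all-zero count tables
with a warning rather than an error.

## Known limitations

- The pooled two-proportion *z* contrast ignores between-motif overdispersion
  within a group; with strong within-group heterogeneity its P-values are
  anti-conservative relative to the Welch route.
- Recurrence detection is coordinate-exact; it does not merge adjacent
  hotspot positions or codon-level recurrence.
- Gene-span orientation uses whole gene bodies, not coding exons only;
  restricting to exons changes NT/T tallies for intron-rich genes.
- The BED12/TSV gene readers assume non-overlapping exons per transcript
  and merge nothing across transcript isoforms beyond identical gene ids.
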