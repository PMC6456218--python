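# Methods

## The problem

HERV-K is the youngest human endogenous retrovirus family and the only one
insertionally polymorphic in humans: at a given genomic locus some
individuals carry a full provirus (gag/pol/env flanked by two long
terminal repeats), some a solo LTR (the scar left when homologous
recombination between the two LTRs excises the viral genes), and some
nothing at all. Because HERV-K loci share well over 80% sequence identity,
short reads from one locus map ambiguously across the family, and standard
per-locus genotyping from low-depth whole-genome data is unreliable. This
package determines the occupation state of every catalogued HERV-K locus
per individual from short-read data, then summarises the cohort
(prevalence, burden, co-occurrence, population contrasts).

## The statistic: n/T over locus-unique k-mers

For each locus we construct the set T of k-mers (default k = 50) that
occur at *exactly one* locus across every catalogued allele of every
locus. Matching is performed in canonical orientation (the
lexicographically smaller of a k-mer and its reverse complement) so that
reads from either strand hit the same table entry, and uniqueness is
enforced in canonical space. Within a locus, k-mers from different alleles
that project to the same anchor position on the designated primary allele
and differ by at most 2 substitutions are merged into a single entry, so T
counts diagnostic *positions*, not allelic variants; the Hamming
comparison is made between like-oriented (allele orientation) strings
because a substitution can flip which orientation is canonical. K-mers
containing N are dropped rather than expanded (expansion would inflate T
with sequences never observed). Loci with byte-identical sequences cannot
be distinguished by any k-mer; they are pooled into one reporting group,
T is computed once for the group representative and the members report
T = 0.

A sample's reads (mined from the catalogued intervals of an indexed BAM,
or supplied pre-extracted) are k-merised, canonicalised and matched
exactly against the table. Per locus, n counts the reference *entries*
with at least one exact match -- an entry counts once however many reads
hit it and whichever merged variant matched -- so n <= T and
n/T in [0, 1] by construction. n/T = 1 indicates the reference allele,
n/T = 0 absence; intermediate values arise from solo LTRs, unreported
alleles, and low coverage.

An entry is flagged `in_LTR` when its window lies *entirely* inside an
annotated LTR interval. Containment (rather than any-overlap) is the
operative definition because it makes the flag mean something physical:
the LTR-flagged entries are exactly the k-mers a solo-LTR haplotype can
produce, so an individual carrying only a solo LTR saturates at
n/T = T_LTR/T, and cluster evidence localising purely to LTR-flagged
entries identifies the solo state.

## Depth-aware clustering

At KGP-like depth (~7x) the reference cluster sits well below n/T = 1 and
disperses, so per-sample thresholding fails. Instead, per locus, the 2-D
points x_i = (n/T, ln depth) over all samples are fit with a truncated
Dirichlet-process Gaussian mixture

    f(x | theta) = sum_{j=1..M} pi_j N(x; mu_j, Sigma_j),   M = 10,

estimated by variational Bayesian EM under a stick-breaking DP prior
(concentration alpha = 1), so the effective number of components is
inferred. The fit is delegated to scikit-learn's
`BayesianGaussianMixture` with 5 seeded initialisations (best lower bound
kept), covariance regularisation 1e-6, and a Normal-inverse-Wishart base
measure centred on the data with two deliberate choices:

- the inverse-Wishart scale is the empirical covariance divided by M^2, a
  per-cluster share of the spread -- with the raw empirical covariance the
  prior expects single components as wide as the whole data range and
  merges well-separated tight clusters (e.g. absent at 0 with solo at
  T_LTR/T);
- a small mean-precision (kappa0 = 0.01) decouples component means from
  their covariances, so a tight component (the point mass of absent
  samples at exactly 0) is not dragged toward the data centroid.

Components are then aggregated into clusters by density mode: from each
active component mean a fixed-point ascent
x <- (sum_j r_j(x) Sigma_j^-1)^-1 sum_j r_j(x) Sigma_j^-1 mu_j (the
Gaussian-mixture mode iteration, responsibilities r_j) is run to a local
maximum of f (tolerance 1e-4 per axis in standardised units, cap 500
iterations; a non-convergent climb attaches to the nearest found mode),
and components whose climbs converge within 1e-3 of each other share a
cluster. The number of distinct modes is the realised number of clusters;
this lets a non-Gaussian smear (the low-depth reference cluster) be
represented by several components without being over-split.

Variational DP fits leave low-weight residual components whose collapsed
covariances would otherwise spawn spurious density spikes. A component is
treated as residue -- excluded from mode climbing and assignment -- when
its weight is below 1% *and* its mean lies inside a heavier component's
basin, taken as Mahalanobis radius sqrt(3^2 + 2 ln n_i) under the heavier
component's covariance (the 2 ln n_i term is the expected extreme radius
of that component's n_i points, so genuine far-tail satellites are
absorbed). Low-weight but isolated components are genuine small clusters
and stay active; this matters because real cohorts contain loci where a
state is carried by well under 1% of individuals.

Points are assigned to the cluster of their maximum-responsibility
component (ties break to the lowest component index). Fits are
deterministic given data and seed.

## State calling

Classification is cluster-level, never per-sample. Each cluster's members
pool their recovered entry ids; the pooled set is localised on the
reference allele (fraction of LTR-flagged entries, coverage gaps). A
cluster is called:

- `provirus_reference` when its mean ratio reaches the reference band.
  The band is 0.95 at depth >= 20 and relaxes linearly below that --
  0.95 - 0.30 x (20 - depth)/20, floored at 0.60 -- because at low depth
  true reference carriers sit at 0.7-0.9;
- `absent` when the mean ratio is <= 0.05;
- `solo_LTR` when intermediate and >= 90% of pooled recovered entries are
  LTR-flagged;
- `provirus_allele` otherwise: coding-region k-mers present but the set
  incomplete, the signature of an allele missing from the catalog. A
  cluster recovering under 30% of entries without LTR purity additionally
  carries a low-confidence flag, since for small T a diverged allele, a
  deletion and a solo LTR become hard to separate.

States propagate to every cluster member. Population summaries count
`provirus_allele` as provirus-present. Per-sample burden is the count of
provirus states over the designated polymorphic loci.

## Population layer

Prevalence tables are computed per population and super-population.
Pairwise equality of proportions between super-populations uses the
chi-square test with Yates continuity correction on the 2x2 table
(mirroring R `prop.test`, against which it is cross-checked in the test
suite); degenerate tables (pooled proportion 0 or 1) return p = 1 with a
warning. Benjamini-Hochberg correction (statsmodels step-up) is applied
within each family, one family per comparison problem x group pair --
with five super-populations there are C(5,2) = 10 families, and per-
individual burden over 20 loci has 21 categories (0..20). Co-occurring
provirus sets are mined with a level-wise Apriori (self-join on the
leading m-1 items, candidate pruning by the anti-monotonicity of
support); supports are exact, so the output equals brute-force subset
enumeration, which the tests assert up to p = 8 loci. "Presence" for
co-occurrence means provirus only -- a solo LTR is not a co-occurring
provirus. Fisher LDA (scikit-learn) projects per-sample profiles -- raw
n/T columns or one-hot state encodings (one-hot chosen over ordinal
because the three states are not ordered) -- onto the top two
discriminant axes; per class pair a separation score is reported as the
squared Mahalanobis distance between projected class means under the
pooled within-class covariance (ridge-regularised with a warning when
singular). The visualisation payload (loci, populations with sizes and
optional display coordinates from an editable TSV, the 0/1 presence
matrix, per-population co-occurrence prevalence of a selected locus set)
is exported as JSON for the interactive map; the browser app itself is
out of scope.

## The cohort simulator

The simulator generates the structure the genotyper assumes, end to end:
one ancestral provirus (9,500 bp with a 968 bp LTR duplicated at both
ends -- the family's dimensions) is mutated independently per locus at
0.08 substitutions/site, keeping pairwise identity just above the >80%
the family exhibits; each locus's LTR is mutated once and duplicated, so
the two LTR copies stay identical within a locus as they are in a young
provirus. Each locus is embedded in unique random host flanks on a
synthetic chromosome. One flank base adjoining each LTR is constrained to
differ from the corresponding internal base so that insertion junctions
remain informative -- without this, a solo haplotype's host-LTR junction
can coincidentally reproduce a provirus junction k-mer and break the
identity "solo recovers exactly the LTR-contained entries".

Diploid states are drawn per sample x locus from per-population haplotype
frequencies of (provirus, solo LTR, absent); when not supplied these are
generated population-structured from the seed (per-locus baseline
provirus frequency uniform on 0.15-0.9, per-population deviation up to
+/-0.2, solo mass a 5-30% share of the remainder). An individual's
observed state collapses the pair: provirus if either haplotype carries
one, else solo LTR, else absent. Default cohort: 10 loci, 500 samples, 2
populations, read length 100, total depth 7x (split between haplotypes),
1% per-base substitution error -- the low-depth regime the method was
built for; validation runs use depth 30/error 0 (saturated) and depth
6/error 1%.

Read starts are stratified-uniform: one uniform draw per equal-width
stratum of the start range. At depth 30 the strata are narrower than a
k-mer window, every window is covered and recovery saturates exactly
(homozygous reference gives n/T = 1, solo exactly T_LTR/T, absent exactly
0); at depth ~6 coverage gaps reappear and, with read errors, reproduce
the dispersion geometry that motivates the mixture model. Read names
encode sample, locus, haplotype and start for ground-truth checks; reads
can be written as FASTQ plus an optional pre-mapped BAM (each read placed
at its true genome position) so the miner runs without an external
aligner.

The simulator does not emulate: a realistic genomic background (flanks
are random, so no off-target k-mer sharing with non-HERV repeats),
instrument-specific error profiles (errors are uniform substitutions),
indel polymorphism (substitution-only by default), or structural variants
beyond solo-LTR recombination. Passing recovery tests therefore
demonstrate the statistical machinery under the stated identity
structure, not robustness to reference-genome artefacts.

## Numerical and implementation notes

- The end-to-end harness profiles simulated cohorts through a streaming
  path that fuses read generation and matching: per (locus, haplotype
  state) the reference entry at each haplotype position is precomputed
  once, and each read's seeded layout (start + error positions) decides
  which windows were sequenced intact. Layouts come from the same seeded
  sampler as the literal FASTQ path, and an error-bearing window matches
  nothing (a 50-mer collision has probability ~4^-50), so both paths
  produce identical profiles; the test suite asserts exact equality of
  n, ratios and recovered entry sets on a cohort with errors.
- Problem sizes in the validation suite: 20 randomized toy catalogs
  (2-5 loci, <=600 bp) for the reference oracle; 3 loci x 60 samples at
  depth 30 for exactness; the full default 10 loci x 500 samples for the
  two recovery regimes.
- Degenerate inputs: all-identical points fit a single component at the
  regularisation floor; loci with T = 0 (reporting-group members) are
  excluded from clustering and reported under their representative;
  reads shorter than k contribute nothing; empty read sets give n/T = 0
  everywhere.
- Depth for the second mixture coordinate comes from sample metadata when
  available (the cohort-published mean), otherwise from mean per-base
  coverage over control intervals; natural log is used.
- High-depth anchor samples (individuals sequenced at both low and high
  depth) are not pooled into low-depth fits; the caller conditions its
  reference band on depth instead.

## Known limitations

- Unique-k-mer presence cannot distinguish heterozygous from homozygous
  occupancy; the simulator still models zygosity's halved coverage.
- Uniqueness is assessed within the catalog, not against the whole
  genome; k-mers shared with uncatalogued repeats would inflate n at
  their loci (the S3-style coverage plots make such entries visible as
  isolated peaks in otherwise-absent individuals).
- For loci with small T, sequence polymorphism, deletions and solo LTRs
  blur; such clusters are labelled `provirus_allele` with a
  low-confidence flag rather than resolved.
- The k-sweep that motivated k = 50 is reproducible as a diagnostic
  (rebuild at several k and compare), but no automated chooser is
  provided.
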