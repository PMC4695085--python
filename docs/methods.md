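# Methods

`symcomm` implements the full computational chain for comparing
*Symbiodinium* ITS2 amplicon communities across reef habitat
compartments (water column, sediment, coral tissue) and between two
thermally distinct backreef pools (labelled 300 and 400): read quality
control, hierarchical taxonomy assignment, community dissimilarity and
ordination with PERMANOVA, Bayesian Poisson-lognormal differential
abundance, and Mantel tests of within-pool spatial autocorrelation. A
synthetic-data generator with known truth stands in for raw survey
reads, so every stage is testable without downloads.

## Read quality control

- **Quality trimming** removes the 3' tail after the last position
  whose trailing running mean quality (window 10 bases, configurable)
  is at least Q25. The window size is a conventional choice; pipelines of
  this kind historically specify only a running-average rule.
- **Homopolymer filter** discards reads containing any single-base run
  longer than 6 (runs of exactly 6 are kept).
- **Primer trimming** locates the forward primer and the reverse
  complement of the reverse primer by semi-global alignment, IUPAC
  ambiguity codes aware, allowing up to 3 edits (substitutions or
  indels) per primer. Reads without a forward-primer match are
  discarded; a missing reverse match trims the forward side only.

## Hierarchical taxonomy assignment

Reads are classified against a clade-labelled ITS2 reference database
(five clades: A, C, D, F, G) in three tiers.

**Clade tier.** Each read is scored against every reference by banded
end-to-end edit distance (edlib), converted to a match/mismatch score
(match +1, each edit -2; with `L` alignment columns and `d` edits the
score is `L - 3d`) and then to an E-value via Karlin-Altschul
statistics, `E = K m n exp(-lambda S)`, with the ungapped `lambda`
solved from the score scheme at uniform base composition and a fixed
`K = 0.3`. A clade is called only when its best E-value is at most
1e-20 **and** at least 1e5-fold smaller than the best E-value of any
other clade (the best/next-best ratio rule; a single-clade database
passes the ratio trivially). Reads failing either rule stay
unassigned. We read the ratio as best/next-best <= 1e-5, i.e. the best
clade must be at least 10^5-fold stronger. Alignments are abandoned
early once a reference is so far behind the current best hit that its
clade could not alter the ratio decision; this changes nothing in the
decision rule, only the runtime. A profile-HMM scorer could be dropped
in behind the same interface; the decision thresholds, not the scoring
engine, define the behavior.

**Subtype tier.** Within the called clade, each read is aligned to
that clade's references with extended-CIGAR end-to-end alignment whose
terminal indel runs are stripped — equivalent to a semi-global (glocal)
alignment for near-full-length amplicons. A hit qualifies when E <=
1e-20, identity > 97% (matches over alignment columns, internal gaps
counted as mismatches) and reference coverage > 90% of the full
reference length. A unique top hit yields that reference's (leaf)
name. Hits are *tied* when their integer alignment scores are equal
and their identities agree to four decimal places; tied reads are
placed at the lowest common ancestor of the tied leaves on the clade
guide tree and labelled `<clade>_i:<node>`, with internal nodes
numbered by preorder from 1. When no guide tree is supplied, one is
built per clade by neighbor joining on pairwise alignment distances,
midpoint-rooted. Reads with no qualifying hit are marked "new".

**De novo tier.** "New" reads are clustered greedily within each
clade: unique sequences are processed in decreasing abundance
(lexicographically smallest read id breaks ties); a sequence joins the
first centroid, in founding order, with global identity >= 97%
(`1 - d / max(len)` under end-to-end alignment), otherwise it founds
the next cluster, labelled `<clade>_d:<cluster>` numbered from 1 in
founding order. The partition is deterministic given the ordering
rule; permuting equally abundant reads can renumber clusters but
(away from identity ties at exactly 0.97) not change the partition.

Counts of all labelled reads are merged into a samples x taxa table;
unassigned reads are excluded but tallied per sample in a QC report,
so assigned + unassigned always equals the post-QC input count.

## Community analysis

Counts are converted to relative abundances and square-root
transformed (so both dominant and rare taxa contribute), and pairwise
Bray-Curtis dissimilarities are computed. Reported group summaries
follow the convention that the within-pool mean is the pair-count
weighted average over pools, and the overall mean is over all pairs —
the overall value is not in general the average of within and between.

PERMANOVA partitions the Gower-centered matrix of `-d^2/2`. The
two-way crossed design (compartment/species x pool with interaction)
uses sequential (Type I) sums of squares in the order given, matching
the convention of vegan's `adonis2(..., by="terms")`, against which the
implementation is verified. Significance comes from free permutation
of sample labels with 9,999 permutations by default and the +1
corrected p-value; an exact mode enumerates all `n!` relabelings for
small n. Following the survey's analysis design, one-way pool tests per
compartment and coral species are run after the two-way test, without
multiple-testing correction across the species-level tests (fewer than
one type I error expected at these test counts). Differential
abundance is only fitted where the one-way pool effect is significant
at 0.05 (a `force` flag overrides the gate).

NMDS uses non-metric SMACOF with monotone regression (best of 20
random starts by default) and reports Kruskal stress-1; taxa can be
projected into the ordination as abundance-weighted averages of sample
coordinates for biplots.

## Differential abundance (Poisson-lognormal mixed model)

Raw counts — not rarefied, not normalized — for one compartment or
species are modeled as

    y[s,t] ~ Poisson(lambda[s,t])
    log lambda[s,t] = alpha[t] + beta[t] x[s] + u[s] + eps[s,t]

with `x[s]` indicating pool 300 (pool 400 is the reference level),
`u[s] ~ N(0, sigma_u^2)` a sample-level effect absorbing sequencing
depth, and `eps[s,t] ~ N(0, sigma_eps^2)` per-cell overdispersion.
Only taxa exceeding 0.1% of the subset's total sequences are tested;
an artificial "sum" taxon, whose count is each sample's **pre-filter**
total, is modeled alongside them. Relative abundances per pool are
`exp(eta_t - eta_sum)` at that pool's fixed effects, and the
between-pool fold-change is their ratio, so the depth effects `u` and
any global scaling cancel. Note the consequence: fold-changes are
relative to total community size, so planting an absolute increase on
one taxon necessarily produces reciprocal relative decreases spread
over the others.

Priors are weakly informative: Normal(0, 10^2) on fixed effects (log
scale) and half-Cauchy(2.5) on both standard deviations. Inference is
an adaptive Metropolis-within-Gibbs sampler: all parameter blocks are
updated elementwise with Gaussian random walks (cells of `eps` are
conditionally independent given the rest, so the whole matrix updates
in one vectorized step), proposal scales adapt toward 0.44 acceptance
during burn-in only, and the chain defaults to 15,000 iterations with
5,000 burn-in and thinning by 10 (1,000 retained draws). Split-Rhat
and autocorrelation-based effective sample sizes of the between-pool
contrasts are reported as diagnostics. Chains are deterministic given
the seed.

Significance uses Bayesian z-scores: `z = |mean(delta)| / sd(delta)`
over draws of the log fold-change `delta = beta_t - beta_sum`, with
two-sided normal p-values and Benjamini-Hochberg control at FDR 0.1.
Point summaries are posterior means on the log scale (geometric
means), with 2.5/97.5 percentile credible limits; a degenerate
zero-variance posterior yields p = 1 with a warning.

## Spatial autocorrelation

GPS coordinates (WGS84) are projected to planar meters, by default
with a transverse Mercator (UTM) projection implemented from the
standard series expansions (round-trip error well under 1 m; zone 2
for the survey region), or alternatively with a local equirectangular
projection about the points' centroid; over a single pool's extent the
two agree to well under half a meter. Samples without coordinates are
excluded with a warning. Geographic distance is Euclidean on the
projected coordinates.

The Mantel statistic is the Pearson correlation of the lower
triangles of the geographic and community distance matrices;
significance comes from simultaneous row/column permutation of one
matrix, one-tailed toward positive autocorrelation, with 999
permutations by default (an exact mode enumerates all relabelings).
The statistic is invariant to positive affine rescaling of either
matrix, so rescaling a pool's spatial extent cannot change the result.

## Synthetic data generator

The generator emulates the original survey at three levels.

**Reference database.** A random ~330 nt ITS2-like root sequence is
evolved into five clade ancestors (default divergence 0.25, roughly
the deep separation of *Symbiodinium* clades) and each ancestor into
`n_per_clade` reference leaves by balanced random bifurcating descent
whose per-path substitution budget equals the within-clade divergence
(default 0.05, placing most subtype pairs below the 97% identity
threshold). Guide trees follow the generating topology. Per clade, a
"novel" taxon is evolved past the 97% identity radius of every
reference; novel taxa appear in communities and reads but not in the
database, exercising the de novo path.

**Communities.** The default design mirrors the survey: two pools,
water n=29/pool along three shore-parallel transects (1 m sample
spacing, transects at 5/20/35 m offshore), sediment n=30/pool
scattered over the pool, and ten coral species at n=5/pool. Clade
mixtures per compartment approximate the observed patterns (water
dominated by C and A; sediment carrying the most D, F and G; corals
mostly C with species-specific D), and each group's clade mass is
spread over subtypes with geometrically decaying weights whose
dominant subtype rotates between coral species, giving the
species-distinct assemblages seen on real reefs (*Porites* nearly
fixed on one subtype, *Pocillopora*/*Acropora* variable). Sample
compositions are Dirichlet draws around the group mixture; the
concentration parameter sets within-group variability (lowest for the
labile coral species, highest for *Porites*). Planted between-pool
fold-changes act multiplicatively in pool 300, including a hundredfold
clade D increase in *Pavona venosa* and up/down shifts of individual
water and sediment taxa. Spatial gradients multiply taxon abundance by
`exp(slope * offshore_distance)`; defaults plant a clade A decline
offshore in water (both pools, ~4-fold across the transect span) and a
clade A increase offshore in sediment of pool 400 only. Library sizes
are log-normal with geometric mean 1,011 and geometric standard
deviation 3.8, redrawn below a floor of 33 reads.

**Reads.** Each count becomes one read: the source sequence copied
with independent substitution errors (default rate 0.002/base, typical
of post-QC pyrosequencing data). Optional modes attach the
amplification primers or plant 7-base homopolymer runs to exercise the
QC filters; chimeras and flowgram-level noise are not simulated, as
the generator emulates reads *after* the provider's denoising steps.

**What passing tests do and do not show.** The generator reproduces
the survey's design, depth distribution, planted effect sizes, and
spatial layout, but real amplicon data additionally carry PCR and
copy-number biases, chimeras, correlated (non-Dirichlet) compositional
noise, and spatially clustered microhabitat structure. Consequently
recovery results here certify the *pipeline* (classification logic,
test calibration, effect recovery), not the biases of real surveys.
One known tension: with unstructured Dirichlet noise the sediment
compartment cannot simultaneously match the observed high within-pool
dissimilarity and a reliably detectable spatial gradient, so the
default sediment gradient is usually below detection power — the water
column is the calibrated power case.

## Numerical choices and edge cases

- E-values are computed in log10 space and clamped to ±300 before
  exponentiation; decision rules compare logs, so underflow cannot
  affect them.
- Subtype ties compare integer alignment scores exactly and round
  identities to 4 decimals; LCA placement needs at least two distinct
  tied leaves, otherwise the single leaf label is returned.
- Zero-total samples are dropped (with warnings) before
  transformation and before the mixed model; a pair of all-zero rows
  makes Bray-Curtis undefined and raises.
- Permutation p-values use the +1 correction, so `p >= 1/(nperm+1)`;
  exact enumeration reports the unadjusted fraction (the identity
  permutation guarantees a nonzero numerator).
- PERMANOVA hat matrices come from pseudo-inverses, so rank-deficient
  (unbalanced, collinear) designs degrade gracefully; degrees of
  freedom are rank differences.
- The MCMC clips the log-rate at ±50 inside exponentials to avoid
  overflow with extreme proposals during early adaptation.

## Problem sizes

The shipped default scenario (178 samples, ~450k reads at full depth)
runs the entire pipeline in a few minutes on one CPU; unit tests use
reduced designs (3-5 samples per group, depths of 100-200) chosen to
exercise every code path quickly, and the calibration checks use
1,000 null simulations for the permutation tests and 50 replicates
for the mixed-model recovery studies.

## Known limitations

- The clade scorer is alignment-based rather than a profile HMM; with
  the shipped decision thresholds the two agree on clean data, but
  scores for heavily gapped or partial reads will differ from an HMM's.
- The de novo tier uses simple greedy centroid clustering (uclust
  style); cluster composition near the 97% boundary depends on
  processing order, as in the original tools.
- One-tailed Mantel tests and free (unstratified) PERMANOVA
  permutations are conventions; both are configurable but the
  originals' exact settings are not documented.
- The model tests one fixed factor (pool); multi-factor or
  zero-inflated extensions are out of scope.
- When a taxon is essentially absent from one pool (all or nearly all
  zero counts), its fold-change posterior is bounded below only by the
  weak fixed-effect prior: the point estimate can far exceed the
  planted effect and the credible interval is very wide. The
  significance flag remains reliable; the magnitude should be read
  together with its interval.
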