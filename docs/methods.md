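# Methods

`coreshift` implements the statistical core of a multi-stress plant-microbiome
study design: several stress treatments applied to replicate plants, 16S
amplicon profiling of root/rhizosphere communities into an OTU count table,
and the question of which community members respond to *stress in general*
rather than to one particular stressor. This note records the models, the
defaults and their rationale, what the synthetic-data generator does and does
not emulate, and the numerical choices.

## The experimental design being emulated

The reference design has four groups — control plus three stressors (copper
toxicity, drought, shade) — with eight plants per group, one community profile
per plant, and sequencing libraries rarefied to a common depth of 19,000 reads
for community analysis. All pipeline defaults (group sizes, rarefaction depth,
thresholds) mirror that design.

## Synthetic data generator

Latent ("basis") OTU abundances are log-normal: per OTU a base log-mean is
drawn from N(0, `basis_log_mean_sd`²) and each sample adds N(0,
`basis_log_sd`²) noise. Planted effects multiply basis means by
2^(±`effect_log2`) — in all three stress groups for *core* OTUs, in exactly
one group for treatment-specific OTUs (alternating sign within a treatment so
both directions occur). Planted inter-OTU associations enter as off-diagonal
entries of the multivariate-normal correlation matrix of the log-basis.
Observed counts are multinomial draws of each sample's depth (uniform on
`depth_range`) from the normalized basis, so the data are compositional by
construction and column sums equal the drawn depths exactly.

Key defaults, with units and rationale:

| parameter | default | rationale |
|---|---|---|
| `samples_per_group` | 8 | replicate plants per treatment in the emulated design |
| `treatments` | control, copper, drought, shade | the emulated stressor panel |
| `depth_range` | 19,000–60,000 reads | spans the rarefaction depth used for community analysis; per-sample depth heterogeneity forces rarefaction to be exercised. The emulated study does not report per-sample depth variability, so the upper bound is a realistic stand-in, not a reported value |
| `n_otus` | 50 | small enough for fast tests, large enough for FDR behavior to be meaningful |
| `n_core_up`/`n_core_down` | 5/5 | both directions of the shared response present |
| `n_specific_per_treatment` | 3 | treatment-specific responders exist but are a minority |
| `effect_log2` | 1.5 | a ~2.8-fold latent shift: detectable at n = 8 but not trivial |
| `corr_strength` | 0.8 | strong planted association, the regime the correlation estimator is meant to flag |
| `basis_log_mean_sd` | 1.0 | realistic spread of mean abundances (roughly 2 orders of magnitude across the community) |
| `basis_log_sd` | 0.5 | per-sample biological variability; ~0.7 log2 units, so `effect_log2 = 1.5` is a ~2-sd effect |
| `planted_log_mean_offset` | −1.5 | responsive OTUs in the emulated study are individually minor members that *collectively* carry on the order of 10–15 % of community abundance; drawing planted OTUs from a lower base abundance reproduces that share (~12 % realized) |

The offset matters beyond realism: because effects are planted on basis means
*before* normalization, planted shifts necessarily perturb the relative
abundances of every other OTU. If planted OTUs carried a dominant share of the
community, unplanted OTUs would show genuine (induced) relative-abundance
shifts and any caller evaluated against the latent truth would appear to have
a high false-discovery rate. With planted OTUs at a ~12 % share the induced
distortion is well inside the per-sample noise.

What the generator does **not** emulate: sequence-level artifacts (chimeras,
contaminants, organelle reads beyond what tests construct explicitly),
phylogenetic autocorrelation of effect sizes (the tree is random relative to
the effects), overdispersion beyond log-normal × multinomial, and the
rhizosphere/root compartment contrast (one compartment per dataset). Passing
tests therefore demonstrate correctness and calibration of the *statistics*
under the model's assumptions, not robustness to those artifacts.

Determinism: all draws descend from one root seed through named substreams
(`basis`, `depths`, `counts`, `tree`, `omics`), so any piece can be
regenerated independently and a fixed seed reproduces tables bit-identically.

## Diversity statistics

**Rarefaction** subsamples each column to the target depth without replacement
(multivariate hypergeometric; one child seed per sample); samples below the
depth are dropped.

**Shannon diversity** uses H = −Σ pᵢ ln pᵢ after dropping OTUs at relative
abundance ≤ 0.01 % and renormalizing — the low-abundance floor suppresses
noise from rare taxa. Natural log.

**Weighted UniFrac** is the branch-length-weighted community distance:
raw d(A,B) = Σ_b ℓ_b·|p_A(b) − p_B(b)|, where p_X(b) is the fraction of
sample X's reads descending through branch b; the normalized variant divides
by Σ_b ℓ_b (p_A + p_B). The default is the raw variant, with normalization
behind a flag; the tests include an exhaustive per-branch oracle. The
computation itself is delegated to scikit-bio.

**PCoA** is classical metric scaling: eigendecomposition of the
double-centered squared-distance matrix; negative-eigenvalue axes are reported
but excluded from coordinates.

**PERMANOVA** partitions the squared distances (total SS = Σd²/n; within-group
SS per group; pseudo-F = (SS_between/(a−1))/(SS_within/(n−a))) and permutes
sample-to-group labels. The **within/between test** compares the list of
within-group-A distances to the A↔B between-group distances with a pooled
two-sample t statistic, permuting the group assignment within the union;
swapping the arguments gives the asymmetric counterpart. Both use the add-one
convention p = (1 + #extreme)/(1 + n_perm), so p is never exactly 0. Note
that under assignment permutation the exact floor 1/(n_perm+1) is generally
unattainable: permutations recreating the original split reproduce the
observed statistic and are counted by the ≥ convention, so the attainable
minimum is ≈ 2·n_a!·n_b!/n!. When both distance lists are constant the t
statistic is ±∞ by the sign of the mean difference (0 if equal).

## Stress-responsive OTUs

Per stress treatment, each OTU's relative abundance (post-rarefaction) is
compared to control with the equal-variance two-sample t-test; zero-variance
ties give p = 1, direction 0. Benjamini–Hochberg runs across OTUs *within*
each treatment, and an OTU is responsive iff raw p < 0.05 **and** BH q ≤
0.10 — the conjunction is the only reading that uses both stated thresholds.
The cross-treatment tally counts, per OTU, the treatments in which it is
responsive and whether all its significant directions share one sign; OTUs
responsive in >1 treatment with a consistent direction are the core stress
set. The responsiveness summary reports, per treatment, the community share
(%) and count of OTUs responsive in exactly 3/3, 2/3 and 1/3 treatments.

Response-profile clustering uses average-linkage hierarchical clustering on
Euclidean distances of log2((mean_t+ε)/(mean_c+ε)) profiles, with ε = half
the smallest nonzero mean. The dendrogram is cut at the smallest merge height
whose flat clustering leaves every cluster at `min_cluster` members — a
deliberate, simpler stand-in for hybrid dynamic tree cutting, which the
emulated analysis used but did not parameterize. Rows are clustered in a
canonical ordering so the partition is invariant to input row order.

## Treatment classifier

Gaussian naive Bayes (via scikit-learn, which is also what the emulated
analysis used) on relative abundances of OTUs present (nonzero) in ≥ 80 % of
samples, boundary inclusive. Per-class priors are empirical (uniform behind a
flag); class-conditional variances carry the conventional smoothing floor of
1e−9 × the largest feature variance. Prediction is in log space with
deterministic argmax tie-breaking by class-name order. Evaluation is
leave-one-out; the collapsed view maps copper/drought/shade to one "stress"
label, asking whether a stressed plant is recognizable as stressed at all.

## Compositional correlations (SparCC)

The estimator recovers correlations between latent basis abundances from the
log-ratio variation matrix t_ij = Var(log(fᵢ/fⱼ)). Under sparsity, basis
variances ω solve M·ω = rowsums(T) with M = (D−2)I + 11ᵀ, and
ρᵢⱼ = (ωᵢ + ωⱼ − tᵢⱼ)/(2√(ωᵢωⱼ)), clipped to [−1, 1] with clip events
counted. The strongest pair with |ρ| above the exclusion threshold (default
0.1) is removed from the system — its tᵢⱼ leaves both row sums and all four
affected entries of M are decremented, since ωⱼ also leaves row i's
coefficient — and the solve repeats, up to 10 exclusions. Per-sample
fractions are drawn from the Dirichlet posterior with add-one concentration
(counts + 1); the final ρ averages 20 such inner iterations. A deterministic
mode uses posterior-mean fractions and is bit-reproducible; exact
OTU-permutation equivariance holds in that mode (the sampled mode is
equivariant in distribution only). Nonpositive solved basis variances mark
the affected OTU's correlations undefined, with a warning — this occurs
mainly on very small sample counts.

Pseudo-p-values re-run the full estimator on bootstrap datasets in which
every OTU's counts are permuted across samples independently (association
destroyed, marginals preserved): p_ij = (1 + #{|ρ_null| ≥ |ρ_obs|})/(1 +
n_boot), two-sided, floor 1/(n_boot+1). Edge selection keeps pairs with
p < 0.1, ranks by descending signed ρ (absolute value behind a flag — the
emulated analysis says only "descending correlation score"), breaks boundary
ties lexicographically, and truncates to the top 10,000. The degree-rank
diagnostic thresholds an edge list at a ladder of |ρ| cutoffs and reports the
Spearman agreement of node-degree ranks between cutoffs plus the edge-count
curve — high agreement justifies fixing a top-k edge count.

A note on the "null maximum |ρ|" check: the maximum over all D(D−1)/2 null
pairs is a stochastic extreme (measured range 0.20–0.31 over 20 generator
seeds at D = 40, n = 200), so tests assert it on the mean of three replicate
datasets rather than a single draw.

## Networks

Hub subnetworks keep the `top_n` highest-degree nodes — ties at the boundary
all included, so selection is deterministic — plus their immediate neighbors,
as a vertex-induced subgraph. Merging per-treatment subnetworks takes the node
union with per-node treatment-membership sets; membership is node presence in
a treatment's hub subnetwork (an edge-level definition would be stricter; the
node-level reading matches the set-overlap presentation of such figures).
Classes — per-treatment-only, shared-k, and the all-treatment core — partition
the merged node set, asserted on every run. Edge attributes keep per-treatment
ρ separately, since each treatment's network is a separate estimation.
Taxonomy composition resolves lineages at phylum or class rank (substring
prefixes `p__`/`c__`; unresolvable → "unclassified"), with optional splitting
of Proteobacteria to class level.

## OTU–omics links

All feature pairs across two matrices are tested with Pearson correlation on
shared samples (≥ 3; constant features skipped with a warning); p-values via
the t transform with n−2 df, two-sided. Records with raw p < 0.05 are kept —
deliberately without FDR, matching the emulated analysis; a BH option exists
but is off by default. OTU abundances enter as relative abundances by default
(clr behind the caller's choice of input). Feature ranking counts distinct
partners, descending, ties by id. The signed log2 fold change is
sign(r−1)·log2(max(r, 1/r)) for r = mean_t/mean_c: magnitude symmetric up and
down, sign marking direction.

## Problem sizes used by the test suite and acceptance script

Chosen as the smallest sizes at which each property is statistically
meaningful: UniFrac oracle on 50 random trees of ≤ 8 tips; BH oracle on 1,000
random vectors; SparCC recovery at D = 40, n = 200 (planted ρ = 0.8, ±0.15)
and pseudo-p calibration at D = 25/15, n = 100 with 100 bootstraps; caller
operating characteristics over 50 simulated experiments at `effect_log2` =
1.5; permutation-test calibration over 200 null replicates of 12 samples;
classifier checks at `effect_log2` = 2; and one full pipeline run on the
default 50 × 32 dataset.

## Known limitations

- The rule "raw p < 0.05 AND BH q ≤ 0.10" is one reading of a dual
  threshold; pre-filtering at 0.05 before BH at 0.10 would differ slightly.
- Average-linkage + height scan is not dynamic tree cutting; cluster counts
  on real data would differ.
- SparCC assumes sparsity of strong correlations; dense correlation
  structure biases the basis-variance solve.
- The within/between permutation test permutes sample assignments; permuting
  distances instead would change the achievable p floor.
- Compositional distortion of unplanted OTUs is inherent to the generator's
  design (effects on basis before normalization) and is only negligible
  because planted OTUs are a minor community share.
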