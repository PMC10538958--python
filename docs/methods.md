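# Methods

This package reimplements, as a tested pipeline over synthetic data, the
statistical analysis chain of a four-arm intermittent-fasting study of
heart tissue: an ad libitum control (AL) against daily 12-h and 16-h
fasting (IF12, IF16) and every-other-day fasting (EOD). The chain runs
from TMT reporter intensities and label-free phosphosite intensities to
differential calls, annotation enrichment, kinase motif enrichment, a
co-regulation perturbation network, interaction-network clustering, and
transcript-protein integration. Every stage is driven by a generator
that plants known effects, so recovery and calibration are measurable.

## Study design

The default design mirrors the study layout: proteome n = 4/5/5/4
(AL/IF12/IF16/EOD) across two TMT 10-plex sets of nine samples each plus
a pooled-AL reference in channel 126; phosphoproteome n = 3 per group
(label-free); transcriptome n = 5 per group. Groups are split across the
two plexes so plex effects are not confounded with diet.

## Synthetic data model

**Proteome.** Latent protein abundances are log-normal (log2 mean 20,
sd 2 by default). Each plex adds a per-protein batch shift
~ Normal(0, batch_sd = 0.3) and each channel a multiplicative loading
factor (log2 sd 0.15) that total-intensity normalization must remove. A
configurable fraction of proteins carries a signed log2 effect in one
non-control group. Sample channels carry measurement-plus-biological
noise of sd `sigma` (default 0.25 log2 units); the reference channel is
the mean of the control latent abundances with noise
`sigma / sqrt(n_control)`, since pooling the control animals averages
their biological variability. Reference-ratio computation then cancels
the plex batch term exactly — which is the point of the pooled internal
reference.

**Phosphoproteome.** Sites carry a 13-mer flanking window whose center
residue is S/T/Y at 80/19/1% frequencies, and a localization probability
drawn from a two-component Beta mixture — Beta(60, 2) for confident
sites (weight 0.84) and Beta(6, 6) otherwise — so roughly 84% of sites
are class I at the 0.75 cutoff. Missingness is missing-not-at-random:
P(missing) is logistic in the centered log2 intensity with slope
`missing_steepness` (default 0.8) and a baseline rate (default 0.25);
steepness 0 degenerates to uniform missingness. The real study does not
describe its missingness mechanism; this logistic dropout is an
assumption, exposed as parameters.

**Transcriptome.** Gene-level log expression shares a standardized
component with the proteome latent abundances with weight `target_corr`,
then counts are negative-binomial (dispersion 0.1) with gene lengths of
0.3–10 kb. Count and length noise attenuate the realized cross-feature
correlation only slightly, so the realized log-FPKM vs log2-protein
Pearson r lands within a few hundredths of the target (default 0.47, the
modest transcript-protein concordance typical of tissue studies).

**Co-regulation and perturbations.** Designated protein pairs share a
standard-normal latent profile plus member noise (sd 0.15, giving
|rho| ≈ 0.98; any value ≤ 0.33 keeps |rho| ≥ 0.9), with half the pairs
sign-flipped. A perturbation event displaces one sample's value in one
member by `displacement` units of the pair's conditional
(residual-from-correlation) sd — the scale on which a deviation from a
correlation is measured and the scale the Mahalanobis screen sees. A
displacement expressed in marginal sd units would corrupt the Spearman
ranks so badly that no threshold recovers the network; the conditional
scale leaves the marginal ranks nearly intact while producing a
`displacement`-sd deviation for the detector.

**Annotations, PPI, motifs.** Planted annotation terms draw 80% of their
members from the planted differential features; other terms are uniform.
PPI graphs are unions of planted cliques and Erdős–Rényi background.
Motif-bearing windows are planted into designated site clusters at a
60% match rate against a 10% background.

All generators split one integer seed into fixed per-generator child
seeds (`SeedSequence(seed, spawn_key=(k,))`), so identical configuration
and seed reproduce every table byte-for-byte.

## Statistical procedures

**Differential testing.** Per feature, one-way ANOVA pooled variance
(df = N − k) feeds Dunnett many-to-one statistics
t_i = (mean_i − mean_0)/(s·sqrt(1/n_i + 1/n_0)). The family-wise
adjusted p-value P(max_j |T_j| ≥ |t_i|) is estimated by Monte Carlo
under the equicorrelated multivariate-t null (default 50,000 draws,
seeded): group means and the pooled variance are simulated directly,
which reproduces the null law without evaluating its density. The draw
depends only on the design signature and is cached, so testing thousands
of features costs one simulation. Proteome calls use strict
adjusted p < 0.01; phosphosite calls use adjusted p ≤ 0.05, after a
class-I filter (localization ≥ 0.75), a ≥ 2-replicates-per-group filter
on observed values, and per-sample down-shifted normal imputation
(width 0.3, shift 1.8 — the de-facto convention for representing
intensities near the detection limit). The replicate filter precedes
imputation, so no site is tested on purely imputed values in any group.

**Rank annotation enrichment.** The 1-D position score is
s = 2·(mean rank of members − mean rank of non-members)/N ∈ [−1, 1]
(equivalently 2U/(n_in·n_out) − 1), with a two-sided Mann–Whitney
p-value (exact enumeration for N ≤ 20 without ties, otherwise the
normal approximation with tie and continuity corrections). The 2-D
analysis scores each dimension the same way and tests the joint shift
with a Hotelling T² on the rank-transformed coordinates
(F(2, n−3) approximation); numerically collinear dimensions are ridged
and flagged. BH adjustment runs within each enrichment run. Terms with
fewer than five scored members are skipped — rank scores on tiny terms
are unstable.

**Exact tails.** Fisher enrichment p-values are hypergeometric upper
tails on the table margins, computed through log-gamma arithmetic;
identity with exhaustive enumeration is asserted for every 2×2 table
with N ≤ 12.

**Co-regulation perturbation analysis.** Spearman correlations over all
protein pairs across all 18 samples, BH-adjusted; edges with q ≤ 0.01
are retained (both signs). Per edge, each sample's pair of values is
scored by Mahalanobis distance against the mean and covariance estimated
from all samples; with estimated parameters the squared distance scaled
by n/(n−1)² has an exact Beta(1, (n−3)/2) null, through which distances
are mapped to standard-normal scores. The single-outlier screen on those
scores is the one-sided maximum test with Bonferroni correction on the
known null — the known-scale form of Grubbs's procedure. The classical
studentized Grubbs test (available via `outlier_test="grubbs"`, and as
`stats.grubbs_one_sided_max`) re-estimates the scale from the 18 scores,
which the covariance-estimation sum constraint biases low; measured on
null data it flags ≈ 12% of edges at α = 0.1 versus ≈ 10% for the
known-null form (raw chi-distributed distances are worse, ≈ 17%). A
residual ~1 percentage point of inflation from the dependence of scores
within an edge remains and is visible only when aggregating many
datasets. Consensus perturbation per group uses the hypergeometric upper
tail over deduplicated (sample, protein) instances — a protein counts
once per sample however many of its edges flagged it. Note that a
single-outlier screen yields at most one instance per edge, so only
proteins with several co-regulation partners can accumulate the repeated
instances that group consensus requires; the consensus test scenario
therefore plants a hub protein with four partners deviating in EOD
samples.

**Network clustering.** Cohesiveness
f(V) = w_in/(w_in + w_bound + penalty·|V|) with the published default
penalty 2. Growth proceeds from unvisited seeds in descending degree,
applying the single add/remove step that most increases f, with one
tie-break: when no strictly improving step exists, an f-preserving
removal is applied (prefer the smaller cluster). The tie-break matters
because for 6-member cliques at penalty 2 a pendant vertex is exactly
cohesiveness-neutral (Δw_in = 1 against Δdenominator = 2 at f = 0.5) and
would otherwise be kept forever once grabbed early in growth. Clusters
overlapping at ω = |A∩B|²/(|A||B|) ≥ 0.8 merge. Significance: one-sided
Mann–Whitney of internal vs boundary edge weights for weighted graphs;
for unweighted graphs, where constant weights degenerate the rank test,
an empirical p from 100 degree-preserving rewirings (shared across
clusters), with p = 0 for boundary-free (maximally separated) clusters.
Clique recovery degrades gracefully with background size: beyond roughly
forty background nodes at density 0.02, absorbing boundary vertices
becomes strictly beneficial under the penalty-2 score, so the recovery
fixtures use two 6-cliques over 20 nodes.

**Transcriptome integration.** FPKM = counts·10⁹/(length·library size);
fold changes log2((mean_g + 1)/(mean_AL + 1)); the transcript-protein
correlation is a cross-feature Pearson r between mean log FPKM and mean
log2 normalized protein abundance with group-mean pairing, because the
proteome and RNA animals are different mice.

## Problem sizes

The test suite and the acceptance script run the pipeline at reduced but
statistically meaningful scales chosen as the package's reference
conditions: 2,000 proteins for differential recovery and calibration
(2,000 null simulations for the family-wise error), 300 proteins /
50 pairs / 30 events for the perturbation chain, 2,000 features for
rank-enrichment calibration (200 shuffles; 500 null replicates for 2-D
uniformity), 10,000 sites for phosphosite composition, 2,000 genes for
the transcript-protein coupling, and a 150-protein end-to-end
determinism run.

## What the synthetic data does not capture

Homoscedastic log-normal noise (no intensity-dependent variance or
heavy-tailed contamination), no peptide-to-protein rollup ambiguity, no
isotopic impurity between TMT channels, no shared-peptide phosphosite
ambiguity, no correlated gene modules beyond the planted structures, and
no circadian or time-course structure. Passing recovery tests therefore
demonstrates the correctness and calibration of the procedures under the
stated model, not their field performance on real LC-MS data.

## Known limitations

- The Dunnett adjustment is Monte Carlo; adjusted p-values carry
  O(1/sqrt(reps)) noise and are floored at the raw p.
- Flagging features at a per-feature family-wise threshold (the
  convention implemented here) controls the per-feature error rate, not
  the across-feature FDR: with 2,000 features of which 5% carry effects,
  calibrated testing at adjusted p < 0.01 yields a realized
  false-discovery proportion near 0.15. Cross-feature BH can be applied
  downstream by the caller when an FDR guarantee is wanted.
- The co-regulation screen tests one outlier per edge; two perturbations
  of the same pair mask each other.
- Greedy cohesiveness clustering is a local search; only the planted-
  clique regime described above is certified by tests.
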