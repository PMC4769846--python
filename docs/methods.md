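# Methods

This note documents the statistical model behind each pipeline stage,
the tunable parameters and their defaults, what the synthetic-data
generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Study design assumptions

The pipeline assumes a paired stimulation design: every subject
contributes one stimulated and one unstimulated sample, subjects belong
to one of several clinical groups, and the unit of "response" analysis
is the per-subject log2 ratio stimulated − unstimulated. Subjects are
the exchangeable units of every case/control contrast; samples are not.
Group labels are free strings, and the case/control contrast for the
differential network stage is named in the configuration rather than
hard-coded, because a three-group study runs several pairwise contrasts.

## PVAC probe-set filtering

For a probe set with P probes measured on n samples, each probe is
standardised across samples and the score is the largest eigenvalue of
the P×P probe correlation matrix divided by P — the fraction of
variance explained by the first principal component. Probes measuring a
common signal give a score near 1; probes measuring independent
background give a score near 1/P. Scores are computed separately per
clinical group (both conditions pooled — the filter asks whether the
set measures *anything* reliably in that group, not whether the signal
responds to stimulation), and a set is retained if it reaches the
threshold (default 0.4) in at least one group.

Numerical notes: probes are standardised rather than merely centred, so
the score is invariant to per-probe affine rescaling; zero-variance
probes are dropped with a warning and a set left without informative
probes raises a degenerate-data error; single-probe sets score 1.0 with
a warning that PVAC is uninformative there. The null distribution of
the score matters for interpretation: with P = 4 probes the largest
eigenvalue of a pure-noise correlation matrix concentrates near the
0.4 threshold only once a group has roughly 40+ samples, so the filter
is sharp at the default design (44–52 samples per group) but noisy on
very small pilot groups.

Gene-level summarisation of a retained set subtracts each probe's
across-sample mean, averages probes, and adds back the set's grand
mean, preserving the log2 scale.

## Differential expression

Within-group comparisons are one-sample t-tests on the subject log
ratios (algebraically the paired t-test); between-group comparisons are
two-sample t-tests on the log ratios, pooled-variance by default with
Welch as an option. Ordinary (not variance-moderated) t statistics are
the default engine throughout: the differential network stage is
defined in terms of the standard t statistic and its 1.96 boundary, and
moderation would silently shift that geometry. Multiple testing uses
Benjamini–Hochberg step-up q-values. Genes with zero variance of
differences are retained with p = 1 and a degenerate flag rather than
dropped, keeping gene indices aligned across stages. PCA of responses
centres genes across subjects without standardising them, so
high-amplitude response genes dominate the leading axes (the intended
reading of a response map).

## Signed networks and modules

The signed similarity s_ij = (1 + cor(x_i, x_j))/2 maps correlation
[−1, 1] onto [0, 1]; a perfectly anti-correlated pair gets similarity
0, not 1 as in unsigned analysis. Soft-thresholding raises s to the
power β (default 12, the conventional choice for signed networks,
configurable); the topological overlap measure
TOM_ij = (ℓ_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij), ℓ = A², quantifies
shared neighbourhoods. Modules are flat clusters of an average-linkage
dendrogram on 1 − TOM cut at a fixed height (default 0.98), with
clusters below the minimum size (default 30) relabelled grey. The
static cut was chosen over the dynamic hybrid tree cut because it is
fully deterministic and directly testable; the dynamic cut is an
extension point, and on well-separated synthetic blocks the two agree.
Modules are colour-named in decreasing size with ties broken by the
smallest member gene id, so naming is deterministic under gene
reordering.

By default group networks are built on the log-ratio (response) scale —
the analysis object is the stimulation response — with the expression
scale available through the library API.

Zero-variance genes receive correlation 0 (similarity 0.5) with a
warning, keeping matrices total.

## Connectivity and the differential network plane

A gene's connectivity K_i is its summed edge weight to all other genes,
computed per group and scaled by the group network's maximum so the
two groups are comparable; the differential connectivity is
diffK = K₁s − K₂s ∈ [−1, 1].

The edge weight that K sums is configurable (`connectivity_basis`), and
the default is the soft-thresholded adjacency, not the raw signed
similarity. This is a deliberate design decision: raw similarity sums
carry a constant baseline of (n − 1)/2 from the s = 0.5 expectation of
uncorrelated pairs, which dominates K for any realistic gene count, so
scaled connectivity concentrates near 1 for every gene and |diffK|
cannot reach the 0.3 sector boundary regardless of how strongly a
module is rewired (at 200 genes the attainable maximum is ≈ 0.05). The
±0.3 boundary is only meaningful when the background contribution is
suppressed, which is exactly what soft-thresholding does. The
similarity basis remains available for sensitivity analysis.

The (t, diffK) plane is divided into eight sectors by strict
inequalities at |t| = 1.96 and |diffK| = 0.3: R2/R6 are differentially
expressed only, R4/R8 differentially connected only, and the corners
R1/R3/R5/R7 both, numbered clockwise so that R3 is "up in both
dimensions in cases". Boundary values are non-significant. Swapping
case and control negates t and diffK exactly and induces the sector
bijection R1↔R5, R2↔R6, R3↔R7, R4↔R8 — an invariant asserted to
machine precision in the tests.

### Permutation null

Sector counts are compared with those from B random reassignments of
subjects to pseudo-groups of the original sizes (default B = 1000).
Each permutation recomputes the t statistics, both group networks'
scaled connectivities, diffK, and the sector counts; the per-sector
p-value is the add-one upper tail (1 + #{count_b ≥ obs})/(B + 1), which
never reports 0 and has floor 1/(B + 1) ≈ 0.001 at the default B. All
randomness flows from a single configured seed through one child stream
per pipeline stage, so a fixed configuration reproduces every
permutation byte for byte. The permutation loop is vectorised
(correlation matrices per permutation via BLAS); B = 1000 on 1,500
genes × 48 subjects completes in a few minutes on one CPU.

## Upstream regulator statistics

Two statistics are computed per signed regulon against a chosen DE
result: the overlap p-value, a hypergeometric upper tail for the count
of regulon targets among the DE-called genes within the analysis
universe, BH-adjusted across regulons; and the activation Z-score,
Z = (n_agree − n_disagree)/√(n_agree + n_disagree) over regulon members
with both a predicted sign and an observed direction call, with |Z| > 2
(strict) flagged significant. Members without an annotated sign count
toward the overlap test but not toward Z. The unweighted ±1 agreement
form is used and stated in the output metadata; commercial
implementations add unpublished literature-confidence weights that are
not reproduced here. Direction calls default to q < α with the sign of
the effect, configurable to raw p (useful at small sample sizes, where
the FDR-based call set is small and unstable).

## Cohort statistics

Prevalence rows are compared by Pearson chi-square without continuity
correction (required to reproduce printed three-group table p-values;
Yates is available for 2×2 only), continuous measures by tie-corrected
Kruskal–Wallis. When the overall test is significant, pairwise
comparisons are Bonferroni-adjusted by default (the adjustment is
configurable and recorded in the output) and summarised as a compact
letter display computed from the maximal cliques of the
"not-significantly-different" graph, which naturally yields overlap
classes such as "a,b" for a middle group distinguishable from neither
extreme. Percent→count reconstruction rounds half away from zero and
refuses values that are not within 0.05 percentage points of an
integer count — the signature of a row whose denominator is not the
stated group size (e.g. missing data).

For a 2×3 table (2 degrees of freedom) the chi-square survival function
has the closed form p = exp(−χ²/2), which the tests use as an exact
oracle.

## The synthetic-data generator

The generator emulates the study design the pipeline assumes: three
clinical groups (default sizes 22/26/24) with paired samples; gene
expression x = μ_i + λ_{m(i),g}·z_{m(i),s} + δ_i·stim + Δ_i·stim·case +
ε on the log2 scale (baseline μ ~ N(8, 1), noise σ = 0.5); probe-level
data with per-probe offsets ~ N(0, 0.3²) and probe noise 0.2; a
controllable fraction of noisy probe sets whose probes track
independent signals of matched variance; and optional additive batch
shifts. Ground truth (planted DE genes per group, differentially
connected genes per contrast, module membership, noisy sets) is
returned with the data.

Design choices that matter:

- **Single latent factor per module.** The simplest generative model
  that yields block-correlated expression with tunable connectivity.
  Differential connectivity is induced through group-specific loadings
  rather than rewiring, matching a correlation-driven statistic.
- **Per-sample latent activity.** z is drawn per sample, not per
  subject, so module coexpression survives in the log ratios the
  network stages analyse (a purely subject-level factor would cancel in
  stimulated − unstimulated differences).
- **Conditional simulation.** z is standardised within each
  (module, group, condition) stratum after drawing. Without this the
  realised factor variance is chi-square distributed — at 20 subjects
  it ranges over roughly a third to twice its nominal value — and the
  soft power β = 12 amplifies that fluctuation several-fold in the
  adjacency, so a generator that merely samples the factor can fail to
  plant the differential connectivity its truth labels claim.
  Standardising makes a loading λ map deterministically onto the
  planted coexpression strength, which parameter-recovery testing
  presupposes.
- **A shared reference module in recovery scenarios.** Max-scaling of
  connectivity compares each gene against the most connected gene of
  its own network. If the control network is structure-free, its
  maximum is a noise order statistic and scaled connectivity there is
  ill-defined, compressing diffK toward zero no matter how strong the
  planted case module is. Real transcriptome networks always carry
  dominant co-regulated modules in every group, so recovery scenarios
  plant one module with differential loading *and* one module with
  equal loading in both groups.

What the generator does **not** emulate: scanner-level intensities and
artefacts, RNA degradation, probe GC effects, correlated noise between
modules, heavy-tailed expression distributions, and any real gene
identity or annotation. Passing tests therefore demonstrate that the
statistics recover the structure they are defined on, at realistic
sizes and noise levels — not that any particular biological claim
about real data is reproduced.

## Problem sizes used by the test suite and acceptance script

Simulated checks run at 120–500 genes with the study's group sizes
(or 20+20 subjects for two-group contrasts) and B = 200 permutations —
scales chosen so the whole suite completes in seconds while leaving
every statistic in its operating regime (e.g. ≥ 40 samples per group
where the PVAC null requires it). Sector geometry, oracle equivalences,
and antisymmetry are size-independent and tested on small random
instances.

## Integration recipe for the deposited real data (GSE73482)

The original study's absolute numbers — per-group DEG counts in the
hundreds, 1442 retained probe sets, 7 and 5 modules with a 406-gene and
an 85-gene disease module, 25 region-3 genes at p ≈ 0.001 — depend on
the deposited raw arrays plus a preprocessing chain outside this
package's scope. Users who wish to run the pipeline on the real data
should:

1. Download the raw CEL files of GEO series GSE73482.
2. Preprocess in R/Bioconductor: RMA with the custom Entrez-gene CDF
   (`hugene10sthsentrezgcdf`), array QC (drop failing samples), and
   ComBat correction for the two hybridisation-date batches.
3. Export the gene-level log2 matrix and probe-level matrix as TSV, and
   build the sample sheet (subject, group, condition) from the series
   metadata.
4. Run `diffconet run --probes ... --sheet ... --case ... --control ...`
   or the individual subcommands; PVAC filtering (threshold 0.4, per
   group, retain-if-any) then reproduces the published filtering rule,
   and the remaining stages follow the published analysis choices.

Step 2 deliberately stays in established Bioconductor tooling; this
package starts at the matrix level.

## Known limitations

- The static tree cut needs a sensible cut height; very weak modules
  merge into grey rather than being rescued as the dynamic cut might.
- Scaled connectivity is a *relative* quantity; diffK comparisons
  assume both networks carry comparable dominant structure (see the
  generator notes above).
- The permutation test recomputes full correlation matrices per
  permutation; beyond ~20k genes a block-wise implementation would be
  needed (out of scope).
- Empirical-Bayes variance moderation, module eigengenes, module
  preservation statistics, and batch *correction* (as opposed to batch
  simulation) are not implemented.
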