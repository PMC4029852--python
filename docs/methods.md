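# Methods

## Design and scope

`co2prof` analyzes a probes × samples matrix of positive, linear-scale
normalized signals over k ordered conditions (default three: ambient /
elevated / high CO₂) with r ≥ 2 biological replicates each.  Upstream
array processing (probe summarization, MAS5/RMA-style normalization) is
out of scope: the pipeline ingests its output and performs its own log2
transforms.  All stages operate on probe identifiers; an optional
probe→gene collapse is deliberately not applied by default because no
principled rule exists without chip annotation.

## Randomized variance model

With m = n_samples − k residual degrees of freedom per gene, the
ordinary per-gene variance estimate s² is unstable at r = 3.  The model
places a Gamma(a, scale b) prior on residual precision 1/σ², under which

&nbsp;&nbsp;s² · a·b ~ F(m, 2a).

`fit_rvm_prior` maximizes the summed log marginal density of the
observed s² values over (log a, log b) (Nelder-Mead from four
moment-based starts, function tolerance 1e-8; the log-parametrization
makes positivity structural and the multi-start guards against the
likelihood's flat ridge at large a).  Degenerate inputs — all s² equal —
push a → ∞ and raise a boundary error instead of silently clipping;
s² below 1e-12 is floored with a warning.  The moderated variance
σ̃² = (m·s² + 2/b)/(m + 2a) shrinks each gene toward the prior mean
variance 1/(a·b), and F̃ = MS_between/σ̃² is referred to F(k−1, m+2a).
As a → ∞ at fixed a·b this reduces to a fixed-variance test; at a → 0
it reduces to the ordinary ANOVA F.  Genes are selected by the
conjunction p < 0.05 and Benjamini–Hochberg q < 0.05 (both thresholds
recorded in the run manifest); the conjunctive reading was chosen over a
sequential one because it is the stricter and more reproducible rule.
Multiple-testing adjustment is delegated to
`statsmodels.stats.multitest`.

The companion `one_way_anova_lsd` implements the classic one-way ANOVA
with Fisher's LSD post-hoc test and a compact letter display (maximal
cliques of the "not significantly different" relation, lettered in
descending-mean order), as used for phenotype tables such as growth and
hormone panels.

## Profile clustering

Selected genes are summarized as v with v[t] = mean log2 signal at
condition t minus the reference mean, so v[0] ≡ 0.  The 16 shipped
model profiles are integer shape vectors anchored at 0, entries in
[−3, 3], steps of at most 2.  Two of the shipped shapes would otherwise
be identical; the set ships with (0, 0, −1) and its mirror (0, 0, 1) so
that both late-response directions are present and shapes are unique.
Assignment maximizes the Pearson correlation between v and the shape
(scale-free, the STEM convention; Euclidean distance was considered and
rejected because the magnitude of a profile's integer coding is
arbitrary).  Flat vectors are unassignable (correlation undefined) and
are reported, not dropped silently; exact ties break toward the lowest
profile id.  No minimum-correlation floor is applied by default —
`min_corr` exists for users who want an exclusion rule.

The permutation null applies every ordering of the condition positions
(3! = 6 for three conditions, identity included) to each vector,
re-anchors at the new first position, re-assigns and averages the
counts.  Two exact consequences are tested as invariants: every
expected count is a multiple of 1/6, and Σ expected = Σ assigned
(flatness is permutation-invariant).  Profile significance is the upper
binomial tail P(X ≥ assigned) with X ~ Binomial(total, expected/total),
accumulated as a logsumexp of log-pmf terms so that tails far below
1e-300 keep an exact magnitude (`profile_log10_significance`).  An
expected count of zero with a positive observed count yields p = 0 with
a warning.

## Enrichment

One-sided over-representation only: p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n), categories intersected with the background
before counting, categories without study hits omitted.  The background
defaults to all probes on the array rather than the genome — the
defensible universe for chip data — and is configurable.  The
enrichment ratio Re = (k/n)/(K/N) supplements p; the GO-style screen is
p < 0.05 and Re > 5, the pathway-style screen p < 0.05 alone.  Raw p is
thresholded by default (BH adjustment behind a flag) to match the
screening convention this pipeline reproduces.  The EASE variant scores
the tail at k−1 (DAVID's conservative convention) and never alters Re.

## Signal network

Pearson correlations are computed across all samples of the selected
genes (9 points for the default design), not across the 3 condition
means — 3-point correlations are degenerate (|r| ≈ 1 almost surely).
Significance uses t = r√(d−2)/√(1−r²) on d−2 df, two-sided at α = 0.05
by default (`use_abs` off switches to a one-sided positive rule).
Catalog relations (directed, typed) survive only when their pair is
significantly co-expressed in either orientation.  Degree counts
distinct neighbors regardless of direction; indegree/outdegree count
distinct sources/targets.  Betweenness centrality uses unweighted
shortest paths (Brandes, via networkx) normalized by (N−1)(N−2)/2
undirected or (N−1)(N−2) directed; graphs with fewer than three nodes
have no interior pairs and return all zeros.  The undirected view is
the reporting default; ranking is by descending bc, then degree, then
gene id, so results are deterministic.

## qPCR

Technical replicates are averaged before any differencing; per
biological replicate ΔCt = Ct(target) − Ct(reference gene), ΔΔCt =
ΔCt(condition) − mean ΔCt(control), fold = 2^−ΔΔCt; the record reports
the mean and SD over biological replicates.  Amplification efficiency
is fixed at 2 (plain 2^-ΔΔCt); efficiency-corrected variants are out of
scope.  The construction is invariant to adding a constant to all Ct
values of a replicate block.  Platform concordance is the Pearson r
between array log2 fold changes and log2 qPCR folds over matched
(gene, condition) pairs (≥ 3 required).

## Synthetic data

The generator draws per-gene precision τ ~ Gamma(a, scale b), baseline
log2 level ~ Normal(8, 1.5) (a typical array signal range), and
replicate log2 signals Normal(condition mean, 1/τ); signals are emitted
as 2^value, so the analysis assumptions hold exactly and the marginal
law s²·ab ~ F(m, 2a) is property-tested by Kolmogorov–Smirnov.
Defaults define the desk-scale demo: 5,000 genes (the full ~61k-probe
array is reachable by config), 3 conditions × 3 replicates, a = 3,
b = 0.5 (mean residual variance 1/(b(a−1)) = 1 on the log2 scale),
10% DE genes distributed over the five transient/reversal profiles
{12: 0.35, 16: 0.20, 10: 0.15, 6: 0.15, 5: 0.15}, and a planted effect
of 4 log2 units per profile step — four noise SDs, the regime in which
profile assignment is reliably recoverable and co-expression edges
among same-profile genes survive the correlation screen.  A
non-uniform mix is essential: a uniform profile mix is its own
permutation null and produces no significant profiles.

Annotation categories (50 of size 50) sample members uniformly, except
five planted categories that weight DE genes 20:1; the interaction
catalog plants a bridge motif — two 6-cliques of same-profile DE genes
joined only through one bridge gene, giving it the dominant betweenness
— plus background relations over a small fraction (2e-4) of remaining
DE-gene pairs.  qPCR plates invert the 2^-ΔΔCt model with Ct noise SD
0.1 cycles.  One global seed feeds all generators through fixed stream
offsets (expression 0, annotations 1, qPCR 2), so stages are
independently reproducible.

What the generator does **not** emulate: probe-level intensities and
normalization residue, correlated noise between genes beyond the
planted profiles, batch or chamber effects, unbalanced designs, or
annotation redundancy (GO ancestor inflation).  Passing tests therefore
demonstrate correctness of the statistical machinery under its own
assumptions, not robustness to violations of them on real arrays.

## Numerical and reporting choices

Result tables are written with fixed float formatting so identical
configurations give byte-identical files; the manifest records every
threshold, the seed and output checksums.  Expression and qPCR files
round-trip exactly (`%.17g` writes, round-trip float parsing).  Test
problem sizes (10,000 genes for prior-recovery and calibration checks,
5,000 for the 100-seed end-to-end recovery study) were chosen as the
smallest at which the parameter-recovery tolerances and the 95%
recovery rates are comfortably stable.

## Known limitations

- The moderated test assumes a common residual df m (complete balanced
  design); missing values are rejected rather than imputed.
- The binomial profile-significance model treats gene assignments as
  independent draws; genes co-regulated in reality violate this, so the
  printed p-values are best read as ranking scores.
- Betweenness on very small intersected networks is coarse: few nodes,
  ties common — hence the deterministic degree/id tie-breaks.
- Real-data ingest expects pre-normalized positive signals; no
  cross-platform normalization is attempted.
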