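# Methods

## The haploid neutral epimutation-accumulation model

Each unit (a cytosine in one sequence context, or a 100-bp methylation bin)
is a two-state Markov chain over mitoses: an unmethylated unit gains
methylation with probability α per mitosis, a methylated unit loses it with
probability β. The organism is haploid, so there is a single copy per unit
and no genotype combinatorics: the divergence between two samples is the
plain probability of discordance of two independent chains that split at
their most recent common ancestor.

With π = α/(α+β) and c = 1 − α − β, the chain started in state s is
methylated after t mitoses with probability p_s(t) = π + (1[s=m] − π)cᵗ.
If the ancestor was methylated with probability p₀, the expected divergence
of two descendants on branches t_i and t_j is

    E[d](t_i, t_j) = Σ_{s∈{u,m}} P(s) [ p_s(t_i) + p_s(t_j) − 2 p_s(t_i) p_s(t_j) ],

which at p₀ = π depends only on Δt = t_i + t_j and collapses to
2π(1−π)(1 − c^Δt): linear growth at rate 2π(1−π)(α+β) initially, saturating
at the independence limit 2π(1−π). Time is measured in mitoses with 25
mitoses per culture transfer; edge lengths are computed from transfer
differences (an alternative published conversion of ≈1015 mitoses per
40-transfer line differs from 40×25 by 15 mitoses; we use the edge-based
arithmetic throughout and treat the constant as configurable).

Fitting minimises Σ (d_k − D₀ − E[d](α, β, p₀, t_i, t_j))² with bounded
L-BFGS-B from 100 random starts (α, β log-uniform in [10⁻⁹, 10⁻²], p₀
uniform in [0,1], D₀ uniform in [0, max d]). The intercept D₀ absorbs
replicate-level technical divergence, anchored by ancestor-replicate pairs
at Δt = 0. Near-tied optima (relative RSS within 10⁻³) break to the lower
gain rate.

**Identifiability.** The divergence curve is exactly invariant under
(α, β, p₀) → (β, α, 1−p₀) — relabelling the two states leaves discordance
unchanged — so with a free p₀ the two symmetric optima differ only by
sampling noise and the gain/loss labels are not identifiable from
divergence alone. The analysis pipeline therefore anchors p₀ to the
methylated fraction measured in the ancestor replicates (the information
the reference workflow takes from the ancestral methylome), which breaks
the symmetry decisively; `p0="equilibrium"` (pinning p₀ = π) and free p₀
remain available. When only saturated time points are present, only π and
α+β-type combinations are recoverable; fits pinned at a rate bound set a
`boundary_` flag and warn instead of failing silently.

## Model comparison

The no-accumulation null is a constant mean (1 parameter); the
phenomenological logistic alternative K/(1+exp(−r(Δt−t_m))) (3 parameters)
tests for *any* saturating growth without a rate interpretation. Nested
least-squares fits are compared with the F statistic
[(RSS₀−RSS₁)/(k₁−k₀)] / [RSS₁/(n−k₁)]; under Gaussian residuals this is
the likelihood-ratio test.

The analytic F reference is **conservative under the null**: with true
rates 0 the null sits on the boundary of the parameter space and the
monotone accumulation curve collapses to a constant, so F piles up at 0.
For calibrated inference the package provides a permutation variant: the
same F statistic, with its null distribution built by permuting divergences
against branch lengths, and a mid-p correction for the atom at F = 0. The
permutation argument requires exchangeable points under the null, which
holds for the ancestor-descendant pair set against a single ancestor
replicate (each point's sample-specific noise is independent; the shared
ancestor noise is a common shift absorbed by the constant). The all-pairs
set is used for point estimation and strength-of-evidence reporting, where
the paper-style framework likewise ignores the within-pedigree correlation
of pairs; the cluster bootstrap (resampling MA lines, reweighting the pair
set by line multiplicity) is the uncertainty summary that respects it.

## State calling and DMR segmentation

Per-cytosine states are called with a two-state HMM over the site index
within each chromosome: binomial emissions Binom(total, level_s) with
per-state methylation levels, distance-independent transitions, EM
(Baum–Welch) to convergence (tolerance 10⁻⁶, cap 500 iterations,
non-convergence warns and keeps the best model), posterior decoding.
Zero-depth sites carry no emission information and are reported *missing*
rather than imputed (an `impute` flag fills them from the chain posterior).
Emission levels are ordered so "unmethylated < methylated". Each strand's
cytosine is a distinct site; no symmetric-CpG collapsing is applied
(the methyltransferase at work here is not symmetric-context-bound).

DMR segmentation tiles each chromosome with fixed 100-bp bins. A bin is
*eligible* in a sample when ≥ 5 cytosines of the context have depth ≥ 5
and a called state; the bin is *methylated* when ≥ 50% of those qualifying
cytosines are called methylated (threshold configurable). A bin is a DMR
when at least two samples are eligible and disagree. The eligibility
reading "5 cytosines present at depth 5" (rather than "5 cytosines already
called methylated") is deliberate: the alternative would make unmethylated
bins uncallable. Outlier samples are flagged when the median of their
pairwise divergences exceeds the median of all samples' medians by more
than k (default 3) unscaled median absolute deviations.

## Divergence statistics

For binary units, divergence is the normalised Hamming distance over units
observed in both samples (missing states shrink the denominator). For
binned read counts, divergence is the mean absolute difference of
counts-per-million-normalised counts (bins are equal-width, so a per-million
scale is equivalent to per-kilobase scaling up to a constant); the rendered
form of the count statistic omits absolute-value bars, but the signed mean
of normalised differences is ≈0 by construction, so the L1 mean is the
meaningful reading. Peak presence/absence divergence applies the Hamming
form to a union-merged nonredundant peak set restricted to variable peaks.
Trend significance uses the least-squares slope of d on Δt with a
permutation of sample labels that moves rows and columns of the pair
structure together (respecting the correlation of pairs sharing a sample);
reversions in the interval-change analysis count in each interval where
they occur.

## The synthetic-data generator

The generator emulates the study's statistical structure, not its sequence
content. Defaults encode the study conditions: two pedigree designs
(bisulfite-style, 10 lines × transfers 5/20/40 with 3 ancestor replicates;
dense long-read-style, 6 lines × transfers 1/5/7/8/10/15), 25 mitoses per
transfer; heritable gain/loss rates confined to centromeric domains at the
published per-context single-site estimates (CG 1.62/8.55, CHG 1.54/8.19,
CHH 2.17/7.18, ×10⁻⁵ per site per mitosis) with an equilibrium ancestral
fraction; transient *observation-level* methylation flips (probability
0.005 per site per observation) outside centromeres, reproducing transient
DMRs without heritable divergence; negative-binomial depth (mean 20,
dispersion 5 — typical bisulfite coverage; the study does not publish a
depth model); conversion error 0.005 (unmethylated read as methylated) and
0.01 (methylated read as unmethylated), typical bisulfite
non-conversion/over-conversion magnitudes; genetic mutations as an
independent Poisson process at 0.033 per mitosis per line (≈33 per line
per 1000 mitoses). Latent evolution uses the exact closed-form
multi-mitosis transition per (domain, context) group; a brute-force mode
loops single mitoses and exists as an oracle. ChIP bin counts are Poisson
around per-bin enrichment means (stable across samples by default; a
drift mode adds a Gaussian random walk on log-means for power analysis),
on 5000-bp genome-wide and 500-bp centromeric bins.

What the generator does **not** emulate: sequence composition (no reads,
no AT-richness, no RIP-degraded repeats), mappability structure, spatial
autocorrelation of methylation beyond domain blocks, per-site rate
heterogeneity within a domain, or selection. Passing tests therefore show
that the estimators are correct under the stated stochastic model, not
that real-data artifacts (mapping bias, conversion drift between batches,
hemimethylation) are handled.

## Enrichment analyses

DMRs are assigned to the chromatin domain (and domain × annotation cell)
containing their midpoint. Expected counts are proportional to stratum
base-pair length; each stratum reports observed/expected rate ratio, a
Wald 95% interval on the log scale, an exact two-sided Poisson tail
p-value, and the Wald p from a Poisson regression of stratum-versus-rest
with a log-length offset (the model-based route; both are reported when
the GLM converges). Interaction in the domain × annotation table is
summarised as the cell ratio divided by the product of marginal ratios.
Annotation precedence when inputs overlap is gene > promoter > TE >
intergenic, with promoters defaulting to 1 kb upstream where not given;
p-values are reported raw (no multiplicity correction) by default. The
TE-proximity test compares the median edge-to-edge distance of query
intervals to TEs against medians of equally sized draws from a background
feature set (without replacement; add-one-smoothed p).

## Problem sizes and determinism

The in-package experiments run at desk scale chosen to keep Monte-Carlo
error well below the effects being measured: rate recovery uses the full
50,000-site, 31-sample bisulfite design (estimate standard errors ≪ the
published interval widths); null calibration uses 3,000 sites and the
dense design with 79 permutations and 100 replicates; the hotspot contrast
uses 8,000 sites per domain. Every stochastic entry point takes an integer
seed and is deterministic given it.

## Known limitations

- Gain/loss labels are unidentifiable from divergence alone (the swap
  symmetry above); anchor p₀ externally or accept the lower-α convention.
- The saturation regime carries little rate information; designs without
  early time points will pin at bounds (flagged, not silently returned).
- The analytic F-test is anti-conservative for correlated all-pairs sets
  and conservative at the boundary null; use the permutation variant or
  the cluster bootstrap for calibrated uncertainty.
- DMR bin states use a fixed majority threshold rather than a segmentation
  HMM over bins; region-mode clustering of bins into longer DMRs is out of
  scope.
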