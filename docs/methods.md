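# Methods

This note documents the statistical procedures implemented in `compartseq`,
the defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical details that matter for reproducing its
behaviour.

## Normalized expression and the housekeeping correction

NE(t, s) = count(t, s) / (length_kb(t) × depth_millions(s)) — an RPKM-style
quantity.  Two readings of "depth" are supported: each sample's own mapped
read total (`density="per_sample"`, the default) or the dataset mean applied
to all samples (`"pooled"`).  They differ only by per-sample scalars, so
profiles, correlations, and fold changes are unaffected; per-sample is the
default because it is the standard RPKM convention.

Gene NE is the **sum** of the gene's transcript NEs — the gene's total mRNA
output.  (An average would under-weight genes whose output is split across
isoforms; no aggregation rule is canonical, so the choice is stated here and
kept fixed.)  Compartment NE is the arithmetic mean of the two replicates;
replicate values are retained for QC.

The housekeeping correction addresses a compositional artifact: relative
units make every gene appear to fall when one transcript expands to a large
fraction of the pool.  With a panel of control genes g and a reference
compartment (EC):

    factor(c) = mean_g NE(g, c) / NE(g, EC)
    corrected NE(g, c) = NE(g, c) / factor(c)

Each control is first normalized to its own reference level so that wildly
different control magnitudes contribute equally; a corrected value of 1 is
then the average control-gene level in that compartment.  The correction is
one scalar per compartment, so it preserves all within-compartment ratios
exactly, and on noise-free data it restores every profile to a fixed
multiple of the true molar abundance.  Panel genes missing from the table
or with zero reference expression are dropped with a warning (a pseudocount
is available but off by default — a zero-reference control is better
excluded than imputed); an empty surviving panel is an error.  The default
panel is the 14 standard qRT-PCR/RNA-seq controls (GAPDH, ACTB, HMBS, H6PD,
RPL4, RPLP0, RPLP1, TFRC, ALB, B2M, SDHA, TBP, TUBB, YWHAZ).

## Exact differential count test

For a feature with counts x, y in libraries of sizes N1, N2, Poisson
sampling gives the classic conditional law (a negative binomial in y with
x+1 successes and success probability N1/(N1+N2)):

    p(y | x) = (N2/N1)^y (x+y)! / (x! y! (1 + N2/N1)^(x+y+1))

`conditional_count_pmf` evaluates it in log space (gammaln), and the test
suite verifies normalization to 1e-9 and point values.

The reported two-sided P conditions on the pair total t = x + y, under
which y ~ Binomial(t, N2/(N1+N2)); the P value is the total probability of
all splits no more likely than the observed one (minimum-likelihood rule,
ties included at relative tolerance 1e-7).  Conditioning on the total was
chosen over summing p(y'|x) directly because only the former is exactly
symmetric under (x, N1) <-> (y, N2) — the flat-prior conditional version
treats the two libraries asymmetrically (e.g. x=1, y=0 at equal depth gives
1.0 one way and 0.5 the other) — and because it is the standard exact
formulation for comparing two counting processes.  Both agree on which
outcomes are extreme and coincide asymptotically.  The implementation uses
the unimodality of the binomial pmf: the extreme set is [0, a] ∪ [b, t],
located by binary search and evaluated with regularized incomplete beta
tails, O(log t) per test, verified against brute-force enumeration for all
x, y ≤ 20 and against an independent exact-test implementation.

Pipeline conventions: replicates are summed per compartment before testing
(the count model describes unreplicated libraries; a conservative
per-replicate mode that keeps the larger P is available); transcript P
values aggregate to genes as the Šidák-corrected minimum
1 − (1 − p_min)^k; adjustment is Benjamini–Hochberg within each comparison
(Bonferroni by flag); log2 fold changes use compartment mean NE with a 0.5
pseudocount.  Genes significant in at least one of the three adjacent
comparisons (EC–EQ, EQ–FP, FP–FC) are partitioned into the 7 non-empty
Venn categories; the categories are disjoint and sum to the significant
total by construction (asserted).

Calibration: between Poisson replicates of equal expectation the fraction
of raw P < 0.05 is 0.05 within 3 binomial standard errors over 2000 genes.
The test assumes Poisson sampling; with biological overdispersion it is
anticonservative, which is why the paper-style design pools many lenses per
replicate.

## Profile correlation and grouping

Profiles are (corrected) compartment-mean NE over the four ordered
compartments.  Pairwise similarity is R² = r² of the Pearson correlation
over those 4 points.  Significance of R² at two-tailed α uses
t²/(t² + df), df = n − 2.  For n = 4, df = 2, the t CDF has the closed form
F(t) = 1/2 + t/(2√(2 + t²)), so the critical R² is exactly (1 − α)²:
**0.9025** at α = 0.05.  (Published renditions of this threshold sometimes
carry extra digits from iterative quantile routines; the implementation
returns the exact value, which agrees with a numerical-quadrature inversion
of the t density to 1e-9 in the tests.)  The df comes from the 4
compartment means; the 2 replicates enter only through the means.

Significance is **sign-aware**: coordinate expression requires r > 0 as
well as R² above the bound — a mirrored profile has R² = 1 but is not
co-regulation evidence.  Constant profiles get R² = 0 with a flag rather
than NaN.

Groups are maximal cliques (networkx) in the graph whose edges join pairs
with r > 0 and R² ≥ 0.93.  The 0.93 grouping floor is deliberately stricter
than the 0.9025 significance bound: the former defines membership, the
latter defines *separation* — with `require_separation` (default) a clique
is only reported if no positively correlated cross pair against an already
reported group reaches significance.  Cliques are reported largest first
(ties by lexicographic member order); a gene in several maximal cliques
stays with the first-reported one and the ambiguity is logged.  Unassigned
genes significantly correlated with every member of a group, but below the
grouping floor, are reported as "loose associates" of that group.
Maximal cliques were chosen over connected components because the construct
is "every within-group pair exceeds the bound", which components do not
guarantee.  All operations take n from the profile length, so nothing is
hard-wired to 4 compartments.

Replicate QC: PCA (scikit-learn) on log10(NE+1) of the samples; a
compartment is flagged when its replicates are farther apart in PC space
than the median distance between samples of different compartments.

## Promoter scanning and matrix set algebra

Promoters are strand-aware 1-kb windows upstream of the TSS, 0-based
half-open ([TSS−1000, TSS) on plus, reverse-complemented [TSS+1, TSS+1001)
on minus), truncated at contig edges with a warning.  The 1-kb window is a
deliberate, stated limitation: distal sites are invisible to this analysis.

Scanning scores log2 odds of the PWM against a 0-order background (by
default estimated from the scanned set, with a pseudocount floor) on both
strands; positions outside {A,C,G,T} contribute zero (background) score.  A
promoter "contains" a matrix when any window reaches the threshold.  The
default threshold is the score whose per-position false positive rate under
the background is 1e-4, computed by exact convolution of the discretized
score distribution (grid 1e-3, per-position scores rounded *up* so the
bound is guaranteed; the threshold is at most width × grid above the exact
one).  An "80% of maximum score" alternative rule is available.  The
threshold is a first-class parameter recorded in the scan metadata, because
presence/absence — and everything downstream — depends on it.  At 1e-4
over ~2,000 scanned strand-positions, chance presence per promoter-matrix
pair is roughly 1 − (1 − 1e-4)^2000 ≈ 0.18; consequences are quantified
below.

Set algebra over groups: common(g) = matrices present in **all** members of
g; a matrix is *unique* to g when it is common to g and common to no other
group (presence in some but not all promoters of another group does not
disqualify — this is the reading forced by the published accounting
51 = 20 + 2 + 17 + 12).  Each matrix in any common set is classified by the
exact set of groups whose common sets contain it, so the additive identity
|common(g)| = |all-groups| + Σ pairwise-shared-only + |unique(g)| holds
exactly and is asserted on every call.

## TF candidate ranking

For each group, candidates are the factors (many-to-many matrix↔factor
table) binding matrices common to all members.  Evidence is combined from:

* **enrichment** — one-sided hypergeometric P of at least the observed
  number of member promoters carrying the matrix, given its carrier count
  in a background universe (default: all scanned genes).  The source
  analysis never defines "the P value of the matrix"; over-representation
  against the scanned universe is the only probability constructible from
  presence data alone, and the choice is recorded in output metadata (the
  P is also a plug-in point: any per-matrix P can be substituted).
* **expression** — mean sign-aware R² of the factor's profile against each
  member (anticorrelated or constant pairings contribute 0); factors absent
  from the expression table are kept but flagged "not quantified".

Combined score = −log10(P) × mean R², strictly monotone in each channel,
zero when expression is uninformative; P = 0 is clamped to 1e-300 with a
warning.  Two views are emitted because they answer different questions and
genuinely reorder candidates: the *filter* view (P < 0.05 and mean
R² > 0.9, sorted by R²) and the *score* view (all quantified candidates by
combined score, ties by smaller P then factor id).  Factors binding a
matrix unique to the group are flagged as particularly strong candidates.

Note that enrichment evidence scales with group size: for a 2-member group
the best achievable hypergeometric P with ~20% background carriers is only
~0.04–0.07, so small groups can fail the P < 0.05 cut even for a genuinely
planted regulator — an honest property of the statistic, visible in the
tests.

## The synthetic generator

`SyntheticConfig` defaults define the emulated study: 120 genes; three
planted groups of sizes (4, 5, 2) with shapes (0.3, 5, 5, 4.5) — rise into
the equatorial epithelium then level, (0.2, 0.6, 6, 10) — dramatic fiber
up-regulation, and (0.3, 4, 1.2, 0.4) — a transient equatorial peak; shapes
are validated pairwise separable (positive-correlation R² below the 0.9025
significance bound).  One dominant transcript is planted so its expected
share of the *read* pool is (2.5%, 5%, 12%, 16%) across EC→FC — the
endpoints follow the measured dominant-crystallin skew, the interior points
are interpolated defaults.  14 housekeeping genes have constant true
abundance; 2 × 4 libraries of 10⁶ reads (a desk-scale stand-in for the
8–13 M of a real run — every statistic here is composition- or rate-based,
so depth only sets the Poisson floor); one planted regulator per group
shares the group's shape at a quarter of the group expression scale.
Counts are independent negative-binomial draws per replicate with
var = μ + φμ² and φ = 0.01 (≈10% extra-Poisson CV — the real design pooled
100 lenses per replicate, leaving no published replicate-variance estimate,
so φ is a single modeling knob, flagged here); φ = 0 gives Poisson, and a
multinomial mode gives exact library sizes for compositional tests.  An
optional constant 4:1 abundance pair supports ratio-invariance tests.

Promoters are i.i.d. background sequence (GC 0.42) of 1 kb; every group
member carries one planted instance of its group's motif (the consensus by
default, hence at maximal score) at a random offset and strand, recorded in
a 0-based half-open BED; background promoters carry each planted motif
independently with probability 0.02.  Three decoy PWMs and decoy co-binding
factors (background genes) populate the matrix↔factor table so ranking has
non-trivial competition.

What the generator does **not** emulate: isoform complexity beyond an even
split (multi-transcript genes share abundance equally), correlated noise
between replicates, GC or length bias in counting, promoter sequence
structure (CpG islands, repeats), motif clustering or cooperative sites,
and any epigenetic layer.  Passing recovery tests therefore demonstrate
correctness of the *statistics*, not robustness to those real-data
artifacts.

Determinism: all draws derive from `numpy.random.default_rng` seeded by the
config (promoters use a child stream of the same seed), so equal configs
give bit-identical datasets.

## Numerical choices and degenerate inputs

* Probability ties in minimum-likelihood tests: relative tolerance 1e-7.
* Gene-level Šidák aggregation via expm1/log1p to keep tiny P values exact.
* Constant profiles: R² = 0 + flag, never NaN; all-constant matrices give a
  degenerate QC report rather than an exception.
* Score-threshold convolution grid: 1e-3 log2-odds units, rounded upward
  (conservative).
* Recovery problem sizes (120 genes, 20 seeds, 1 M-read libraries) keep the
  full test battery under ~10 s while leaving all planted effects many
  standard errors from their detection thresholds.

## Known limitations

* The exact count test models technical (Poisson) sampling only; it is
  anticonservative under biological overdispersion.
* 4-point correlations are blunt: R² significance at df = 2 has little
  resolution, which is why the grouping floor (0.93) and the significance
  bound (0.9025) are kept distinct.
* Motif presence is single-matrix; family-level aggregation of similar
  matrices is a documented extension point, not implemented.
* The hypergeometric enrichment treats promoters as exchangeable bags; GC
  or length covariates of the universe are not modelled.
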