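# Methods

## Discretization

Each gene is z-scored against its own mean across samples,
z = (x − μ_g)/s_g, and coded +1 / −1 / 0 by a cutoff Z applied with strict
inequality (|z| must exceed Z; ties at the boundary are measure-zero on
real-valued data and a deterministic rule is preferable to a random one).
The standard deviation uses ddof = 1 by default; a `ddof=0` switch is
provided since either convention is defensible and the choice only moves
codes at the boundary. Genes with zero variance code to all zeros rather
than raising — background genes must pass through harmlessly. Constant
rows are detected exactly (max = min) because floating-point rounding of
the mean can otherwise manufacture a tiny nonzero standard deviation and
turn a flat gene into spurious ±1 codes.

Z defaults to 0.4: the operational floor at which changes in expression
are still observable rather than numerical noise. Raising Z strictly
shrinks the set of nonzero codes, and network size is non-increasing in Z
(verified over Z ∈ {0.4, 0.8, 1.2, 1.6}).

## Co-occurrence and the null

With indicator matrices P (codes = +1) and M (codes = −1), the inner
products P·P', M·M', P·M' count supporting samples per pair; pp/mm are
symmetric (read upper-triangular, zero diagonal), pm is square and
asymmetric with a structurally zero diagonal. The counting is verified
against brute-force per-sample accumulation.

The null for a pair conditions on the two genes' sign-specific densities
d1, d2 (number of +1s for a P-side gene, −1s for an M-side gene): permuting
two fixed-density binary vectors of length n makes their overlap
hypergeometric(n, d1, d2). Thresholds therefore depend only on
(d1, d2, n) and are cached per triple rather than re-simulated per pair —
mathematically identical and orders of magnitude faster; a literal
shuffle-and-count reference implementation is kept and tested against the
shortcut. Two modes:

- `monte_carlo` (the reference procedure): 1000 draws, linear-interpolation
  quantile at 0.995; an observed count is accepted when it strictly
  exceeds that quantile (for integer counts, strictly exceeds its floor).
- `exact_hypergeometric`: the discrete quantile — smallest k with
  CDF(k) ≥ 0.995 — with the same strict-exceedance rule. This is the
  limiting value of the Monte-Carlo threshold and serves as its oracle;
  the two agree within ±1 across the full density grid at n = 20 and are
  equal for ~95% of density pairs.

Because the null is integer-valued, the realised per-pair acceptance
probability is below the nominal 1 − 0.995 = 0.5% (measured ≈ 0.3% on
independent 100 × 100 data); the quantile rule is conservative, never
anti-conservative. pm thresholds use gene1's +1 density and gene2's −1
density — the permutation null must condition on the actual sign-specific
densities.

## Correlation cross-check

Significance of a Pearson r uses t = r·√(N−2)/√(1−r²) with N−2 degrees of
freedom, two-tailed (this convention reproduces the reference operating
points p(0.1, 100) ≈ 0.32 and p(0.3, 100) ≈ 0.0024). The inverse `p_to_r`
is closed-form: r = t*/√(N−2+t*²) with t* the t quantile, exact to the
round-trip tolerance of 1e−9. Only Pearson correlation is implemented;
constant genes are skipped (undefined r), not errors. Filtering requires
positive correlation for pp/mm edges and negative for pm, and only ever
removes edges.

## Predictions from a signed regulatory network

The truth network's adjacency sets ac = +1, re = −1 and du = 0 (du is
deliberately ignored: its action is sign-ambiguous). Instead of reading
the sign of A^k — where positive and negative walk counts can cancel
silently — A is split into A⁺ and A⁻ and walk counts with even and odd
numbers of repressive steps are propagated separately. Two views are
exposed: effector→target pairs per exact path length (the matrix-power
view), and shared-effector target pairs per depth k (paths of length ≤ k;
the view that actually predicts co-expressing pairs). A pair with both
positive and negative evidence at a depth is reported as *ambiguous*,
never silently signed. Depth sets are cumulative, so predictions are
monotone in k except where new depth reveals a conflict.

Scoring partitions every network edge into exactly one of
{direct definition, transitive prediction, unexplained} (precedence in
that order, matching on unordered pairs), with background-gene pairs
tallied separately; du definitions found in a network are counted as their
own matched category and never as expected-positive or expected-negative.

Low-variance gene selection estimates the modal variance as the peak of
the log-variance histogram (numpy `auto` binning; log scale stabilises the
mode, zero-variance genes are always selected and excluded from the
estimate) and returns genes below a fraction (default 0.5) of the mode.
At least 10 genes are required — the mode of a smaller histogram is
meaningless.

## Randomization significance and spectral reordering

Network-size significance shuffles each row of the ternary matrix
independently (preserving every row's code histogram, hence every density
— one threshold table serves all randomizations), rebuilds the network
n_rand times (default 100), and reports a one-sample t statistic oriented
null-minus-observed (a real network far exceeding chance gives a large
negative t) with a one-sided p from Student t with n_rand − 1 df. If the
null sizes are all identical the t is undefined and an exact count
comparison is reported instead, flagged degenerate.

Spectral reordering sorts genes by their component in the leading
eigenvector of the binary symmetric adjacency (support-weighted optional;
pm input is symmetrized with a warning). The sign ambiguity ±v is fixed by
making the largest-magnitude component positive, and ties break by gene
name, so orderings are reproducible and permutation-invariant.

## Synthetic data generator

The generator emulates simulator-built "microarray" data driven by a known
transcriptional network. Defined genes form a random DAG: ~15% roots, every
other gene takes 1–2 parents among earlier genes chosen with probability
proportional to out-degree + 1 (preferential attachment), so hub effectors
and shared-regulator motifs — the source of transitive predictions — are
plentiful. Edge types are drawn independently: re with probability 0.275
and du with 0.075 (the ac:du:re ≈ 97:11:41 mix of an E. coli-style
transcriptional definition set), ac otherwise.

Expression propagates linearly: roots draw standard-normal values per
sample; each regulated gene sums its parents' standardised values with the
edge sign (du contributes a fresh random sign per sample) scaled by
`effect_size`, then is standardised. Observed values mix signal and noise
as (1 − b)·signal + b·ε with b = `bio_noise` and ε ~ N(0, 1); b is thus a
noise-to-signal mixing weight on unit-variance components (b = 0
noiseless, b = 1 pure noise), spanning "low noise" ≈ 0.1 to "high noise"
≈ 0.5. Background genes (`bgr_` prefix) are pure ε and take part in no
interaction. All randomness flows from one run seed through separate
streams for topology, signal, du signs and noise; the same seed at
different b reuses identical signal and noise draws (common random
numbers), so noise sweeps degrade monotonically rather than confounding
the noise effect with resampling. Background noise is freshly drawn every
run — two runs share no spurious background structure, a property the
tests check via the between-run correlation of background pair
correlations.

`planted_module_study` builds the complementary clean configuration: one
driver activates every gene of module M1 and represses every gene of M2,
with no du edges and no sign-cancelling paths. Within-module pairs are
expected in pp *and* mm (Gaussian signals make up- and down-excursions
symmetric) and M1–M2 pairs in pm only, so this is the configuration for
probing relation exclusivity and reciprocity.

What the linear-Gaussian generator does *not* emulate: saturating
(Michaelis–Menten-style) transfer functions, platform artefacts (probe
effects, dye bias), heavy-tailed or heteroscedastic noise, and condition-
dependent (rather than per-sample random) dual action. Passing tests show
the network machinery recovers monotone signed co-variation against a
calibrated null; they do not certify behaviour under saturation or
structured technical noise.

Under the *general* DAG generator, relation exclusivity between pm and
pp/mm is bounded away from zero by design: du edges and mixed-sign paths
genuinely place some pairs in both senses (those same pairs are the ones
the prediction machinery flags ambiguous), which is why the exclusivity
analysis uses the planted-module configuration.

## Problem sizes and test design

The test suite runs the full pipeline at the study's reference scale —
100 defined + 100 background genes × 200 samples, noise sweep over
b ∈ {0.1, 0.3, 0.5} — which completes in seconds because counting is two
matrix products and thresholds are cached per density pair. Calibration
uses a single 100 × 100 independent Gaussian matrix in Monte-Carlo mode;
null-size significance uses 100 randomizations; the counting oracle is
checked on 200 random 50 × 20 ternary matrices. Property-based tests
(hypothesis) run derandomised with 50 examples each. All randomness in
tests is seeded; pipeline results are deterministic given (data, seed,
mode).
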