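# Methods

This note records the statistical models, numerical conventions and
design choices behind `dnadistort`, and what the synthetic-data
generators do and do not emulate.

## Hotspot statistics

Under the null that each of the M recorded G:C>T:A substitutions lands
on any of the S candidate guanines with equal probability, the count at
one site is Binomial(M, 1/S) (the marginal of the uniform multinomial).
For the curated *TP53* panel, M = 421 and S = 353, so the per-site null
probability is 1/353 and the expected count ≈ 1.19.

Two p-value modes are exposed:

- `point` (default): Pr[X = N]. This is the quantity that reproduces
  the published non-hotspot values at M = 421, S = 353
  (Pr[X=0] = 0.303, Pr[X=1] = 0.362, Pr[X=2] = 0.216); the
  corresponding upper tails would be 1.0, 0.697 and 0.333.
- `tail`: Pr[X ≥ N], the conventional one-sided exact binomial test.
  For hotspot-scale counts (N ≥ 9) the two modes agree to one
  significant figure, so either reproduces the hotspot calls; for small
  N they differ, which is why `point` is the default. Both are kept
  because the field's terminology ("exact binomial test") does not pin
  down the choice.

All probabilities are computed in log space via `gammaln` (tail sums via
`logsumexp`), which keeps 10⁻⁴⁰-scale magnitudes exact to ≥12
significant digits; calls carry `log10_p` alongside `p_value`. The
family-wise correction is Bonferroni with divisor S (the number of
candidate sites), threshold α/S with α = 0.05 by default.

Power note: with Bonferroni at 0.05/350 and M = 400 draws over S = 350
sites, the point-mass criterion flags a site only at N ≥ 8. A site
enriched 10-fold (expected count ≈ 10.6) is detected in ~84% of
realizations, so jointly recovering three such sites succeeds only
~60% of the time; at 20-fold enrichment — the scale actually seen at
the strong *TP53* hotspots, e.g. 27 observed vs 1.19 expected at codon
157 — joint exact-set recovery exceeds 98%. The planted-recovery test
therefore uses 20-fold enrichment.

## Mutation signatures

Substitutions are referred to the pyrimidine of the mutated
Watson–Crick pair: purine-reference records are reverse-complemented
before channel lookup, making the signature independent of the strand
on which a record is written. Channels are ordered substitution-class
major (C>A, C>G, C>T, T>A, T>C, T>G), flanks in A/C/G/T order.
Probabilities are percentages of all 96 channels (sum 100); a
per-class renormalization (`Signature96.class_probabilities`) is
available for plots normalized within one substitution class, since
published bar charts do not always state their normalization.

The probability-vs-difference correlation takes the 16 contexts of one
substitution class (C>A, i.e. G:C>T:A, by default) as paired
observations: Pearson r between the smoker probabilities and the
smoker-minus-nonsmoker differences, with a two-sided p-value from
t = r·√((n−2)/(1−r²)) on n − 2 df. With n = 16, r = 0.580 gives
p ≈ 0.0185, consistent with reported values for this analysis.
Smokers and ex-smokers are conventionally pooled into the smoker
stratum upstream of this module; the TSV reader maps any stratum other
than `smoker`/`nonsmoker` to `unknown` so the pooling choice stays
explicit in the data-preparation step.

## Hydrogen-bond quality index

I_H = Σᵢ₌₁³ (dᵢ − d⁰ᵢ)² + (1 + cos γᵢ)², with ideal G:C donor–acceptor
distances d⁰ = (2.91, 2.95, 2.86) Å for O6–N4, N1–N3 and N2–O2, and
ideal D–H…A angle 180°. The index mixes Å² and dimensionless terms
without reweighting, as published; it is ≥ 0, zero exactly at ideal
geometry, and strictly increasing in each deviation. Angles are degrees
at every interface and converted to radians only inside the cosine.
Per-frame values are summarized by median and 25th–75th percentile
range; adducted-vs-control comparisons report the signed and absolute
median difference with a two-sided Mann–Whitney p-value. Published
absolute I_H levels for near-Watson–Crick DNA (≈4.5) reflect the
original trajectories' systematic geometry offsets and are not
reproducible without them; the tests therefore validate the analytic
cases and planted-shift recovery instead.

## Trajectory summaries

- Equilibration discard keeps frames with t ≥ t_start (inclusive);
  with 2-ps sampling over 0–10 ns and t_start = 300 ps this retains
  4851 of 5001 frames, which fixes the boundary convention.
- Terminal-level trimming drops the first and last k level columns
  (default k = 1, end-of-duplex fraying); original level indices are
  preserved in metadata, and the pipeline records actual post-trim
  widths per parameter in its output manifest rather than assuming
  them.
- Quartiles use linear interpolation between order statistics (type-7,
  numpy's default). This is stated explicitly because IQR error bars
  depend on it.
- Mann–Whitney U: midranks for ties; exact enumeration of all
  C(n+m, n) rank splits when both samples have ≤ 8 observations
  (two-sided p = share of splits at least as extreme in |U − nm/2|),
  otherwise the normal approximation with tie-corrected variance and a
  0.5 continuity correction. If all pooled values coincide the result
  is flagged degenerate with p = 1.
- Anderson–Darling: composite normality with estimated mean and
  sd (ddof = 1), adjusted statistic A²(1 + 0.75/n + 2.25/n²) against
  the 5% critical value 0.752. MD parameter distributions are almost
  never normal; the test is advisory and the pipeline reports the rank
  test regardless.
- RMSD uses the Kabsch algorithm (SVD of the covariance, proper
  rotations only — the smallest singular direction is flipped when the
  determinant is negative). Frames must share a unit tag; collinear
  point sets are rejected as degenerate.

## Multiple factor analysis

Step 1 standardizes each parameter's table (center, unit variance with
ddof = 1; scaling is a flag since conventions differ) and divides it by
√λ₁ of its own PCA, so every block's first singular value becomes 1 and
no parameter can dominate. Step 2 is a global PCA (SVD) of the
concatenated weighted blocks. Conventions:

- eigenvalue divisor n − 1 throughout; any consistent divisor rescales
  all groups identically, so the solution is invariant to the choice
  (tested);
- component signs are fixed so each component's largest-magnitude
  loading is positive, making score plots reproducible;
- zero-variance columns are dropped with a warning when scaling (they
  cannot be standardized); a group whose first eigenvalue is 0 is an
  error;
- variable–component correlations are computed against the
  standardized pre-weighting columns, so group weights do not distort
  them; group contributions are sums of squared loadings per block
  (unit sum per component).

Observation features are the per-level medians (the summary the rest of
the pipeline produces); the same long-format input accepts
frame-stacked values if a caller prefers time-resolved observations.

## Synthetic data: what it emulates, and what it does not

The generators stand in for upstream tool outputs with planted,
recoverable structure; all are pure functions of config + seed.

- Mutation tables: multinomial allocation of M substitutions over S
  sites (defaults 421/353, the curated panel scale); enriched sites get
  a configurable weight factor and take their trinucleotide context
  from the shipped duplex panel. Strata are smoker/nonsmoker with
  smoker fraction 0.75 overall (lung-cancer mutation records are
  smoker-dominated) and 0.95 at enriched sites (hotspot counts are
  almost entirely from smokers, e.g. 26/27 at codon 157).
- Helical trajectories: per level, a stationary AR(1) series (default
  coefficient 0.8) around a target median, innovation variance chosen
  so the *stationary* IQR matches the target via IQR = 1.349σ.
  Baselines are near-canonical B-DNA values (twist 34.3°, rise 3.32 Å,
  propeller −11°, …) with rotation IQR 8° and translation IQR 0.6 Å,
  plausible MD fluctuation scales. The adduct effect shifts the median
  at the CpG levels 5/6 (+15° rotations, +0.8 Å translations) and
  flips the sign of buckle/opening at the methylated cytosine
  (level 5) — the codon-157-like pattern in which those rotations run
  opposite to all control sequences. AR(1) correlation is deliberate:
  it exercises the effective-sample-size caveats of MD summaries that
  i.i.d. noise would hide.
- Bond geometry: Gaussian around ideal + shift, angles clipped to
  [0, 180]°.
- RMSD: piecewise-stationary Gaussian plateaus (windows must tile the
  time span), emulating a low equilibration plateau followed by a
  higher production plateau.
- MFA panel: `gen_mfa_panel` generates the summary-level tables
  directly (22 observations × trimmed level columns, adduct offset of
  1.5σ on levels 4–6), which is what MFA consumes and keeps
  100-replicate studies to sub-second cost; the frame-level generator
  is exercised separately.

None of this is physically realistic dynamics: there is no
sequence-dependent mechanics, no coupling between parameters, no
non-Gaussian tails, and the adduct effect is a clean localized shift.
Passing tests therefore demonstrate that the *analysis* recovers planted
structure of realistic magnitude under realistic noise and correlation —
not that any particular MD result is correct. Quantities that depend on
the original trajectories (global MFA variance shares such as ~41%/21%
on the first two components, absolute I_H levels, specific buckle/
opening medians, RMSD plateau values) are covered by oracle-equivalence
and planted-recovery properties rather than by value reproduction.

## Problem sizes used in the test suite

Chosen to keep the default suite fast while leaving the statistical
properties well-powered: planted-median recovery uses 1001-frame
trajectories (2-ps sampling over 2 ns) across 50 seeds, with the full
5001-frame accounting checked exactly where frame counts matter;
replicate studies (MFA separation, hotspot recovery, uniformity
calibration) use 100 seeds on panel-scale problems; the I_H reference
median comes from a single 200 000-frame draw.

## Known limitations

- The hotspot model treats all guanines as equally mutable a priori;
  it ranks sites against a uniform null, not a context-adjusted one.
- Signature probabilities are percent-of-96; if a published figure is
  normalized within a substitution class, use the per-class
  normalization explicitly.
- The exact Mann–Whitney branch enumerates rank splits and is limited
  to ≤ 8 observations per sample by design; larger samples use the
  tie-corrected approximation (agreement within 0.01 at n = 9 per arm).
- MFA assumes complete observation × level tables; missing cells are an
  error rather than being imputed.
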