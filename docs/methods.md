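# Methods

## The achiasmate F2 design

In a female-achiasmate species, the F1 female transmits one of her two
parental chromosomes *intact* (probability 1/2 per chromosome), while the
F1 male produces ordinary recombinant gametes.  Writing `r1` for the
recombination fraction between the left flanking marker and a putative
QTL, `r2` for QTL-to-right-marker, `r` for the whole interval and
`s* = 1 - r*`, the conditional law of the QTL genotype given the
flanking-marker class follows from enumerating the two maternal
haplotypes against the eight paternal three-locus gametes.  Two marker
classes — opposite homozygotes at the two flanks — are impossible in this
design (requesting them raises a dedicated error rather than returning
zeros, to surface data/design mismatches); the remaining seven classes
give first-order expressions in `r1, r2` such as

```
P(QQ | MM, MM) = s1 s2 / s      P(Qq | MM, MM) = r1 r2 / s
```

whereas the chiasmate law gives second-order expressions
(`s1^2 s2^2 / s^2`, ...).  Expected effect coefficients use the standard
F2 coding: `x_A = P(QQ) - P(qq)` (additive, +1/0/−1) and
`x_D = P(Qq)/2 - (P(QQ)+P(qq))/2` (dominance, +0.5 heterozygote, −0.5
homozygotes); epistatic coefficients are products of the per-locus
`x_A, x_D`.  All closed forms are verified in the test suite against an
independent gamete-enumeration oracle at 1e−10.

The recombination map is Haldane (no interference): 10 cM ↔ r = 0.0906,
20 cM ↔ r = 0.1648; sub-interval fractions compose exactly as
`r = r1(1−r2) + r2(1−r1)`, and `r2` is always derived from that
constraint (under Haldane this equals converting the remaining map
distance).  Crossover-interference models and sex-chromosome transmission
are out of scope.

## Missing markers

Missing genotypes receive multipoint expectations.  For the achiasmate
design the latent structure is a chromosome-wide indicator of which
maternal haplotype was transmitted combined with a first-order Markov
chain for the paternal allele; for the chiasmate design it is a joint
four-state chain over both gametes.  Forward–backward over these chains
conditions each missing locus on *all* observed markers of the
chromosome; with only the two adjacent markers observed this reduces
exactly to the flanking conditional law (a property the tests assert), so
a separate flanking-only fast path would be redundant and is not
implemented.  A fully missing chromosome falls back to the marginal 1:2:1
expectation with a warning.

## Coefficient-difference analysis

For a fixed interval fraction `r`, the QTL position sweeps `r1` over a
fine interior grid (default 1000–2000 points) in `(0, r)`; at each point
both laws' `x_A, x_D` are evaluated for the seven feasible classes and
the absolute (`D_i = |x_a − x_c|`) and relative (`R_i = D_i / |x_a|`,
skipped where `x_a = 0`, e.g. the additive coefficient of the double
heterozygote class) differences recorded.  The reference interval widths
are `r = 0.09` (10 cM) and `r = 0.16` (20 cM).  The absolute envelopes peak at the
symmetric point `r1 = r2`; the relative envelopes are largest near the
interval ends, where the reported supremum depends mildly on the grid's
first point.  At `r = 0.09` the maxima are 0.0025 (absolute additive),
0.0072 (absolute dominance, attained by the double-heterozygote class,
consistent with the relative dominance maximum 0.0145 = 0.0072/0.4975),
0.0098 (relative additive); at `r = 0.16`: 0.0092, 0.0259, 0.0363, 0.0527.

## The population simulator

Chromosomes are walked locus by locus with QTLs inserted as pseudo-loci,
so marker and QTL genotypes are jointly consistent.  The female gamete is
an intact haplotype (or a second recombinant walk in the chiasmate
contrast mode); the male gamete flips between parental haplotypes with
the per-interval Haldane fraction, independently across intervals (no
interference).  Phenotypes add, to a mean of 10: the fixed QTL and
epistatic contributions (true-genotype coding), a random sex effect, the
QTL-by-sex and epistasis-by-sex deviations, and Gaussian residual noise.
Sex-interaction deviations are either supplied as fixed realized values
or drawn per sex with a two-level sum-to-zero constraint (each level
marginally `N(0, σ²)` with the second level the negative of the first).

The built-in silkworm scenario has 5 chromosomes × 11 markers at 10 cM,
7 QTLs (nonzero main effects on Q1–Q5 ranging |a| 1.9–3.88, |d| 0–2.3;
Q6, Q7 purely epistatic), three cross-chromosome epistatic pairs, fixed
realized sex-interaction values for Q2–Q4 and the pairs, n = 300 with
equal sexes.  The residual SD 5.34 was calibrated once by a large-n
variance audit so the fixed-genetic fraction of phenotypic variance is
≈ 50.5% (the audit utility is part of the public API); with the fixed
realized sex-interaction values the G×sex fraction is then ≈ 8% and the
narrow heritability ≈ 31%.  These three quantities cannot be chosen
independently once the realized interaction values are fixed; we
prioritize the genetic fraction.  The per-component interaction variances
in the scenario's `VarianceComponents` (5.0 each) only matter when the
realized values are re-drawn.

What the simulator does *not* emulate: genotyping error, segregation
distortion, selection, missing-data patterns of real genotyping
platforms, more than two environments, or sex chromosomes.  Passing tests
therefore demonstrate correctness of the method under its own model
assumptions, not robustness to real-data artifacts.

## Scanning procedure

1. **Background screening.**  Every adjacent marker pair is tested (8
   per-sex additive/dominance columns) against sex means by the partial-F
   statistic.  The screening threshold is *comparison-wise* — the pooled
   95th percentile of the candidates' within-sex-permutation F values —
   because genome-wide control belongs to the declaration stages;
   marginally significant intervals then pass through forward selection
   on conditional F (capped at 12) and backward elimination.  Joint
   selection is essential here: under achiasmata, marker coefficients on
   one chromosome are correlated at ≥ ~0.5 at *any* distance (the intact
   maternal gamete), so marginal selection would retain blankets of
   redundant cofactors.
2. **1D scan.**  A genome-wide walk (default 1 cM) tests the per-sex
   QTL additive/dominance terms at each position, conditioning on the
   selected background pairs *except those on the tested chromosome*.
   The chromosome-wide exclusion is deliberate and differs from the usual
   chiasmate-CIM window: conditioning on an intermediate marker blocks
   linked-QTL dependence only if recombination can separate loci, which
   the maternal gamete never does, so any same-chromosome cofactor
   absorbs roughly half of a tested QTL's signal at any distance (a
   finite window is available as an option).  The genome-wide threshold
   is the 95th percentile of per-permutation maximum F over the whole
   grid; peaks are strict local maxima above it, separated by at least
   one marker interval, then jointly pruned by backward elimination.
3. **Pair screening and 2D scan.**  All interval pairs are screened (16
   per-sex epistatic product columns, comparison-wise threshold, forward
   selection capped at 12); each selected pair is then scanned on a 2D
   grid widened by one interval per axis — pair screening often lands on
   a neighboring interval, and the widening lets the 2D walk reach the
   true peak — testing the four per-sex epistatic terms of the putative
   QTL pair, conditioning on the other pairs' marker-epistasis blocks
   (outside the scanned region) and the main effects of the 1D QTLs, with
   its own genome-wide max-F permutation threshold.
4. **Full model.**  Detected positions define the mixed model: fixed
   mean, per-QTL `a, d`, per-pair `aa, ad, da, dd`; random sex and the
   six interaction terms, each with one variance component and
   2-per-unit levels.

Permutations shuffle phenotypes *within sex* so the null preserves the
sex structure.  Thresholds are recomputed per stage; every stage logs its
seed and threshold.  The three strategies share this procedure exactly
and differ only in the conditional-probability backend (Model I/III:
achiasmate; Model II: chiasmate) and in whether the epistasis stages run
(Model III: no) — a contract the tests enforce by injecting the
achiasmate backend into Model II and requiring bitwise-identical output.

## Mixed-model estimation

Variance components are estimated by REML, maximizing the restricted
likelihood with a Woodbury-factored covariance (the random design has at
most a few dozen columns), bounded at zero; non-convergence is flagged,
not raised.  Fixed effects are GLS at the REML components; random effects
are BLUP rescaled per term so the empirical second moment of the
predicted levels equals the estimated component ("adjusted unbiased"
scaling — the citation chain for AUP specifies no algebra, so this is our
concrete choice).  These serve as initial values for a Gibbs sampler with
normal conditionals for effects and scaled-inverse-chi-square conditionals
for variances; the prior is weakly informative (1 pseudo-observation at
the REML estimate, floored at 1e−3 of the phenotypic variance), divergent
variance draws are capped at 1e4 × the phenotypic variance and counted.
Default chain: 11,000 iterations, 1,000 burn-in, no thinning.  Effects
are reported as posterior means with SDs and tested by
`t = mean/SD` against Student-t with `n − rank(X)` degrees of freedom.

Numerical conventions: ranks via pivoted QR with relative tolerance
1e−10 (this fixes the partial-F degrees of freedom, so it is frozen);
the partial-F denominator pairs the full-model SSE with the
reduced-model df, matching the statistic's definition above — under a
Gaussian null it is therefore a scaled central F, which the permutation
thresholds absorb automatically; near-perfect fits guard the denominator
with a relative epsilon; a singular GLS covariance falls back to the
pseudo-inverse with a warning.

## The simulation study

`run_simulation_study` simulates replicates, analyzes each with the
requested strategies (same replicate data and stage seeds across
strategies, so contrasts are paired), and scores: a detection matches the
nearest unmatched true QTL on the same chromosome within 10 cM (one
marker interval; greedy in descending F); power is the matched fraction
of replicates; FDR pools unmatched detections over replicates.
Detections matching the purely epistatic QTLs are excluded from both
power and FDR numerators.  Effect estimates come from the full-model
posterior means of detecting replicates, so they carry winner's-curse
bias at low power.  Power and FDR are reported with binomial Monte-Carlo
standard errors.

Problem sizes: the default scaled-down study runs 50 replicates with 200
permutations and 2,000 Gibbs iterations (the acceptance-test study uses
a 2 cM walk step); the full design — 300 replicates, 1,000 permutations,
11,000 iterations, 1 cM step — is available by passing those values.

## Known limitations

- With complete marker data, Models I and II differ *only* through
  conditional-probability tables whose entries differ by < 0.03 at 10–20
  cM marker spacing; their genome scans therefore almost always coincide
  replicate by replicate.  Strict Model-I-vs-II power orderings at
  moderate replicate counts are at the mercy of a handful of
  threshold-marginal cases.
- Within-chromosome localization is intrinsically weak for small-effect
  QTLs in this design: the maternal half of a QTL's variance carries no
  positional information inside a chromosome, so scan peaks can drift
  far along the chromosome at low signal (the chromosome-5 QTL of the
  built-in scenario is the worst case).
- Epistasis between QTLs on the *same* chromosome is not fully
  identifiable in an achiasmate F2 (only seven two-locus genotype
  classes segregate); the built-in scenario's pairs are all
  cross-chromosome, and no reduced-model workaround is provided.
- The stepwise searches are greedy; no multi-QTL simultaneous position
  refit is attempted.
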