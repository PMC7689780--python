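# Methods

## The quantity being modelled

A pairwise plant–soil feedback experiment grows two plant species, A and B,
in soil cultivated by each of them, yielding four biomass means
(A_a, A_b, B_a, B_b) with standard errors. The dissimilarity response

    r = ln(A_a / B_a) − ln(A_b / B_b)

is zero when the two species respond proportionally identically to the two
soil communities, and grows in magnitude as their responses diverge. With
the conspecific-soil biomass in the numerator of the left-hand ratio,
positive r means the pair performs better overall in conspecific soil (net
positive feedback). r is invariant to rescaling either species' biomasses
and to swapping the species labels, which is what makes responses comparable
across studies with different species, soils and growth conditions.

Its sampling variance uses the first-order delta method on the log scale:
var(r) = Σ (SE/mean)² over the four means, the standard variance of a log
response ratio. The delta method is first-order, so it degrades when SE/mean
is large; tests validate it against Monte-Carlo resampling in the
SE/mean ≤ 0.1 regime (agreement within 5%). Zero or missing standard errors
are treated as zero variance with a logged warning — the observation is then
taken at face value, which understates uncertainty.

## Measurement hierarchy and the seven models

Observed responses are modelled as noisy readings of latent truth at two
levels: r_ij ~ Normal(r*_ij, σ²_rij) with σ²_rij known from the delta
method, and r*_ij ~ Normal(r*_j, σ²_w), where σ²_w absorbs variation among
replicate feedbacks of the same species pair (replicates are
pseudoreplicates — often the same pair under different treatments — not
independent pairs). The pair-level mean r*_j then follows one of seven
models in the phylogenetic distance t_j (modelled in units of 100 Myr):

| id | pair-level law | signal |
|----|----------------|--------|
| 1 | Normal(0, σ²) | none |
| 2 | Normal(βt, σ²) | directional trend |
| 3 | Normal(0, σ² + kt) | gradual (Brownian) divergence |
| 4 | Normal(βt, σ² + kt) | trend + gradual divergence |
| 5 | t(0, s², υ + kt) | heavy-tailed divergence |
| 6 | t(βt, s², υ + kt) | trend + heavy tails |
| 7 | t(βt + α_f, s², υ + kt), α_f ~ t(0, s²_α, ν_α) | family-pair shifts |

Model 3 is the distance-based expression of Brownian trait evolution:
variance linear in divergence time, normal responses. The Student-t models
capture occasional large co-evolutionary shifts: smaller degrees of freedom
mean heavier tails and (for df > 2) larger variance, so a negative k is a
divergent signal of growing kurtosis. Model 7 asks whether family-pair mean
shifts α_f absorb that excess: if they do, k collapses toward zero. The
Student-t is parameterized as location m, scale s (not variance), df ν.

Pairs are treated as exchangeable given t_j; shared species across pairs and
study-level effects are deliberately not modelled.

## Likelihood computation

Both latent levels are integrated out of the likelihood before sampling.
The replicate level collapses analytically: r_ij | r*_j ~ Normal(r*_j,
σ²_w + σ²_rij). For normal pair-level laws the remaining integral is a
rank-one multivariate normal, evaluated with the Sherman–Morrison identity
in O(n_j) per pair. For Student-t laws, the product of replicate normals is
collapsed to a single normal in r*_j and the one-dimensional integral of the
t density against it is computed by 64-node Gauss–Hermite quadrature. The
collapsed normal's width (√v_j, from the known measurement variances) is
small relative to the t scale in all realistic settings, where this rule is
essentially exact; tests pin the error below 10⁻⁴ in log-likelihood against
brute-force nested quadrature, and below 10⁻³ against the analytic normal
model at df = 10⁶.

A by-product is that per-pair marginal log-likelihoods are available exactly
at every draw — these are the pointwise contributions for LOO, with the
species pair as the leave-one-out unit (the level at which the seven models
differ).

## Priors, sampling, diagnostics

Priors are deliberately weak: Normal(0, variance 10) on β and k, Uniform(0,
10) on every standard deviation (σ, σ_w, s, s_α), and — for parameters the
uninformative convention does not pin down — Uniform(2, 100) on the kurtosis
parameters υ and ν_α so the pair-level variance exists, with the joint
support truncated so σ² + k·t > 0 (normal models) and υ + k·t > 2 (t
models) at every observed distance.

The marginal posterior is low-dimensional (2–6 global parameters, plus one
α_f per family pair in model 7), and is sampled with a componentwise
adaptive random-walk Metropolis sampler: proposal scales adapt toward 44%
acceptance during burn-in only and are then frozen, keeping the retained
chain exactly Markovian. Three extra moves address known geometry problems:
υ and ν_α use log-scale proposals (with the Hastings correction) to cover
2–100 evenly; a joint (υ, k) move walks along their posterior ridge by
changing υ while holding the df at the median distance fixed; and model 7
interleaves a non-centered rescale move that multiplies s_α and all α_f by
a common factor (Jacobian (F+1)·log c), which breaks the hierarchical
funnel that otherwise freezes s_α. Because the likelihood factorizes over
pairs and each pair carries exactly one α_f, all family effects are updated
per iteration with a single vectorized likelihood evaluation and independent
componentwise accept/reject.

Defaults mirror the reference protocol (3 chains × 10 000 iterations after
1 000 burn-in); scaled-down settings (2 chains × 1 500–2 500 after 400–800)
are used for the simulation studies and give max R-hat ≤ ~1.07 at 470 pairs.
Convergence is monitored with the rank-normalized split-chain potential
scale reduction factor (via arviz), warning above 1.1; constant chains are
NaN-guarded to 1.0. Identical seeds give bit-identical draws; per-chain
generators are seeded from (seed, chain, model id).

A two-stage plug-in variant (each pair reduced to its empirical mean with a
fixed standard error before fitting the pair-level model) is available
behind a flag for sensitivity analysis; the joint fit is the default because
it propagates measurement and replicate uncertainty into every parameter.

## Model comparison

PSIS-LOO (via arviz) estimates each model's expected log pointwise
predictive density from the per-pair log-likelihood matrices; the table
reports the deviance scale, LOO = −2·elpd, with ΔLOO the gap to the best
model and ΔLOO > 10 flagged as very strong support. Per-pair Pareto-k
diagnostics are carried through, with a reliability warning when more than
10% exceed 0.7. Tests check PSIS-LOO against exact refit leave-one-pair-out
at 30 pairs (agreement within 2 SE) — the refit oracle is independent of the
importance-sampling path.

## The synthetic-data generator

The generator emulates the statistical shape of the compilation the models
target: 470 unique pairs from 165 species in 39 families (family sizes
mildly skewed), replicate counts truncated-geometric on 1–11 with mean
≈ 2.06, within-family distances uniform on 5–300 Myr and between-family on
300–800 Myr (300 Myr being the approximate within/between-family boundary),
pair means drawn from any of the seven models, within-pair scatter σ_w = 0.3,
and per-biomass relative standard errors around 15%. Default generating
parameters (e.g. s = 0.5, υ = 6, k = −0.4 per 100 Myr; β = −0.022 per
100 Myr, i.e. ≈ −0.13 over 600 Myr) put the simulated data in the regime the
models are meant to separate: a slight trend dwarfed by divergence. Emitted
tables contain biomass means and standard errors, not r values, so they
exercise the same input path as real data; the emission fixes species B at a
baseline biomass and lets species A carry the signal, with equal relative
SEs so the delta-method variance hits the target measurement variance
exactly (construction is exact by design; tests pin r recovery at 10⁻¹⁰).

An independent Brownian oracle — Yule trees (dendropy) with a Brownian trait
walk along branches — confirms the distance-based variance law the
gradual-divergence model assumes: squared tip-trait differences regress on
patristic distance with slope σ²_BM.

What passing tests on synthetic data do **not** show: robustness to
correlated responses from shared species, study-level heterogeneity,
non-normal replicate scatter, systematically missing standard errors, or
phylogenetic distance error — none of which the generator produces.

## Numerical and design choices

- Distances are stored in Myr and converted to 100-Myr units at model-build
  time; β and k are always reported per 100 Myr.
- Unordered pair identity: the pair key is the sorted species-label tuple;
  r's relabelling invariance makes the choice content-free.
- Rows of one pair whose recorded distances differ by more than 1 Myr raise
  a consistency error rather than being averaged silently.
- The worked-example checks compare at two decimal places (the printed
  precision of the reference values 0.12 and 0.49; exact values 0.1178…,
  0.4855…).
- Problem sizes in the acceptance script (470 pairs, 2 chains × 2 000–2 500
  iterations, 20-replicate recovery studies) are the package's scaled-down
  study conditions; the full reference protocol is the default for real
  analyses.
- CSV exports use 17-significant-digit floats and round-trip parsing, so
  write→read reproduces r, var(r) and t bit-identically.

## Known limitations

- The Gauss–Hermite rule integrates the t density against the collapsed
  normal; if measurement noise were made very large relative to the t scale
  (v_j ≫ s²), accuracy would degrade. Realistic compilations are far from
  this regime.
- υ is weakly identified below ~500 pairs; its posterior is wide and only
  its small-vs-large character is meaningful. The (υ, k) ridge move makes
  this honest rather than fast.
- Model 7 estimates one α_f per observed family pair, most supported by a
  single species pair; the heavy-tailed hierarchical prior shrinks these
  strongly, and individual α_f intervals should be read with that in mind.
- Exact refit-LOO is quadratic in the number of pairs and only used as a
  test oracle at small n.
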