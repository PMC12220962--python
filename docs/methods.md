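# Methods

## The estimand and the data model

A duplex-sequencing experiment interrogates B duplex bases in a sample and
calls N single-molecule somatic mutations. The per-base burden is r = N/B.
Given the true per-base rate λ, N is modeled as Poisson(λB); B is treated
as known (it is reported by the calling pipeline). All downstream analysis
operates on (N, B) per sample plus the trinucleotide context of each call —
no read-level information is used, and mutation calling itself is out of
scope.

## Exact Poisson intervals and derived standard errors

For small N (sperm samples can carry single-digit counts) a Wald interval
on N/B is badly anticonservative, so the 95% interval on the Poisson mean
is the exact equal-tailed Garwood interval from chi-square quantiles:

    low  = χ²((1−level)/2, 2N) / 2        (0 when N = 0)
    high = χ²(1−(1−level)/2, 2N + 2) / 2

equivalently the means whose tail probabilities at the observed count equal
(1−level)/2. Dividing by B gives the interval on the burden. The standard
error used to weight the regression is the symmetric-width reading
se = (high − low)/(2z) with z = 1.959964 at 95% — the convention used when
interval endpoints are converted to meta-analysis weights. Exact intervals
are conservative: measured coverage at λ ∈ {0.5, 2, 10, 100} is ≥ 0.944
(and well above 0.95 at small λ), which the acceptance suite verifies
against an independent tail-sum bisection oracle.

## Genome-equivalent conversions

Burden differences are communicated as whole mutations per genome,
`round_half_away_from_zero(Δr · G)`. Factors shipped as configuration:

| factor | value | provenance |
| --- | --- | --- |
| human diploid somatic | 6.0 × 10⁹ | consistent with the published 282/888/720 conversions |
| human haploid (sperm) | 2.91 × 10⁹ | reverse-derived from a printed 28-mutation conversion; printed sperm conversions are mutually inconsistent at the ±3% level, so this is a config default, not an assertion |
| mouse | 6.8 × 10⁹ | reverse-derived: it reproduces the printed 1,424 (progenitor) and 2,418 (liver) per-genome counts from the printed group-mean differences; no stated source value exists |

## The group-effect regression

Per-sample burdens y_i are regressed on age and exposure group with
additive terms and no interaction:

    y_i ~ Normal(α + β_age·age_i + δ·1[exposed_i], √(se_i² + σ²_group(i)))

Two modeling commitments deserve comment.

**Measurement-error weighting.** The known per-sample se_i enters the
likelihood added in quadrature to the group residual SD — the generative
random-effects meta-analysis form — rather than as an inverse-variance
log-likelihood multiplier. The quadrature form keeps the model a proper
probability model and reduces to plain weighting when σ → 0.

**Distributional (heteroscedastic) variance.** σ is parameterized on the
log scale with one intercept per group, because exposed cohorts are
empirically far more dispersed around the age line than controls; a shared
σ would both miscalibrate the interval on δ and distort the weights.

Priors: Student-t(3, location, scale) on the intercept with
location = median(y) and scale = max(1.4826·MAD(y), 2.5) on the internally
rescaled response; flat priors on β_age and δ; Student-t(3, 0, 2.5) on each
log σ. The response is rescaled to mutations per Gb (×10⁹) for
conditioning and all reported draws are transformed back to the per-base
scale. Predictors (age and the group dummy) are centered internally so the
intercept decorrelates from the slopes; the reported α is transformed back
to the age-0/control origin. The intercept prior applies to the centered
intercept, matching the convention of the regression packages this model
family comes from.

**Sampler.** Per-parameter adaptive random-walk Metropolis, vectorized
across chains: proposal SDs start at 2.4× the least-squares coefficient
standard errors (0.3 on the log-σ coordinates) and are tuned during warmup
toward a 20–40% acceptance rate in windows of 50 iterations. Chains start
from the least-squares solution plus chain-indexed jitter (2 coefficient
SEs) drawn from the seeded stream. Defaults are 4 chains × 5,000
iterations with 2,500 warmup, i.e. 10,000 kept draws. The target posterior
is what matters, not the algorithm: the sampler is validated by split-R̂
(threshold 1.05; non-convergence is flagged, never silently ignored), by a
weighted-least-squares limit contract (σ pinned to 0, equal SEs, flattened
priors ⇒ posterior means equal the least-squares solution within 2%), and
by credible-interval calibration on replicate synthetic cohorts.
Split-R̂ follows the half-chain construction:
R̂ = √(((n−1)/n·W + B/n)/W); all-constant draws return 1, separated
constant chains return +inf.

**Problem sizes.** The calibration suites run 100 replicate cohorts of
40 + 40 samples at 4 chains × 1,500 iterations (750 warmup) per fit — a
reduced but converged setting chosen so the full calibration remains a
routine check rather than an overnight job; the per-fit defaults above
remain the full 4 × 5,000.

## Signature refitting

Spectra are built by collapsing each call's trinucleotide context to the
pyrimidine strand and binning into the 96 canonical channels (classes C>A,
C>G, C>T, T>A, T>C, T>G; flanks alphabetical within class). An optional
32-vector of genome/analyzed trinucleotide abundance ratios rescales
channels and renormalizes to the original total, correcting for uneven
context coverage of the interrogated bases.

*Regression route:* minimize ‖s/‖s‖₁ − Ce‖₂ subject to e ≥ 0 (NNLS),
iteratively dropping signatures with exposure proportion below a threshold
(default 0.05, always echoed in the output) and refitting until stable.
The threshold and the drop-and-refit rule are this package's explicit
selection procedure.

*Bayesian route:* s ~ Multinomial(N, Ce) with a flat Dirichlet prior on e,
sampled by adaptive random-walk Metropolis on the additive-log-ratio
transform (the prior contributes the log-Jacobian Σ log e_k); convergence
reuses split-R̂. Posterior-mean exposures are reported.

Both routes report the residual L2 norm and the cosine similarity between
observed and reconstructed spectra. At realistic sperm depths (tens of
mutations) mixture recovery degrades gracefully — exposures remain unbiased
but their spread grows roughly as 1/√N, which is why low-frequency
signatures are hard to call in that regime.

The bundled catalogue is **synthetic**: six deterministic columns (two
flat-ish clock-like profiles, sharp platinum-like and thiopurine-like
profiles, and one filler) with the same layout as a COSMIC v3.2 TSV, so
tests need no download; real catalogues load through the same reader.

## Auxiliary statistics

Welch's t with Welch–Satterthwaite df and two-sided p (two-sided is the
conservative default throughout); Pearson r with the exact t-based p on
n − 2 df; R² as the squared Pearson r of the simple linear fit; modified
Z-scores z = 0.6745·(x − median)/MAD with the unscaled MAD (the classical
definition), all-zero when MAD = 0 with equal values, ±inf sentinels when
MAD = 0 otherwise, and a default outlier threshold |z| > 3.5. The trio
comparison converts an observed per-genome burden into fold change over
the age-expected paternal germline burden (intercept + slope·age), the
excess, and years-to-accumulate = excess/slope. The default trio model
(slope 1.5 mutations/year, intercept 7) is an illustrative stand-in for
external trio fits and is configuration. Cross-sample overlap counts
distinct shared (chrom, pos, ref, alt) tuples, e.g. to confirm sperm calls
are absent from the same donor's saliva.

## The synthetic-cohort generator

What it emulates: age-linear burden accumulation with a group-level shift
δ and group-specific between-sample SDs (λ_i = max(ε, α + β·age_i + δ·g_i
+ η_i), η_i ~ N(0, σ²_group), floor ε = 10⁻¹² because Normal noise on a
positive rate can cross zero and the observed-rate model is silent there);
duplex bases uniform over a range; counts Poisson(λ_iB_i); contexts i.i.d.
from the group's signature mixture. One record per event; positions are
uniform over a virtual per-contig coordinate space and collisions are
allowed, since only counts and contexts matter downstream. Determinism:
one integer seed, per-sample substreams keyed by (seed, sample index), so
identical configs give byte-identical tables.

Human defaults: 32 controls + 36 exposed, ages Uniform(20, 65), B
Uniform(1, 3) Gb, intercept 2 × 10⁻⁹, slope 5 × 10⁻¹⁰ /base/year (a
paternal-germline-like ~1.5 mutations per haploid genome per year),
δ = 9.62 × 10⁻⁹, σ_control = 1.5 × 10⁻⁹, σ_exposed = 8 × 10⁻⁹. The
between-sample SDs are not published quantities; they are illustrative,
config-exposed values chosen to reproduce the qualitative pattern (exposed
group markedly more dispersed than controls at these burden magnitudes).

Mouse mode: arms at 0–3 treatment cycles, 2 animals per arm by default
(matching a per-cycle euthanasia schedule), one tissue per call, per-cycle
burden levels as config with defaults in which only the 3-cycle arm is
elevated (sperm 7.435 × 10⁻⁹ control → 3.029 × 10⁻⁸ at 3 cycles;
progenitor and liver analogues provided). The Welch power check in the
test suite uses 4 animals per arm — with 2 per arm the Welch df collapses
to ≈1 and no effect of this size is reliably detectable, which is a
property of the t test, not of the generator.

What it does not emulate: read-level error, duplex-family structure,
contamination, callability masks, clonal hematopoiesis or any
within-sample clonal structure, and inter-tissue correlation within a
donor. Passing tests therefore demonstrate correctness of the estimators
and calibration under the assumed sampling model, not robustness to those
real-data complications.

## Numerical and interface choices

TSV is the native interchange (restricted upstream data; no BAM/CRAM);
minimal VCF 4.2 export/import carries CHROM/POS/REF/ALT plus the collapsed
context as an INFO tag. Validation errors name the offending file line.
Rounding of per-genome counts is half away from zero. Multinomial channel
probabilities are floored at 10⁻³⁰⁰ inside the Bayesian fitter to keep the
log-likelihood finite on zero-probability channels. The pipeline exits
nonzero on validation failure but only warns (and flags the manifest) on
MCMC non-convergence, so a long run is never discarded for a recoverable
diagnostic.

## Known limitations

* The per-patient results of chemotherapy-exposure studies are not
  reproducible here — the underlying human data are restricted access; all
  calibration claims are statements about the synthetic data process.
* The NNLS selection rule (threshold + drop-and-refit) is one reasonable
  procedure among several; fitted proportions near the threshold are
  sensitive to it.
* The random-walk sampler is adequate for this 5-parameter posterior but
  would scale poorly to models with many covariates; swapping in a
  gradient-based sampler would not change any interface.
* Trio-model defaults and the haploid/mouse genome-equivalent factors are
  reverse-derived or illustrative configuration values, documented above.
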