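# mutburden

Somatic mutation burden analysis for duplex-sequencing cohorts.

High-fidelity duplex sequencing (e.g. NanoSeq) calls somatic mutations on
single DNA molecules, giving a per-sample burden of mutations per
interrogated duplex base. Studies of mutagenic exposures — chemotherapy
being the motivating case — compare these burdens between exposed and
unexposed donors across tissues (sperm, saliva, blood, liver), where the
counts per sample can be in the single digits and the exposed group is far
more variable than controls. `mutburden` implements that analysis as a
tested, reusable pipeline for statistical geneticists and sequencing
groups:

* **Burden estimation** — exact (Garwood) Poisson confidence intervals on
  the count N, burden r = N/B for B duplex bases, standard errors derived
  from the interval width, and conversion of burdens and burden differences
  into mutations per genome via a genome-equivalent base count G
  (`round(Δr · G)`).
* **Group-effect regression** — a Bayesian distributional regression

  ```
  y_i ~ Normal(α + β_age·age_i + δ·1[exposed_i], sqrt(se_i² + σ²_group(i)))
  ```

  with per-sample measurement SDs entering the likelihood in quadrature
  (meta-analysis weighting), group-specific residual SDs, Student-t(3)
  prior on the intercept and flat priors on coefficients, sampled by
  multiple independent MCMC chains with split-R̂ convergence diagnostics.
  δ is the exposure-associated shift in burden.
* **Signature refitting** — 96-channel pyrimidine-collapsed spectra refit
  against a COSMIC-layout SBS catalogue by non-negative least squares with
  iterative pruning, and by Bayesian multinomial inference with a flat
  Dirichlet prior; both report per-signature proportions of mutations
  explained plus reconstruction diagnostics.
* **Cohort statistics** — Welch's t test, Pearson correlation, linear R²,
  modified Z-score outlier detection (0.6745·(x − median)/MAD),
  trio-expected germline burden comparison (fold change and
  years-to-accumulate), and cross-sample mutation overlap.
* **Synthetic cohorts** — a generator that emulates the assumed data
  process (age-linear burden, group shift, group-specific between-sample
  variance, Poisson counts given duplex bases, contexts from signature
  mixtures) with stored ground truth, so every stage is testable without
  the restricted-access human data. A mouse mode emits cyclic-dosing arms
  (0–3 treatment cycles).

## Worked example

```python
import mutburden as mb

cfg = mb.CohortConfig(n_control=40, n_exposed=40, group_shift=9.62e-9, seed=7)
meta, muts, truth = mb.simulate_cohort(cfg)
burdens = mb.estimate_burden_table(meta, muts)
print(burdens.head(3).to_string(index=False))

spec = mb.RegressionSpec(chains=4, iterations=2000, warmup=1000, seed=7)
summary, _ = mb.fit_group_effect(burdens, meta, spec)
d = summary.parameters["delta"]
print(f"group shift: {d.mean:.3e} (95% CrI {d.q2_5:.3e} to {d.q97_5:.3e}), "
      f"R-hat {d.rhat:.3f}, converged={summary.converged}")
print("additional mutations per genome:", mb.additional_mutations(d.mean, 6.0e9))
```

prints

```
sample_id  count  duplex_bases         rate       ci_low      ci_high           se  mutations_per_genome
     C001     60  2.551371e+09 2.351676e-08 1.794577e-08 3.027074e-08 3.144182e-09                   141
     C002     29  1.378195e+09 2.104201e-08 1.409216e-08 3.021983e-08 4.114277e-09                   126
     C003     54  2.867477e+09 1.883189e-08 1.414709e-08 2.457153e-08 2.659343e-09                   113
group shift: 1.085e-08 (95% CrI 7.984e-09 to 1.354e-08), R-hat 1.021, converged=True
additional mutations per genome: 65
```

Each row is one sample: 60 mutations over 2.55 Gb of duplex bases is a
burden of 2.35 × 10⁻⁸ per base with its exact 95% Poisson interval and the
derived SE used to weight the regression. The posterior for δ recovers the
simulated exposure shift (truth 9.62 × 10⁻⁹, inside the credible interval),
and the point estimate corresponds to ~65 extra mutations per 6-Gb diploid
genome.

The same stages are available from the shell:

```sh
mutburden simulate --seed 7 --samples-out samples.tsv --mutations-out muts.tsv
mutburden burden --samples samples.tsv --mutations muts.tsv --out burdens.tsv
mutburden regress --samples samples.tsv --burdens burdens.tsv --out regression.json
mutburden run --config config.yaml        # full pipeline from a YAML config
```

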