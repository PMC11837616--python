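# Methods

## The model

`compdm` fits a mixed-effects Dirichlet-multinomial (DM) regression to
matched count compositions — in the motivating application, mutational-
signature exposure counts for clonal and subclonal mutations of the same
patients.  For observation *j* (a patient/group combination) with counts
**y**_j over K signatures and total T_j:

    u_i  ~ MVN(0, Σ)                                (patient intercepts)
    η_j  = x_j' β + z_j' U                          (ALR-scale predictor)
    p_j  = ALR⁻¹(η_j)                               (mean composition)
    log λ_j = d_j' θ                                (precision, log link)
    y_j  ~ DM(λ_j · p_j, T_j)

β is P×(K−1): in the default two-group design row 0 is the baseline
log-ratio composition and row 1 (β₁) the group shift — the differential-
abundance parameter.  Exposures are compositional: only ratios carry
information, so everything is modelled on the additive log-ratio scale
against a reference signature (last column by default; internally
categories are rotated so the reference is last and reported in that
order).  The precision λ enters on the log scale so that the group
coefficient is a log-shift and positivity is structural; lower λ means
more overdispersion relative to the multinomial.

Variants (`variant=` in `DirichletMultinomialMixedModel` / `fit_model`):

| name                  | likelihood   | random effects        | precision    |
|-----------------------|--------------|-----------------------|--------------|
| diagREDM (default)    | DM           | diagonal Σ            | per D column |
| fullREDM              | DM           | unstructured Σ        | per D column |
| singleREDM            | DM           | scalar shared across log-ratios | per D column |
| fullREM               | multinomial  | unstructured Σ        | none         |
| FEDMsinglelambda      | DM           | none                  | single       |
| diagREDMpatientlambda | DM           | diagonal Σ            | per patient  |

`fullREM` has no precision parameter because the multinomial has none;
`singleREDM` draws one scalar intercept per patient and adds it to all
K−1 log-ratio columns.

## Estimation

Random intercepts are integrated out by the Laplace approximation.
Because Z is a patient indicator, the integral factorises over patients;
an inner Newton optimisation (vectorised across patients, analytic
gradient and Hessian of the DM term with respect to η, eigenvalue-clamped
steps, per-patient step-halving) finds each posterior mode û_i, and the
marginal negative log-likelihood is

    Σ_i [ f_i(û_i) + ½ log det H_i − (d/2) log 2π ]

with H_i the per-patient Hessian of the joint NLL.  The trigamma function
needed for the Hessian is computed by upward recurrence plus an asymptotic
series (≈10⁻¹² accurate), which is substantially faster than the generic
zeta-based routine and dominates the inner-loop cost otherwise.

The outer problem — β, θ, and the random-effect parameters (log-SDs, or an
unconstrained Cholesky factor with log-diagonal for the unstructured Σ,
which makes positive-definiteness structural) — is minimised by L-BFGS
with forward-difference gradients (step 10⁻⁵), warm-starting the inner
modes from an anchor that only advances at accepted iterates so the
objective stays a deterministic function of the parameters during
differencing.  The inner tolerance is machine-tight (10⁻¹⁰ scaled by √T
per patient) because the log-determinant term is *linear* in the mode
error: a loose inner solve makes the outer objective microscopically
rough, which corrupts finite-difference Hessians.  After convergence a
short Newton polish with central-difference gradients (step 10⁻⁶) pins
the optimum down so that refits under permuted category orderings agree
to ~10⁻⁸ in the NLL.

Standard errors come from the inverse of the central-difference Hessian
of the marginal NLL at the optimum (step 10⁻³, chosen to balance
truncation against rounding noise).  Random-effect variances estimated at
the zero boundary leave the objective flat in their log-SD coordinate;
those directions are pruned before inversion, and the remaining
parameters keep valid SEs.  A non-invertible Hessian yields
`converged_=False` with `vcov_=None` rather than an exception — this is
the regime the model genuinely struggles in (many signatures, few
samples, a signature in very low abundance).

Initial values: row 0 of β from the ALR of the pooled reference-group
composition (0.5 pseudocount on empty cells), other rows zero; θ at
(log 50, 0, …); log-SDs at log 0.5.

## Inference

* **Differential abundance**: generalised Wald statistic
  w = β̂₁' Σ_{β̂₁}⁻¹ β̂₁ against χ²_{K−1}.  The statistic is invariant to
  the ALR baseline for the invariant families (no random effects, or
  unstructured Σ); for the diagonal-RE variant the model family itself is
  reference-dependent, but a pure relabelling of categories that keeps
  the same reference signature leaves the fit unchanged (tested to 1e-6
  in NLL and 1e-4 in w).
* **Differential precision**: two-sided z test on the group log-precision
  shift θ₂, with its SE from the same covariance.  A negative estimate
  means the second group is more overdispersed.
* **Multiple testing** across cohorts: Benjamini–Hochberg step-up
  (delegated to statsmodels).
* **Softmax coefficients**: β̂₁ mapped to the K-simplex with the baseline
  appended at 0; log-ratios are preserved, so pairwise comparisons remain
  meaningful and the baseline gets a value.
* **Minimal perturbation labels**: each signature (baseline included,
  with estimate 0 and SE 0) is labelled increase/decrease/no-change by
  whether its estimate ± 1.96·SE interval clears the median of the
  augmented β̂₁ vector.  The z-interval rule is our concrete choice where
  several are defensible; it assumes most signatures do not change.

## Exposure extraction

Given signature definitions S (F×K, columns on the simplex; F is
typically 96 trinucleotide categories) and an observation's category
counts v with total T, exposures solve

    min_e ‖ v/T − S e ‖²   s.t.  e ≥ 0, Σe = 1

by non-negative least squares with a heavily weighted (10⁴) sum-to-one
row followed by exact renormalisation — for noiseless data the constraint
is inactive at the solution, so recovery is exact to solver precision
(tested at 10⁻⁸).  Counts are then formed by largest-remainder rounding
of T·e so every row sums exactly to T (the DM likelihood needs integers
with preserved totals; the rounding rule is our choice).  The least
squares is on the proportion scale and unweighted by T; a T-weighted
variant would be a reasonable alternative but is not implemented.

## Synthetic data

`simulate_from_model` draws matched two-group data from the generative
chain above.  The defaults define the study conditions used throughout:
200 patients, K=5 signatures, log-normal totals (median 3000, σ_log 1 —
whole-genome-scale tolls), diagonal intercept SDs 0.5, θ=(log 50, −0.5)
(subclonal group more dispersed), and β₁ mixing zero and non-zero entries
(pattern 0.5, 0, −0.5 cycled).  These match a realistic cancer-cohort
regime; sample size and totals can be pushed down to ~20 patients and
~50 mutations, where convergence failures start to appear and are
reported rather than hidden.

`simulate_mixture` emulates the catalog-level pipeline: group-1 exposures
are drawn from a logistic-normal distribution A (ALR-normal, dispersion
0.3); group-2 exposures are the per-patient convex mixture
(1−π)·e_A + π·e_B with e_B from a second logistic-normal B whose mean
reverses the abundance ranking.  Mutations over the F categories are
multinomial with probabilities S·e.  π=0 is an exchangeable null; power
should rise with π.  The packaged signature definitions are synthetic
(sparse Dirichlet draws over the 96 standard trinucleotide categories) so
no external catalog download is needed; they mimic the peakedness of real
signatures but not their empirical correlation structure.

What the generators do *not* emulate: signature-extraction error
correlated across observations, clonality misassignment, copy-number or
coverage artefacts, and cohort-level heterogeneity in the active
signature set.  Passing tests therefore demonstrate correctness of the
estimator and testing machinery under the stated model, not robustness
to those real-data pathologies.

`monte_carlo_study` derives one seed per replicate from a master seed by
counter (order-independent), counts failed fits rather than dropping them
silently, and reports per-element bias, empirical and mean model SE,
95%-CI coverage and Wald rejection rate.  Monte-Carlo fits use a reduced
accuracy profile (no Newton polish, inner tolerance 10⁻⁸, outer ftol
10⁻⁹): per-replicate summaries need ~10⁻³ relative accuracy, not the
10⁻⁸-level reproducibility of the default profile.

## Problem sizes used in the shipped studies

Chosen as desk-scale versions of the study design: coverage uses 200
replicates of 200 patients at K=5 (the generator defaults); null
calibration uses 500 replicates of 40 patients at K=3 with β₁=0; the
mixture power ladder uses π ∈ {0, 0.08, 0.5} with 40 replicates of 25
patients over a 4-signature catalog and ~2000 mutations per observation.

## Known limitations

* No error propagation from exposure extraction into the regression; the
  fitted counts are treated as observed.
* The Laplace approximation error grows as λ falls; at λ ≲ 40 the
  marginal NLL can differ from quadrature by ~10⁻³ relative (the K=2
  oracle test runs at λ=1000 where the approximation is in its accurate
  regime).
* The Wald test relies on the asymptotic χ² null; at very small n it can
  be mildly anticonservative (the null-calibration suite pins its size at
  n=40).
* `diagREDM` is not invariant to the choice of reference signature (the
  diagonal covariance is basis-dependent); `fullREDM` and the no-RE
  variants are.
* Gradients are finite-difference; an AD backend would be faster and
  cleaner but is deliberately out of scope.
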