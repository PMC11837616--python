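# compdm

Differential abundance of mutational-signature exposures between matched
groups of observations — e.g. the clonal versus subclonal mutations of
the same tumours — modelled as compositional count data.

Signature exposures are relative: each observation is a vector of counts
over K signatures whose total is not of interest, only the allocation.
`compdm` fits a **mixed-effects Dirichlet-multinomial regression** on the
additive log-ratio (ALR) scale:

    u_i ~ MVN(0, Σ)                       patient random intercepts
    p_j = ALR⁻¹(x_j'β + z_j'U)            mean composition
    log λ_j = d_j'θ                       group-specific precision
    y_j ~ DM(λ_j p_j, T_j)                counts with total T_j

The group-shift row β₁ of the coefficient matrix captures differential
abundance; the joint null β₁ = 0 is tested with the generalised Wald
statistic w = β̂₁' Σ_{β̂₁}⁻¹ β̂₁ ~ χ²_{K−1}.  The precision shift θ₂
tests whether one group is more overdispersed.  Random intercepts are
integrated out with a Laplace approximation; all variants (diagonal,
full, scalar or no random effects; multinomial likelihood; per-patient
precision) share one estimator.

The package is aimed at statistical genomicists comparing signature
activity between timepoints, clonality strata, chromosomes or treatment
groups, and ships the surrounding pipeline: QP extraction of exposures
from COSMIC-style category counts, matched-design simulators, a
Monte-Carlo harness, TSV/JSON I/O and a CLI.

## Worked example

```python
import numpy as np
from compdm import (ModelSimConfig, simulate_from_model, fit_model,
                    wald_test, precision_shift_test, results_table)

cfg = ModelSimConfig(n_patients=200, K=5, seed=42)   # matched two-group cohort
data, U_true = simulate_from_model(cfg, "diagREDM")

fit = fit_model(data, variant="diagREDM")
print(np.round(fit.coef_[1], 3))          # group-shift (differential abundance)
print(wald_test(fit))
print(precision_shift_test(fit))
```

Output:

```
[ 0.417 -0.101 -0.545  0.403]
WaldResult(w=363.1643449034117, df=4, p_value=2.519549310605745e-77)
(-4.710967728174094, 2.465432785116095e-06)
```

The simulation truth was β₁ = (0.5, 0, −0.5, 0.5) with group
log-precision shift −0.5: the estimates land within ~2 standard errors
of the truth, the Wald test emphatically rejects no-differential-
abundance (w = 363.2 on 4 degrees of freedom), and the precision test
(z = −4.71) correctly reports the second group as more overdispersed.
`results_table(fit)` returns a tidy per-signature frame with β̂₀, β̂₁,
SEs, softmax-transformed shifts and increase/decrease/no-change labels.

The estimator is also available directly as a scikit-learn-style class:

```python
from compdm import DirichletMultinomialMixedModel
est = DirichletMultinomialMixedModel(variant="diagREDM")
est.fit(X, Y, groups=patient_ids)       # X: N×P design, Y: N×K counts
est.coef_, est.vcov_, est.random_effects_
```

## Command line

```bash
compdm simulate --n-patients 50 --k 5 --seed 1 --out exposures.tsv
compdm test --exposures exposures.tsv --model diagREDM --out results/
compdm extract --catalog catalog.tsv --signatures cosmic.tsv --out exp.tsv
compdm mc-study --n-reps 100 --seed 1 --out mc.json
```

Exit codes: 0 success, 1 input error, 2 fit did not converge (results
still written with `converged: false`).

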