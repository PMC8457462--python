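# carabclock

Fossil- and geology-calibrated Bayesian node dating for the *Carabus*
ground-beetle phylogeny — calibration prior densities, Felsenstein-pruning
likelihood under strict and relaxed clocks, Yule-prior MCMC over node ages,
leave-one-out calibration sensitivity analysis, and gamma-fitted secondary
calibrations.

## The problem

Molecular divergence dates are only as good as their calibrations. A
re-dating of the *Carabus* radiation showed that replacing geological
island/strait calibrations with fossil evidence — in particular a ~99 Ma
Harpalinae amber fossil constraining the Carabidae root — roughly doubles
the inferred ages of key splits, and that the root prior drives the result
almost single-handedly. `carabclock` packages that workflow as a reusable,
testable pipeline: you declare an alignment, a partition/clock/tree-prior
configuration and a table of node-age priors, and get posterior node-age
summaries, sensitivity runs where each calibration group is dropped in
turn, and secondary-calibration gamma fits — together with a synthetic-data
generator that builds study-shaped datasets with known truth, so every
stage can be checked for parameter recovery.

The posterior sampled is the standard node-dating target

    p(t, λ, θ | D) ∝ L(D | t, θ) · f_Yule(t | λ) · ∏_k c_k(t_k) · p(λ, θ)

with node ages `t` in Ma, a Yule (pure-birth) tree prior, and calibration
densities `c_k` (offset log-normal in the real-space-mean convention,
truncated normal, uniform, offset exponential, gamma) on constrained
clades. See `docs/methods.md` for the model, the moves, and the numerical
conventions.

## Worked example

```python
import numpy as np
from carabclock import (
    CalibrationDensity, DatingProblem, McmcSettings, run_chain, summarize_clades,
)
from carabclock.synthetic_data import make_recovery_study

study = make_recovery_study(seed=42)          # 20 taxa, 2000 nt, true root 50 Ma
problem = DatingProblem(
    tree=study.tree,
    settings=McmcSettings(chain_length=40_000, sample_interval=40),
    alignment=study.alignments["marker"],
    partition_scheme=study.partition_schemes["marker"],
    models=study.models["marker"],
    clock=study.clock,                         # strict, 0.01 subs/site/Ma
    scheme=study.scheme,                       # one informative root prior
)
trace = run_chain(problem, np.random.default_rng(7))
(root,) = summarize_clades(trace, ["root"])
print(f"root: median {root.median:.2f} Ma, "
      f"95% HPD ({root.hpd_lo:.2f}, {root.hpd_hi:.2f}), ESS {root.ess:.0f}")
```

prints

```
root: median 47.16 Ma, 95% HPD (37.78, 57.09), ESS 339
```

— the posterior median sits within ~5% of the simulated truth (50 Ma) and
the 95% highest-posterior-density interval covers it; ESS is the
autocorrelation-corrected number of independent samples behind the
estimate.

The same machinery drives the command line:

```bash
carabclock prior-report --config configs/calibrations_revised.yaml
carabclock simulate --name nd5_extended --seed 58 --out-dir scratch/nd5
carabclock run --config run.yaml --seed 7 --out results/
carabclock loo --config run.yaml --groups C,F,GO,J,M,RO --out-dir results/loo
carabclock secondary-fit --trace results/trace.tsv --clades A,B,C
```

`prior-report` tabulates each calibration density with its central 95%
prior interval, reproducing the analytically consistent bounds of the two
published calibration tables (e.g. the revised Canary-Islands log-normal
gives 2.39–59.5 Ma; the root prior's lower bound is 98.2 Ma). `loo` runs
the all-priors chain plus one chain per omitted calibration group and
exports a long-format table ready for violin plots; on the bundled
root-dominated synthetic study, dropping the root group shifts the root
median younger by tens of Ma while dropping any other single group moves it
only a few — the mechanism the sensitivity design exists to expose.

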