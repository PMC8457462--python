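# Methods

## The model

`carabclock` implements Bayesian node dating of a rooted, binary,
ultrametric time-tree. The posterior over node ages **t**, birth rate λ,
and clock/model parameters θ is

    p(t, λ, θ | D) ∝ L(D | t, θ) · f_Yule(t | λ) · ∏_k c_k(t_k) · p(λ) · p(θ)

with

- **Likelihood** `L`: Felsenstein pruning over compressed site patterns.
  Per-branch expected distance = branch duration (Ma) × branch rate
  (substitutions/site/Ma). Substitution models JC69, K80, HKY and GTR, all
  normalized to one expected substitution per unit distance (closed-form
  transition probabilities for the HKY family, eigendecomposition for GTR);
  optional discrete-gamma rate heterogeneity with category rates equal to
  the means of equal-probability quantile slices (4 categories by default).
  Gaps and IUPAC ambiguity codes are missing data, marginalized through
  partial-likelihood vectors; they are never a fifth state. Alignments may
  be split into partitions (per-gene blocks, or the mitochondrial "2P"
  scheme: codon positions 1+2 versus 3, with the reading frame declared).
- **Tree prior** `f_Yule`: pure-birth density, log f = (n−1)·ln λ − λ·(total
  branch duration), up to constants free of λ and node ages. λ carries a
  uniform(0, 100) hyperprior and is sampled. For validation runs the tree
  prior can be switched off entirely (`tree_prior: none`), which makes the
  sampled marginal of a single calibrated node equal its calibration
  density — the basis of the prior-sampling tests.
- **Calibration densities** `c_k`: one of five families on a constrained
  node age — offset log-normal parameterized by the *real-space* mean
  (log-mean M = ln μ − σ²/2, the "meanInRealSpace" convention), truncated
  normal renormalized on [a, b], uniform, offset exponential, and gamma.
  Densities multiply the tree prior without an interaction correction for
  nested calibrated nodes (the behaviour of the standard dating tools this
  package mirrors); `validate_scheme` warns when a nested pair is
  structurally incoherent.
- **Clocks**: strict (one rate) or uncorrelated log-normal (ULN) with
  i.i.d. per-branch multipliers of real-space mean 1 and log-sd σ_ULN,
  resampled by MCMC moves (continuous rates, not the discretized-quantile
  assignment some tools use).

### Reporting conventions

Ages are Ma, present = 0, increasing into the past. Summaries are the
posterior median, mean, and the 95% HPD interval — the shortest contiguous
window of sorted samples containing ⌈0.95·n⌉ points, ties resolved to the
smallest lower endpoint. ESS is n / (1 + 2Σρ_k) with Geyer's
initial-positive-sequence truncation of the autocorrelations; a
zero-variance series is reported as ESS = n with a warning. Burn-in drops
`floor(burnin_fraction × rows)` leading trace rows (default 10%).

A density with a hard ceiling (e.g. the 163.5 Ma family-level fossil bound)
is renormalized on the truncated support, but its reported 95% prior
interval is computed on the un-truncated density by default — this matches
how the published calibration tables print log-normal intervals whose upper
bound is the ceiling itself.

### Published bounds reproduced, and the ones that are not

The prior-report command reproduces, at printed precision, the twelve
analytically consistent interval bounds of the two published calibration
tables: C1 2.39/59.5, F 5.4/158.5, F1 lower 5.43, J1 1.55/5.46, M2
5.31/7.14, C2 1.5/58.5, and the root (RO) lower bound 98.2. A few printed
cells cannot be derived from their stated densities under any convention we
tried and are deliberately not matched: the original table's uniform lower
bound 0.03 (central 2.5% of Uniform(0, 14.5) is 0.36), the revised table's
J upper 14.3 and M 5.54–14.8 cells (central quantiles give 14.625 and
5.7375–14.7625), the F2 lower 26.5 (26.4), and the GO interval 32.1–163.5
(central quantiles of the stated log-normal give ≈31.4–162.6). These look
like rounding or transcription artefacts in the source tables; we always
report central 2.5–97.5% quantiles.

## MCMC

Metropolis–Hastings over node ages with fixed topology by default (every
reported quantity is an age); a constrained nearest-neighbour-interchange
mode samples topology while honouring monophyly and basal-attachment
constraints. Moves and Hastings terms:

- node-age uniform slide within (oldest child age, parent age) — symmetric;
- root-age log-scale, log-Hastings ln m;
- whole-tree scale of internal ages, log-Hastings n_int·ln m;
- rate–time ridge move scaling ages by m and the clock mean by 1/m
  (branch distances unchanged, so no likelihood re-evaluation),
  log-Hastings (n_int − 1)·ln m;
- scale moves on λ and the clock mean rate;
- ULN single-branch multiplier resampling from its prior (independence
  kernel);
- root-calibration independence draw: the root age is re-proposed from the
  root calibration density itself, log-Hastings q(old) − q(new). Sharp
  offset priors (the root prior has half its mass within ~0.02 Ma of its
  offset yet a 97.5% quantile 64 Ma higher) mix extremely poorly under
  local scale moves; the independence kernel makes prior sampling of such
  densities effectively i.i.d. and remains a valid kernel when data are
  present.

Likelihood evaluations are incremental: each partition caches per-branch
transition matrices and per-node partials (rescaled per pattern, with
accumulated log scalers); a node-age move re-evaluates only the changed
branches and the ancestors of the moved node, with O(1) revert on
rejection. The inner loops are numba-compiled when numba is importable and
fall back to equivalent numpy code otherwise. Initialization
rejection-samples node ages (root age drawn from the root calibration,
internal ages rescaled, jittered, and nudged into their supports) until the
joint prior is finite, up to 10⁴ attempts.

All randomness flows through one seeded generator; a chain is bit-identical
given its seed. In multi-run experiments each run's seed derives
deterministically from the base seed and the run label (CRC32, kept below
2³¹).

## Synthetic studies

The generator produces complete studies — true Yule tree (backward
construction: waiting time Exponential(kλ) while k lineages remain,
uniform pair joins), true clock, sequences simulated forward under the
likelihood model (per-site gamma category drawn once), and calibration
schemes anchored on true node ages whose supports are asserted to contain
the truth. Three fixtures mirror the source study's dataset shapes: 58
taxa × 1 marker, 34 taxa × 9 markers totalling 7888 nt (five
mitochondrial 2P blocks of 1137/708/786/1101/672 nt and four nuclear NP
blocks of 900/840/804/940 nt — the split is our choice; only the total is
given), and a 19-taxon ingroup. True parameters echo the organism's scale:
root ≈ 100 Ma, strict rate ≈ 0.01 substitutions/site/Ma.

Two purpose-built studies drive the experiments:

- **Recovery** (20 taxa, 2000 nt, root 50 Ma, rate 0.01, HKY+Γ): a single
  tight log-normal root calibration whose real-space mean is the true root
  age. Across 20 replicates the root-age 95% HPD covers the truth in ≥16
  and the median replicate's posterior-median error stays below 15%.
- **Sensitivity** (16 taxa, 800 nt, root 60 Ma): five internal calibration
  groups (C, F, GO, J, M) anchored on truth plus a root group (RO) whose
  support contains the truth but whose mass sits far older (real-space mean
  2.2× the true root age above an offset at 0.85×). This reproduces the
  qualitative mechanism of the source analysis: the leave-one-out design
  (one run per omitted group plus an all-priors run, monophyly constraints
  retained) shows the root group moving the dating more than any other
  single group, and all tracked clades dating older with the root prior
  than without it.

What the generator does *not* emulate: sequencing error, indels and
alignment uncertainty, missing-data patterns, substitution-model
misspecification, and topological uncertainty in the fixed-topology runs.
Passing tests demonstrate correctness of the machinery and the qualitative
calibration mechanism on clean data, not field performance on real
alignments.

## Gamma secondary calibrations

Posterior node-age samples are condensed into gamma densities by maximum
likelihood: moment initialization (shape = mean²/var, scale = var/mean),
then Newton iterations on the profile score ln k − ψ(k) − s with
s = ln(x̄) − mean(ln x), to relative tolerance 1e-8; the scale follows as
x̄/k. The fit agrees with an independent dense grid search to 3 significant
figures and recovers the published node-A generating pair (shape 80.576,
scale 0.231) within 5% from 10⁴ draws. Fitted densities become gamma
priors (offset 0) on the same crown clades of another dataset, mirroring
the secondary-calibration workflow. Note the published node-A gamma has
mean ≈ 18.6 Ma while the same analysis reports a median of 17.58 Ma for
that node; the tension is in the source values themselves and is not
resolvable here.

## Problem sizes and numerical choices

Chains in the test-suite experiments use 4×10⁴–4×10⁵ states (thinned to
~10³ rows), our desk-scale choice for the experiments' statistical targets;
the full protocol (10⁸ states sampling 10⁴ trees, 10% burn-in) is supported
verbatim and validated structurally. Strict age ordering uses tolerance
1e-9, with exactly tied ages jittered by 1e-6 Ma at construction (logged).
Pattern-likelihood underflow is prevented by per-pattern rescaling shared
across rate categories. Quantile/CDF round trips hold to 1e-9; densities
integrate to 1 within 1e-6 under adaptive quadrature, including offset and
truncated cases.

## Known limitations

- Calibration densities multiply the tree prior; nested calibrations are
  therefore approximate, as in the reference tools.
- Substitution-model averaging is out of scope; per-partition fixed models
  (default HKY+Γ₄) stand in. Invariant-site proportions, codon and
  amino-acid models are not implemented.
- The constrained-NNI topology sampler is adequate for the constraint-
  respecting runs it mirrors but is not tuned for hard topology inference.
- The published posterior medians (e.g. crown-group TMRCA 53.92 Ma) require
  the archived real alignments and 10⁸-state chains; this package provides
  the workflow, not those numbers.
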