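# Methods

## The linear birth–death process and its rate functions

`bdtree` works with the linear (per-capita) birth–death process (LBDP): with
`n` individuals alive, the population-level birth rate is `n·λ` and the death
rate `n·μ`. Starting from one individual, the population size `Z(t)` has an
atom at 0 (extinction by `t`, probability `α(t)`) and a geometric law on
`{1, 2, …}` with parameter `β(t)`:

```
p_10(t) = α(t),     p_1m(t) = (1 − α(t)) (1 − β(t)) β(t)^{m−1},   m ≥ 1
β(t) = λ(e^{(λ−μ)t} − 1) / (λ e^{(λ−μ)t} − μ),   α(t) = (μ/λ) β(t)    (λ ≠ μ)
β(t) = α(t) = λt / (1 + λt)                                          (λ = μ)
```

with the useful identity `dβ/dt = λ(1 − α)(1 − β)`. The Yule (pure birth,
`μ = 0`) case reduces to a geometric law with success probability `e^{−λt}`;
`r` independent founders give a negative binomial. A pure-birth process with
time-varying split rate `λ(u)` is a deterministic time-change of a unit-rate
Yule process through `ρ(t) = ∫₀ᵗ λ(u) du`.

Numerical choices:

- The `λ = μ` expression is used whenever `|λ − μ| ≤ 1e−8·λ`; the general
  formula has a removable singularity there and cancels catastrophically
  nearby. Continuity across the switch is tested to 1e−6.
- Geometric powers are computed in log space so large `n·λ·t` does not
  overflow; infinite sums are truncated where the closed-form geometric tail
  falls below 1e−12 (`bdp_support_upper`).
- `ρ(t)` uses adaptive quadrature with absolute tolerance 1e−10; the pmf's
  accuracy is limited by the accuracy of `ρ`. Negativity of the rate is
  screened on a 33-point probe grid (quadrature cannot detect it reliably).

## Trees: complete, pruned, and directly reconstructed

`TimedTree` stores a strictly binary timed tree as parallel arrays (parent,
birth/end time, end reason, lineage label). Time runs from the root at 0 to
the tips at the horizon `t`; Newick serialization stores branch *durations*
and the root's stem edge, so absolute times are recovered on read. Lineage
labels follow creation order: at a split the first child continues the
parent's label, the second starts the next label.

`simulate_complete_tree` is an event-driven (Gillespie) simulation: with `n`
extant lineages the next event is exponential with rate `n(λ+μ)`, a uniformly
chosen lineage splits with probability `λ/(λ+μ)` or dies. Extinct trees are
valid outputs. `prune_to_reconstructed` removes lineages with no extant
descendant and concatenates the branch segments of the resulting unary
pass-through nodes; the stem from time 0 to the first surviving split is
retained. The root convention is deliberate: when the MRCA of the survivors
postdates time 0 the tree keeps its stem (flagged by
`TimedTree.stem_from_origin`), which is also what makes truncal mutations
representable in the cell model.

Conditioned on `n` survivors at `t`, the `n−1` split times are the increasing
order statistics of i.i.d. draws with CDF

```
G(u) = 1 − β(t−u)/β(t),   0 ≤ u ≤ t,
```

which `simulate_reconstructed_tree` inverts in closed form (the probability
integral transform; `β` is analytically invertible in both the `λ ≠ μ` and
critical branches). Topology is grown by bifurcating a uniformly chosen
extant lineage at each split time. The direct sampler is the production path;
rejection on the extant count appears only in tests, as the independent
oracle for the conditional law. Split-time ties at float resolution (an
event of probability zero) are perturbed by one ulp with a warning.

## Immigration, family sizes, and the Ewens sampling formula

Families arrive as a homogeneous Poisson process of rate `θ` and grow as
independent LBDPs from one founder. Marking each arrival with its family size
at the horizon makes the size-class counts `C_j(t)` independent Poisson
variables with

```
E C_j(t) = θ ∫₀ᵗ p_1j(t−u) du = (θ/λ) β(t)^j / j,   j ≥ 1.
```

The `j = 0` quantity `θt + (θ/λ)log(1 − β(t))` is exposed as the expected
number of families that arrived *and went extinct* by `t` — a cumulative
count that grows with `t`, not a Poisson mean bounded by 1; the quadrature
cross-check path (`expected_family_count_quadrature`) confirms it equals
`θ∫₀ᵗ α(u) du`. The total population `Z(t)` is negative binomial with shape
`θ/λ`, and conditional on `Z(t) = n` the family-size configuration follows
the Ewens sampling formula with concentration `κ = θ/λ`. `ewens_pmf` takes
`κ` directly (the formula depends on the model only through it) and uses a
dense multiplicity vector `c_1..c_n` with `Σ j c_j = n` enforced. Family
simulation runs one event-driven LBDP per family rather than a joint
Gillespie over individuals, mirroring the independence structure the
marked-Poisson results rely on.

## Fisher's two-sample variance

For the ecology application the growth model is a Yule process with the time
unit fixed by `λ = 1` (general `λ` is a time rescaling). A *specimen* is
counted at its birth or arrival instant — the only embedding under which the
species count in `(0, t₁]` is Poisson(`θt₁`) and the closed forms hold. The
overlap count `F(a,b)` (families with at least one specimen in `(a,b]`) is
Poisson with mean `θ·log(e^b − e^a + 1)`; covariances across ordered windows
are explicit, yielding

```
E V₂ = ½ E(F₁ − F₂)² = ½{ θ log(e^{2t₂}e^{−t₁}/w) + θ² log²(e^{t₁}/w) },
w = e^{t₂} − e^{t₁} + 1,
```

and, with `t₁, t₂` chosen so the expected specimen counts are `n₁` and
`n₁+n₂`, the size parameterization with equal-size reduction
`θ log((2n+θ)/(n+θ)) → θ log 2`. `overlap_mean` is restricted to `a > 0`:
at `a = 0` the printed formula degenerates to the plain arrival count `θb`,
which is not an overlap of previously arrived families. The replicate-
population scenario (two independent samples, `E V₂ ~ θ log n`) has no
simulator here. The specimen simulator draws each family's Yule birth times
with chunked exponentials (the event count grows like `e^horizon`).

## The cell-population model

Cells age for an exponential time with rate `λ` (default 1, fixing the time
unit) and then divide with probability `p` or die — an LBDP with rates `pλ`
and `(1−p)λ` per cell. Growth runs from a single founder until `N` cells are
alive at once; attempts that die out first are discarded (mean number of
attempts `p/(2p−1)`, the reciprocal survival probability; a cap of 10⁴
attempts guards the near-critical corner). The population is frozen at the
instant the `N`-th concurrent cell appears. A uniform sample of `n` cells is
drawn, its ancestry pruned and unary-suppressed with the stem retained, and
infinite-sites mutations are dropped per branch as Poisson(`θ · duration`).
Mutations on a branch with `d` sampled descendants contribute to `f_d`; stem
mutations have `d = n` (truncal). The SFS is condensed to
`(S, b₁..b₉, truncal)` where `b_k` is the proportion of mutations with sample
frequency in `((k−1)/10, k/10]`; `b₁₀` is derived and omitted because the
truncal count carries the top bin's information.

Open design points, decided as follows:

- **Mutation clock.** The default is per unit branch time, reading the
  infinite-sites rate as a time clock on the ancestral branches; a
  per-division clock (Poisson(`θ ×` divisions on the branch), division counts
  tracked through unary suppression) is available via `per_division=True`.
- **Stem.** Included by default (`include_stem=False` removes it), since an
  observation can legitimately contain zero truncal mutations either way.
- **Defaults `N = 1000`, `n = 100`.** `N` matches the inference example's
  population size; the sample size is not pinned down by the problem and 100
  is an arbitrary but realistic bulk-sample scale — both are plain config
  knobs, never hard-coded downstream.

## ABC with (distributional) random forests

The reference table pairs prior draws `(p, θ)` — uniform on `(0.5, 0.8)` and
`(10, 20)` — with simulated summary vectors. Crucially, a growth attempt that
dies out is discarded *together with its parameter draw*: the table's
realized `p`-marginal is the survival-conditioned prior, stochastically above
the nominal uniform, while the `θ`-marginal stays exactly uniform (survival
does not depend on `θ`). The conditioned `p`-marginal is reported alongside
the nominal prior rather than silently absorbed.

Three posterior constructions over table rows:

- **Rejection**: Euclidean distance on summaries standardized by table
  mean/sd (never by the observation — no leakage), uniform weights on the
  closest `⌈fraction·R⌉` rows.
- **ABC-RF**: a regression forest per scalar parameter.
- **ABC-DRF**: one forest with the bivariate response `(p, θ)`; responses are
  standardized and splits minimize summed variance reduction across
  components. This is a deliberate simplification of distributional
  splitting (kernel/MMD criteria); the part that defines the posterior — the
  leaf-weighting scheme — is implemented exactly: the weight of row `i` is
  the average over trees of `1{row i in the leaf containing the observation}
  / leaf size`, and the weights equip the joint empirical law of `(p, θ)`.

The forest is built here as bagged CART trees (scikit-learn
`DecisionTreeRegressor` base learners) with per-tree bag bookkeeping, because
the posterior weights, OOB error and permutation importance all need the
per-tree structure. Defaults: 500 trees, minimum leaf 5, `⌈d/3⌉` candidate
features per split — conventional regression-forest settings, stated so
results are reproducible; the forest hyperparameters are not dictated by the
method itself. Variable importance is out-of-bag permutation importance on
the standardized-response squared error. `posterior_report` produces
weighted means, medians, equal-tailed credible intervals, weighted-KDE
marginals, a 2-D weighted-KDE joint grid, and a Q–Q table for comparing two
posteriors.

## What the generators emulate — and what they do not

The synthetic data throughout are draws from the models themselves: the tests
establish internal consistency (simulators match the closed forms; the
inference machinery recovers parameters *of this simulator*). They do not
address model misspecification, sequencing noise, read-depth or detection
limits in real SFS data, copy-number events or selection, or non-Poisson
immigration — all outside the model class. Passing tests therefore validate
the mathematics and the implementation, not the fit of the model to any
particular biological dataset.

## Problem sizes and determinism

Distributional checks use 10⁴–10⁵ replicates (chi-square/KS at level 0.01,
moment checks at 3 standard errors); the ABC study uses a reference table of
R = 2000 rows, 200-tree forests, and 50 synthetic test observations — sizes
chosen so the full suite and the acceptance script each run in minutes on one
core while leaving the statistical conclusions unambiguous. Every stochastic
routine takes an explicit seed or `numpy` Generator; reference-table rows use
`SeedSequence.spawn` substreams so row `k` is reproducible in isolation.
Identical seeds give identical tables, ensembles, weights, and CLI output
bytes.

## Known limitations

- The complete-tree simulator is event-per-event Python; horizons with
  `e^{(λ−μ)t}` in the many thousands are slow (the direct reconstructed
  sampler avoids this entirely for conditioned trees).
- `read_newick` requires strictly binary trees with branch lengths on every
  edge; it is a dialect reader for this package's output, not a general
  phylogenetic parser.
- The DRF split criterion is the summed-variance simplification described
  above; posteriors for strongly multimodal joint laws may differ from a
  kernel-criterion DRF.
- Near-critical growth (`p → 1/2`) makes the conditioned cell model
  expensive; the attempt cap turns pathological rows into explicit errors
  (or, in table building, a fresh parameter draw).
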