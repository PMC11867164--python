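# File formats

All outputs are plain text; floats are serialized with 12 significant digits,
and re-parsing a written file reproduces the values exactly at that precision.

## Newick trees (`*.nwk`)

Single line, semicolon-terminated, branch lengths mandatory on every edge and
equal to branch **durations** in model time units. The root edge carries the
stem length (0 when the root splits at time 0), e.g. a two-tip ultrametric
tree of depth 1 with no stem:

    (1:1,2:1):0;

Tip labels are lineage numbers in order of creation. On read, absolute times
are reconstructed with the root at time 0; tips at the maximum depth (within
1e-9 relative) are marked observed, shallower tips dead. Only strictly binary
trees are accepted; polytomies and missing lengths are parse errors.

## CSV tables

Every CSV has a header row.

- `bdtree pmf`: columns `m,probability`; the truncated tail mass is logged to
  stderr.
- `bdtree immsim`: one row per replicate, columns `Z,F,C_1..C_max` (max over
  the replicates; shorter rows padded with zeros).
- `bdtree esf`: columns `c_1..c_n,probability`, one row per partition of n.
- `bdtree fisher`: one row with `theta,n1,n2,t1,t2,ev2_times,ev2_sizes`
  (+ `ev2_equal` when n1 = n2, + `ev2_mc,ev2_mc_se` with `--simulate`).
- `bdtree cellsim`: summary row `S,b1..b9,truncal`; with `--sfs-out`, the SFS
  as `j,f_j`.
- Reference tables (`bdtree abc build-table`): columns
  `p,theta,S,b1..b9,truncal,attempts`.
- Posteriors (`bdtree abc infer`): columns `row,<params...>,weight`; weights
  sum to 1.

## JSON

- `bdtree abc build-table --config sim.json`: object with optional keys
  `priors` (mapping parameter name to `[low, high]`), `target_size`,
  `sample_size`.
- `scripts/acceptance.py --out`: mapping of quantity name to
  `{"value": <number>, "n": <problem size>}`.

## Seeds

Every stochastic subcommand requires `--seed`; identical command lines give
byte-identical outputs. Reference-table rows use per-row substreams spawned
from the seed, so any row is reproducible in isolation.
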