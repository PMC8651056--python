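# Methods

## Model and semantics

A Boolean model is an ordered list of nodes, each a binary variable
with an optional logic rule and a pair of rate expressions. The
dynamics are a continuous-time Markov jump process on `{0,1}^n`: in
state `S` the propensity of node `i` is `rate_up_i(S)` if `S_i = 0` and
`rate_down_i(S)` if `S_i = 1`. Exactly one node changes per jump, so
the process realizes the asynchronous updating strategy with physical
time. A state with zero total propensity is a fixed point and absorbs
the trajectory.

Models imported from pure-logic formats (BoolNet, Boolean SBML-qual)
get rates derived from the rule: `rate_up = logic ? k_up : 0`,
`rate_down = logic ? 0 : k_down`, with `k_up = k_down = 1` so that one
time unit is one expected switching attempt. Explicit rates in `.bnd`
files take precedence over derived ones. Rates must evaluate finite and
non-negative on every visited state; division by zero or a negative
value aborts the simulation with the offending node and state named.
Both rates may be positive in the same state (spontaneous flipping);
that is legal dynamics, not an error.

Mutations are clamps. A knock-out forces the initial value to 0 and
replaces `rate_up` by the constant 0; a knock-in is symmetric. The node
therefore never leaves its forced value regardless of the logic, which
is the observable contract of KO/KI perturbations. Clamping was chosen
over rate re-weighting because it is exact, composable (double mutants
are two independent clamps; OFF+ON on one node is rejected at
validation), and independent of the magnitudes of the unperturbed
rates.

## Estimators

Ensemble statistics use windowed occupancy: `[0, max_time]` is split
into `time_points` equal windows and the probability of a (projected)
state in a window is the mean fraction of the window the trajectories
spend in it. This estimates the window-averaged transient law and has
no point-sampling bias at window edges. Node marginals are computed
from the projected-state table (sum of probabilities of states in which
the node is active), so the identity "marginal = sum of state
probabilities" holds exactly, not approximately. The last-state
distribution is the projected state at `max_time`; the fixed-point
table collects the full states in which trajectories were absorbed,
with their trajectory shares. If `max_time` is too short for the chain
to be absorbed, fixed points may be missed — the table reports what the
ensemble reached, and the exhaustive search (below) is the complete
reference for n ≤ 20.

Projected-state tables are sparse: only states actually observed get a
column, absent states implicitly have probability 0. Together with the
15-output cap this bounds memory on large models.

## Reproducibility

Each trajectory `t` draws from `PCG64(SeedSequence((seed, t)))`, so
results are bit-identical for a seed and independent of execution
order. Screens derive one seed per entry from the master seed and the
entry index the same way. The CLI writes `run_info.json` (tool version,
seed, resolved settings) with every run.

## Exact oracle

For n ≤ 12 the master equation is solved directly: the generator `Q`
has off-diagonal entries `Q[S, S⊕i] = r_i(S)` and diagonal `−R(S)`, and
`p(t) = expm(Q^T t) p0` is evaluated with SciPy's sparse
`expm_multiply`. This is an independent path to the transient law used
to validate the stochastic estimator (total-variation comparison at the
final-window midpoint; the window-averaging discrepancy is second-order
at near-stationary times). The Monte-Carlo floor of that comparison
scales as `N^{-1/2}` and, for a distribution spread over `m` states,
roughly as `Σ_s sqrt(2 p_s(1−p_s)/(πN))/2`: at `N = 10⁴` trajectories a
distribution diffused over most of the 64 states of a 6-node network
sits near TV ≈ 0.025, while mass concentrated on a few fixed points
gives TV ≤ 0.01. Comparisons on networks without fixed points should
therefore be read against that floor rather than as evidence of bias.

Exhaustive fixed-point search enumerates all `2^n` states (n ≤ 20) and
exits a state's propensity scan at the first positive rate, which makes
the average cost per state a small constant.

## Multi-valued conversion

A variable `v` with levels `0..m` becomes components `v_b1..v_bm`
(single-component variables keep their name) under the thermometer
encoding: level = number of active components, admissible states
satisfy `v_bj ⇒ v_b(j−1)`. The target level `F_v` is the source model's
function-term list evaluated with first-match semantics over levels
reconstructed from components. Component `j` activates only when
`F_v ≥ j` and `v_b(j−1)` is active; it deactivates only when `F_v < j`
and `v_b(j+1)` is inactive. Levels therefore move one step at a time
even when `F_v` jumps further — the standard stepwise-asynchronous
convention — and admissibility is invariant along trajectories. The
conversion is validated structurally: the Booleanized network's
asynchronous state-transition graph restricted to admissible states is
isomorphic, via the level projection, to the source model's ±1-step
graph (checked by brute force on the test models). Initial levels
translate to joint istate blocks (level k ⇒ first k components active
with probability 1). The component map is emitted as JSON next to
converted files.

## Fixtures: what they emulate and what they do not

The toys are desk-scale analytic stand-ins for curated signaling
models: the two-state node has a closed-form transient, the toggle
switch is the minimal bistable motif, the odd-ring repressilator is the
minimal fixed-point-free oscillator, and the multi-valued toy is the
minimal model with a level-2 target. Random N-K networks (k distinct
regulators per node, uniformly random truth tables written in
disjunctive normal form; degenerate all-false tables are written as a
contradiction over the regulators so the syntactic in-degree stays
exactly k) probe the engine on unstructured dynamics. None of these
reproduce the statistical structure of real regulatory networks —
degree heterogeneity, canalyzing rules, modularity — so passing tests
demonstrate correctness of the semantics and estimators, not biological
fidelity on any particular published model.

## Defaults and limits

- `sample_count = 10⁴`: brings binomial standard errors on state
  probabilities to ≤ 0.005, adequate for phenotype fractions filtered
  at coarse thresholds.
- `max_time = 10`, `time_points = 100`: with unit default rates, ten
  expected flips per node reach absorption in the small models shipped
  here; 100 windows is also the hard per-trajectory cap.
- Output nodes per simulation ≤ 15 and time points ≤ 100, enforced at
  configuration time, before any computation: the projected state space
  (`2^15` labels) and trajectory tables stay printable and storable.
- Initial states: per-node or joint ("istate") blocks, each block
  sampled atomically; uncovered nodes are Bernoulli(0.5) ("random"
  initial conditions). Block probabilities must sum to 1 within 1e−9.
- Phenotype filtering uses the last-state probability mass and a
  *strict* threshold (`> 0.35` excludes a mutant at exactly 0.35),
  matching the "more than X%" reading of phenotype queries.

## Design notes and limitations

- The expression grammar accepts both symbolic (`! & | ^`) and word
  (`NOT AND OR XOR`, case-insensitive) operators and serializes to the
  symbolic form; numeric literals other than 0/1, arithmetic and the
  ternary operator are rate-context only, which keeps logic rules
  exchangeable across formats. The `.bnd`/`.cfg` dialect implemented
  here is documented in `boolmc.io.maboss` and prioritizes round-trip
  fidelity over bit-compatibility with any particular external tool
  version.
- Interaction graphs use syntactic dependency (free variables of the
  rule, or of the rates when no rule exists); a vacuous reference still
  counts as an edge. This is deterministic and format-faithful but can
  over-count relative to a functional-dependency reading.
- SBML-qual support is import-only and covers the math subset
  and/or/not/xor over species–integer comparisons; sign and threshold
  attributes on transition inputs are ignored because the math is
  authoritative. GINsim models are consumed through their SBML-qual
  export; the native `.zginml` format is not parsed.
- Not implemented by design: limit-cycle detection,
  basin-of-attraction computation, rule-robustness analysis, entropy
  outputs, omics-based model personalization, and any client/server or
  web deployment machinery.
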