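# Methods

## Logical model and update scheme

The chemokine switch is modeled as a multi-valued logical network over six
variables: injury `I` (three-level input), latent intermediate `X` and `MIG`
(Boolean), and `MCP1`, `IP10`, `IL6` (three-level). Three-level variables
are represented by a low and a high bit; the *sum* of the bits gives the
level, so the decoder accepts the non-canonical pair (low=0, high=1) as
level 1, while the canonical encoding of level 1 is (low=1, high=0). One
synchronous step encodes the current levels canonically, evaluates every
rule on that previous state, and decodes the new bits by the sum rule. This
makes the level state the unit of dynamics: trajectories can be verified by
re-stepping, and the state space at fixed injury is exactly the
2·2·3·3·3 = 108 internal level combinations.

Updates are synchronous and deterministic. The biological reading is that
chemokine–cytokine interactions act through cell recruitment, signaling and
transcription, i.e. on comparable, slow timescales; asynchronous or
stochastic schemes (which would be needed if receptor-level competition
dominated) are deliberately out of scope. Input variables carry no rule;
clamping (used for the node-X experiments) overrides a variable's computed
level at chosen steps, with per-step schedules supported.

Step 0 is the initial state; "within the first k steps" means steps 1..k.
Because the successor map is a function, attractor analysis is exact: one
vectorized batch step over all 108 states yields the successor index of
every node, a functional-graph decomposition finds all terminal cycles and
times-to-attractor, and the pseudo-Kaplan–Meier curve is the fraction of
initial states with time-to-attractor > t, each state weighted equally.
Equal weighting replaces the original random-restart ensembles (reported
inconsistently as 500 or 1000 draws); exhaustive enumeration is a superset
of any such sample and removes Monte Carlo error entirely.

## The reference ruleset and the constraint suite

The shipped ruleset is a reconstruction, not a transcription: the primary
source for its behavior is a suite of twelve machine-checkable constraints
(B1–B10 required, B11–B12 soft), each an executable predicate decided by
exhaustive simulation in well under a second. Two design points were
genuinely open and were resolved in favor of required constraints:

- **No direct injury→MIG induction.** A direct term forces MIG on from the
  zero state under moderate injury, contradicting the required claim that
  only IP-10 responds there (B2). The induction reading survives only as a
  searchable alternative in the variant space.
- **MIG suppression reads IP-10 activity (low bit), not "IP-10 high and
  MCP-1 active".** The literal conjunction creates a second fixed point
  (MIG and MCP-1 jointly blockading IP-10), violating the
  one-attractor-per-severity requirement (B6).
- **IP-10 self-feedback is routed low↔high** (the low bit reads the high
  bit). A plain low-bit self-loop latches IP-10 after any transient X pulse,
  which would defeat the spike-vs-step discrimination (B9).

"Highest level" is read as level 2, "moderate/low level" as level 1/0 of a
three-level variable. B4 ("MCP-1 never attains its highest level under
moderate injury") is asserted at every step ≥ 1 along every orbit including
the recurring attractor states; initial conditions themselves are
unconstrained, since the ensemble deliberately includes MCP1 = 2 starts.
Attractor uniqueness is asserted for moderate and severe only: under mild
injury the IP-10 self-loop can sustain nonzero states from nonzero starts,
and the steady-state analysis contrasts only moderate vs severe.

## Ruleset-space uncertainty search

The variant space fixes the topology (who regulates whom, per target bit)
and permutes the logic realizing it. Rules are first normalized to negation
normal form, so group negations such as `not (MIG and MCP1_low)` become
per-literal signs; the free choices are then per-leaf sign
(activating/inhibiting), per-leaf threshold (`>= 1` vs `== 2`) for
three-level regulators, and AND/OR at each internal connective. This
definition guarantees the reference ruleset is a member of its own space.
A same-sign-group normal form (one combiner over activators AND NOT one
over inhibitors) was considered and rejected: it provably cannot express
the MCP-1 activity rule, whose severe-injury term must override the
IP-10-high inhibition for MCP-1 to persist under severe injury (B5).

Scoring is lexicographic — required constraints passed, then soft
constraints, then mean absolute level distance of the zero-init moderate
and severe trajectories from the reference — because qualitative behavior
arbitrates first and trajectory match second. The full product space over
all eight target bits is astronomically large (~10^13 with all freedoms),
so exhaustive certification uses the switch-core subspace: signs and
connectives of the three core rules (`IP10_high`, `MCP1_low`, `MCP1_high`),
32 768 variants, everything else held at the reference. In that space eight
variants satisfy all ten required constraints and four tie at the top score
(10 required, 2 soft, distance 0), the reference among them — the logic is
tightly, but not uniquely, determined by the constraints. Larger spaces are
explored by seeded uniform subsampling without replacement.

## Synthetic cohort generator

The generator emulates the study design the pipeline targets, not any
particular dataset: three injury groups of 48/47/47 patients, a small
healthy-baseline group, and serial sampling at 0, 8, 16, 24 h then daily
through 168 h. One synchronous model step represents 8 h, so steps 1–3 span
the first day and step 21 is day 7. The admission (0 h) sample is included
so that "first-sample MCP-1" reflects the patient's initial condition — the
quantity the low-MCP-1 subgroup (< 1000 pg/ml) is defined on.

Each patient draws an initial level state uniformly from the 108
combinations, simulates the reference model at their injury level, and maps
level ℓ of mediator m to `baseline_m · fold_m^ℓ · exp(ε)`,
ε ~ N(0, σ²) i.i.d. per sample — multiplicative lognormal noise, because
plasma immunoassay concentrations are positive and right-skewed. Defaults
(σ = 0.3; MCP-1 baseline 100 pg/ml, fold 6; IL-6 5×10; MIG 200×5; IP-10
150×5; IFN-γ 10×4) are declared stand-ins chosen so that the MCP-1 levels
straddle the 1000/1500 pg/ml clinical strata (level 1 → 600, level 2 →
3600 pg/ml); they are not fitted estimates. IFN-γ reports the latent node X
(its clinical surrogate); three bystander channels (IL-8, TNF-α, eotaxin)
are baseline noise only, giving network inference true-negative edges.
Mild patients run at injury level 0, since induction is attributed to
moderate/severe injury only. Per-patient seeds are spawned from the master
seed, so cohorts are reproducible and order-insensitive.

What the generator does *not* emulate: missing visits and irregular
per-patient schedules, assay floors/ceilings and batch effects,
between-patient parameter heterogeneity, the full 24-mediator panel, and
clinical outcomes. Passing recovery tests therefore show that the inference
stack works when its modeling assumptions hold approximately — not that it
would perform identically on real Luminex panels.

## Dynamic-network inference

The inference stage is a stationary first-order dynamic Bayesian network:
one network per injury group, lagged parents only, self-edges allowed, no
acyclicity constraint (a changepoint/inhomogeneous process is explicitly
out of scope, since the object of interest is a single consensus network
per group). Values are log-transformed (the data are lognormal-like) and
z-scored per mediator over all patient-time cells; samples are assigned to
the nearest grid slot, transitions pair consecutive slots and never span
patients, and the uneven spacing of the clinical grid (8 h early, 24 h
late) is treated as a uniform slot sequence — a documented caveat, not a
modeled feature.

Local scores use the BGe marginal likelihood with the Geiger–Heckerman
subset formula on the stacked vector (parents at t, target at t+1):
zero prior mean, α_μ = 1, α_w = d + 2, prior scale T = cI with
c = α_μ(α_w − d − 1)/(α_μ + 1), and degrees of freedom shifted by
α_w − d + l for an l-column block (d = number of mediators). This yields
score equivalence — Markov-equivalent structures score identically — which
the tests assert on a three-variable static embedding, and the closed form
is verified against brute-force numerical integration (2-D quadrature over
(μ, τ) for one column; Bartlett-factor quadrature over the 2×2 Wishart for
two columns) to |Δlog| ≤ 1e−4.

Structures are sampled by Metropolis–Hastings over single-edge toggles,
uniform over feasible moves with a fan-in cap of 3, uniform structure
prior, burn-in 20 % of the chain by default; the proposal asymmetry at the
fan-in boundary is corrected by the feasible-move-count ratio. Because the
uniform prior factorizes over targets, small problems admit exact
enumeration of the posterior, which the tests use as the sampler's
correctness oracle (agreement within 0.05 at 50 000 sweeps on a
two-mediator problem). Consensus networks keep edges at posterior frequency
≥ 0.5 (closed threshold).

Recovery is benchmarked on severe-injury cohorts (richest dynamics;
inference is per-group): positives are the six lagged edges the generator
realizes (chemokine self-edges, IFN-γ→IP-10, MCP-1/MIG→IL-6), negatives are
bystander-incident edges, and AUROC uses posterior frequencies with midrank
ties. At the default noise (σ = 0.3, n = 90, seeds 1–5) mean AUROC is
≈ 0.93. One caveat: at that noise level recovery is near ceiling for both
n = 30 and n = 90, so the benefit of cohort size is demonstrated at
σ = 1.2, where it is measurable (mean AUROC ≈ 0.80 → 0.88).

## Numerical and degenerate-input conventions

- Fixed-point detection compares consecutive states; cycles are detected by
  first repeat of a full state. Constraints that require settling fail
  explicitly (with the counterexample) on cycling candidates.
- Ensemble SE uses the sample standard deviation (ddof = 1) over √n, zero
  for singleton groups; identical members give SE exactly 0.
- Ties in the consensus threshold are included; ties in ranking metrics use
  midranks; search rankings break score ties by variant id for stability.
- Empty cohorts, empty suites, zero-budget searches, sub-minimal clamp
  profiles and off-grid sample times are rejected with specific errors;
  a cohort mediator that is constant across all cells cannot be z-scored
  and raises rather than silently producing NaNs.
- `align_panel` drops patients with fewer than two usable slots (with a
  warning), mirroring the study's minimum of three samples per patient.

## Problem sizes

All logical-model analyses are exhaustive over the 108-state space and run
in milliseconds. The certification search covers the 32 768-variant core
subspace. Inference experiments use cohorts of 30–90 patients, 10 grid
slots, 8 mediators, and chains of 6 000–50 000 sweeps; these sizes keep any
single analysis in the minutes range on one CPU while leaving the
statistical conclusions unchanged under larger chains.
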