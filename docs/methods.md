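# Methods

This note records the model definitions, conventions and design choices
behind `temponet`, at the level of detail a user needs to interpret results
or reproduce them elsewhere.

## Contact sequences

A contact sequence is an ordered multiset of triples (i, j, t): undirected
contacts at discrete integer times. On construction the time origin is
shifted so the first contact is at t = 0; T is then the time of the last
contact. Vertex labels are opaque strings mapped to dense indices; storage is
canonicalised entirely in label space (pair orientation and the order of
contacts sharing a timestep follow label order), so any reordering or
reorientation of input rows yields the identical object and — because the SIR
engine keys its RNG streams by label — identical simulation output.
Real-valued timestamps are rejected rather than rounded: silently coarsening
time would change tie structure, which the SIR tie-shuffling rule makes
meaningful. Identical duplicate rows are kept; several contacts between one
pair in one timestep are legal and are shuffled like any other ties.

**Burstiness.** For every pair with ≥ 2 contacts the successive gaps are
pooled into one series; the burstiness of the data is reported, by default,
as the normalised dispersion B = (σ − m)/(σ + m) of that series — bounded in
[−1, 1], zero for Poissonian gaps, −1 for periodic ones. The raw coefficient
of variation σ/m is available as `mode="cv"`. The normalised form is the
default because it is the standard burstiness index for heavy-tailed human
interevent statistics and stays finite on them; empirical contact data sets
typically land around B ≈ 0.4–0.65.

## Static representations

All outputs are simple undirected graphs containing only vertices incident to
a representation edge; how missing vertices enter downstream correlations is
an evaluation-stage decision (below).

- *Time slice*: edge iff a contact falls in the **closed** window
  [t_start, t_stop]. The full window is the accumulated network.
- *Ongoing*: edge iff contacts exist **strictly** before t_start and strictly
  after t_stop. Closed versus strict endpoints differ between the two
  definitions on purpose; they follow the definitions of the window as,
  respectively, an observation interval and a gap to be straddled.
- *Exponential threshold*: wᵢⱼ = Σ e^(−t/τ) over the pair's contacts, t from
  the data's first contact; edge iff wᵢⱼ > Ω (strict — "exceeds"). Limit
  identities used in tests therefore place Ω at half-integers (τ ≫ T,
  Ω = n − ½ ⇒ pairs with ≥ n contacts), avoiding float-equality fragility.

## SIR on the contact sequence

Parameters: per-contact transmission probability λ ∈ [0, 1], infective
duration δ > 0 (native time units), RNG seed. Contacts are processed in time
order; contacts sharing a timestep are re-shuffled uniformly every run. A
vertex infected at t₀ is infective on the half-open interval [t₀, t₀ + δ) —
a contact exactly at t₀ + δ does not transmit (any boundary convention is
defensible; half-open avoids double-counting). A vertex infected mid-timestep
can transmit at contacts later in that timestep's sampled order.

The seed becomes infective immediately *before* its own first contact, so
that contact can transmit. The alternative (activation after the first
contact) would make every vertex whose only contact is its first a guaranteed
dead end and degenerate the importance ranking.

σᵢ is the Monte-Carlo mean outbreak size over n_runs independent runs seeded
at i (default 1,000), with the run-level sizes retained so rank-correlation
standard errors can be bootstrapped without re-simulation. Given the same
seed the whole table is bit-reproducible.

**Calibration.** δ defaults to T/5. λ is chosen so that the all-seed average
outbreak size equals a target fraction (default 1/5) of its λ = 1 value, by
bisection on λ — the mean outbreak is non-decreasing in λ, and matched RNG
streams across evaluations keep the response smooth. Tolerance 0.01 on the
fraction, 30 iterations cap; a target below the λ = 0 floor (mean size 1)
raises a calibration error reporting the bracket. The reference average is
taken over *all* seeds (not random ones), which is deterministic in
expectation and uses the same machinery as the importance table.

## Evaluation

ρ is the Spearman rank correlation (mid-ranks for ties; computed via
`scipy.stats.spearmanr`) between σᵢ and the static predictor — degree or
coreness — across **all vertices of the original data**. Vertices absent from
the derived network get predictor value 0: they exist in the data and have
σᵢ ≥ 1, and dropping them would make ρ incomparable across representations
with different vertex sets. Constant vectors (e.g. an edgeless window) make ρ
undefined; scans record such points as missing rows rather than dropping
them, and fail only if every point is undefined.

Default grids echo the natural axes: a triangular n × n grid (n = 21) of
(t_start, t_stop) fractions of T for window representations, and 16
log-spaced τ/T ∈ [10⁻², 10] × 16 log-spaced Ω values for the exponential
threshold. The standard error of ρ_max is a nonparametric bootstrap (200
resamples by default) over each vertex's run-level outbreak sizes; per-point
surface errors are available but off by default since they multiply the cost
by the grid size.

## Synthetic generator

The generator emulates heavy-tailed, bursty human contact data with tunable
concurrency, in three stages:

1. **Degrees and topology.** Degrees are i.i.d. truncated power-law integers
   on [k_min, k_max] (defaults 1 and N−1, exponent γ = 2.2, N = 5,000):
   a continuous variate with density ∝ x^(−γ) on [k_min, k_max+1) is drawn by
   inverse transform and floored, giving
   P(k) ∝ k^(1−γ) − (k+1)^(1−γ) ~ k^(−γ). The fully discrete zeta form has a
   markedly lighter tail at these exponents and does not reproduce the edge
   counts this generator is built to hit (the realized mean M ≈ 1.06 × 10⁴ at
   defaults; the discrete form gives ≈ 0.73 × 10⁴). Stub matching draws two
   remaining stubs uniformly, rejecting self- and multi-edges; after 10⁴
   *consecutive* failures (counter reset on success) the remaining stubs are
   deleted — a logged event, not an error. Realized degrees are pointwise ≤
   drawn degrees.
2. **Activity intervals.** Each edge is active on one interval of duration
   exactly μT with start uniform on [0, (1−μ)T]. μ ∈ (0, 1] is the overlap
   (concurrency) control: μ = 1 makes all partnerships concurrent. The
   package default is μ = 0.5, the middle of the interesting range. Skewed
   interval durations are deliberately not modelled — they would confound the
   single overlap control.
3. **Contact times.** L = 10 M contacts in total (configurable
   `contacts_per_edge`). Every edge gets one contact plus a multinomial
   share of the remaining L − M, so the total is exact and every edge of the
   topology appears in the sequence. Per edge, interevent gaps are i.i.d.
   truncated power-law integers (β = 2 on [1, 10⁴], same sampler as degrees),
   accumulated into a time series and mapped affinely onto the edge's
   interval, rounded to integer timesteps (coincident rounded times are kept
   as distinct contacts; a single-contact edge places its contact uniformly).
   The affine per-edge rescaling preserves the bursty within-edge profile
   while honouring both the contact budget and interval confinement; the
   alternative reading — splitting one global gap series sequentially across
   intervals — would couple an edge's contact count to its interval length
   and break the exact L = 10 M accounting.

Defaults: T = 10⁵ timesteps, sized so a μ = 1 interval accommodates the mean
total gap of a 10-contact edge. Generation is deterministic given the seed,
to the byte, including the emitted contact file.

**What the generator does not emulate:** correlations between topology and
temporal structure (none are induced by construction), skewed interval
durations, vertex-level (as opposed to edge-level) activity rhythms, and
real-world sampling artefacts. Tests passing on synthetic data therefore
demonstrate correctness of the machinery and qualitative behaviour
(e.g. which representation wins and roughly where its optimum sits), not
quantitative transfer to any empirical data set.

## Null model and diagnostics

S is the largest-component fraction of the derived network's own vertex set;
d the mean shortest-path length over unordered pairs within that component.
The null model goes sequentially through all edge positions; for edge (i, j)
it draws a random partner (i′, j′) and applies one of the two degree-
preserving replacements — (i, j′),(i′, j) or (i, i′),(j, j′) — with equal
probability, redrawing on self-edges, duplicates, or identity replacements.
After 10⁴ failed draws for one position the edge is kept in place (strict
mode raises instead); rigid graphs such as K_n therefore map to themselves
with zero null variance, which is the correct degenerate answer. Null means
S₀, d₀ use 10⁴ randomizations by default (tunable; desk-scale work uses
10²). Note the sequential pass is deterministic on very small rigid-ish
graphs (on a 4-cycle each position admits exactly one valid swap); genuine
randomisation needs a configuration space with choice, which any realistic
network has.

## Problem sizes used in the shipped tests and scripts

The test suite runs oracle equivalences on hundreds of small random fixtures
(≤ 50 vertices; exhaustive enumeration on ≤ 6 contacts), the planted-recovery
scan on a ~210-vertex sequence with 200 runs per seed, and the generator
edge-count check at full scale (N = 5,000, 100 instances). The acceptance
script uses the same full-scale generator run. These sizes were chosen so the
whole suite completes in about a minute while every stochastic check retains
a ≥ 3-standard-error margin.
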