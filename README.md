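# temponet

**Distilling temporal contact data into static networks for epidemiology.**

Contact data — who met whom, and when — is increasingly recorded with
timestamps: sexual-contact surveys, hospital proximity sensors, e-mail logs.
Most of network epidemiology, however, runs on *static* graphs. Collapsing
the timestamped contacts into a single graph throws information away, and how
you collapse matters: an edge that was active years before an outbreak should
not count the same as one active yesterday.

`temponet` is a toolkit for choosing that collapse well. It is written for
infectious-disease modellers and temporal-network researchers who want to
know, for a given contact sequence, *which static representation best
preserves epidemiological structure* — and at which parameters.

## What it computes

A contact sequence is a list of triples (i, j, t): an undirected contact
between vertices i and j at discrete time t, with time counted from the first
contact and total sampling time T.

**Ground truth.** A stochastic SIR process runs directly on the contacts:
seeding at vertex i's first contact, each contact between an infective and a
susceptible transmits with probability λ, and an individual infected at t₀ is
infective during [t₀, t₀+δ). The expected outbreak size σᵢ over many runs
(typically 10³) measures vertex i's true spreading importance. By default
δ = T/5 and λ is calibrated so the mean outbreak is one fifth of its λ = 1
size — an intermediate regime that separates important from unimportant
spreaders.

**Static representations.** Three parameterized reductions to a simple graph:

- *time slice*: edge iff the pair has a contact with t_start ≤ t ≤ t_stop;
  the full window [0, T] is the *accumulated* (aggregated) network;
- *ongoing*: edge iff the pair has contacts strictly before t_start **and**
  strictly after t_stop — partnerships that straddle the window
  (concurrency, in STI terminology);
- *exponential threshold*: each contact adds weight e^(−t/τ) to its pair; edge
  iff the total weight wᵢⱼ exceeds a threshold Ω. As τ → ∞ the weight tends to
  the pair's contact count, so Ω = n − ½ keeps pairs with ≥ n contacts.

**Score.** A representation is good if a cheap static predictor — degree kᵢ
or coreness cᵢ of the derived graph — ranks vertices like σᵢ does. The score
is the Spearman rank correlation ρ(σ, k), computed over *all* vertices of the
original data (vertices absent from the derived graph enter with predictor 0).
`scan` maximizes ρ over a parameter grid and reports ρ_max, the argmax and a
bootstrap standard error.

Also included: a synthetic generator (configuration-model topology with
truncated power-law degrees, per-edge activity intervals of duration μT
controlling concurrency, bursty truncated power-law interevent times,
10 contacts per edge on average), temporal statistics (burstiness
B = (σ−m)/(σ+m) of the pooled interevent times), and static diagnostics
(largest-component fraction S, mean distance d, and a degree-preserving
edge-swap null model giving S₀, d₀).

## Worked example

`examples/compare_representations.py` generates a 200-vertex synthetic
sequence, calibrates λ, estimates σᵢ (300 runs per seed) and scans all
representations:

```
synthetic data: N=200 M=340 L=3400 T=19974
calibrated lambda = 0.1172 (target: mean outbreak = 1/5 of lambda=1)

accumulated network:        rho = 0.447
time_slice                  rho_max = 0.487 +/- 0.007 at window [0.20, 0.40] T
ongoing                     rho_max = 0.457 +/- 0.006 at window [0.40, 0.40] T
exponential threshold       rho_max = 0.537 +/- 0.006 at tau = 0.398 T, Omega = 2.51
```

Read: accumulating *all* contacts scores ρ = 0.447 — discarding timing costs
real predictive power. An optimally windowed time slice does better (0.487),
and the exponential-threshold network, which discounts old contacts smoothly,
does best (0.537 at τ ≈ 0.4 T). The ongoing (concurrency) network barely
beats accumulation. Higher ρ_max = a static picture whose degrees better
identify the individuals who would actually spread an infection.

The other examples (`generate_contacts.py`, `outbreak_importance.py`,
`network_diagnostics.py`) each exercise one capability and print a short
annotated result.

A thin CLI wraps the same library: `temponet generate | represent |
simulate | calibrate | scan | stats` (every run writes a YAML config echo;
grid times are fractions of T by default).

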