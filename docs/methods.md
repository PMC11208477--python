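# Methods

`ojipscreen` couples a Morris elementary-effects screening engine to a
mass-action kinetic model of the photosynthetic electron transport
chain whose observable is the rapid chlorophyll-*a* fluorescence rise
(the O-J-I-P transient). This note records the model, the numerical
choices, the places where the design was genuinely open, and what the
synthetic data do and do not establish.

## Morris screening on time-resolved outputs

A screening run perturbs k rate constants on a discretised unit grid
{0, 1/(p−1), …, 1} (p = 4 levels by default, grid step Δ = (p−2)/(p−1)
= 2/3; at p = 2 the step degenerates and Δ defaults to 1). A
*trajectory* is a sequence of k+1 parameter vectors in which
consecutive points differ in exactly one factor by ±Δ, built from a
random base point via the randomised construction
B* = (J X* + (Δ/2)[(2B − J)D* + J])P* with a ±1 diagonal D* and a
random permutation P*. Two deliberate departures from the canonical
Morris scheme, both needed to reproduce the reference worked example:

* **Base points are drawn from all p levels**, not only levels ≤ 1−Δ.
  A +Δ step from level 1 therefore overshoots the nominal interval,
  and the affine map to rate constants, v = v0(1−s) + u·2sv0 for scale
  fraction s, extrapolates linearly (unit level 5/3 at s = 0.2 maps to
  1.467·v0).
* **The elementary-effect denominator is the signed unit step**, so
  EE_i(t) = [f(row after) − f(row before)]/(±Δ) estimates the
  unit-space directional derivative regardless of step direction. The
  canonical |Δ| convention and a real-space denominator are available
  as options (`denominator=` in `elementary_effects`).

Because the model output is a full time series F(t), each EE is a time
series too. The default aggregation is two-stage: EEs are averaged
over the m trajectories at each time point, giving ē_i(t); then
μ_i = mean_t ē_i(t), μ*_i = mean_t |ē_i(t)|, and σ_i = sample standard
deviation (n−1) of ē_i(t) across time points. σ is computed on ē_i(t),
not |ē_i(t)|; a pooled alternative (all trajectory×time EEs as one
sample) is selectable and never silently mixed with the default.
Ranking uses μ* descending, with ties broken by σ descending and then
name — σ otherwise never affects ranks. m = 4 trajectories is the
default. One seeded generator is threaded through base point, D* and
P* draws in that fixed order, so a seed fully determines a run.

## The worked two-ODE example

dx1/dt = a·x1 + b·x2, dx2/dt = a·x1 − b·x2 with x1(0) = x2(0) = 1,
output y = x1 + x2 on [0, 1] s, a = b = 5 screened at ±20%, p = 4,
Δ = 2/3. Four fixed reference trajectories (unit levels
{0, 1/3, 2/3, 1, 4/3, 5/3}) make the computation deterministic. The
coefficient matrix has eigenvalues ±√(a² + b² … ) with a positive
branch ≈ √(2ab) ≈ 7.07 s⁻¹, so y and all EEs grow roughly
exponentially and the time aggregation is dominated by late times.

The output grid density matters for the aggregated measures because the
integrand grows exponentially. The default is **301 uniform points on
[0, 1] s**, chosen by calibrating the unstated grid against the
reference values of the example; at that density the package computes
μ*(a) = 1909.7, σ(a) = 3836.9, μ*(b) = 156.1. The fourth reference
value (σ(b) = 230) is not reproduced — every defensible σ convention
(two-stage/pooled, n vs n−1, per-trajectory, per-time-point, trapezoid
weighting) and every grid density from 50 to 2000 points yields
σ(b) ≈ 294–300 while leaving the other three measures matched to ~1%,
and since all EEs of this example are positive, sign conventions
cannot move it. We treat that reference value as anomalous and report
our computed value; the acceptance test for it is expected to fail and
is left failing rather than loosened.

The closed-form matrix-exponential solution is kept alongside the
numerical integration purely as an independent oracle in the tests.

## The electron-transport-chain model

43 state variables, factorised as: PSII 12 microstates
(P680 × Q_A × Q_B = 2×2×3), OEC 4 (S0–S3), PQ pool 3 (PQ, PQ⁻, PQH2),
cytochrome b6/f 12 (f × b_L × b_H = 2×2×3), Pc 2, PSI 4 (P700 × F_B),
Fd 2, FNR 4 (inactive, active oxidised, singly, doubly reduced). This
factorisation is a **reconstruction**: it reproduces the published
variable count and instantiates every tabulated reaction (18 forward,
14 backward rate-constant families, 116 elementary transitions), but
the source model's exact state decomposition, fluorescence weights and
dark splits are not published, so curve shapes match only
qualitatively. That is also why the screening orderings beyond the
headline positions are not expected to coincide with the published
tables.

Kinetic conventions:

* intra-complex steps are first order in the complex microstate;
* complex↔pool steps are second order with the pool fraction
  normalised by the pool total (flux = k·[complex]·[pool]/pool_total),
  keeping every constant in s⁻¹;
* the OEC↔P680⁺ coupling is a pool-level bimolecular approximation,
  the flux distributed over P680⁺ substates in proportion to their
  population (the exact joint treatment would need the unpublished
  96-state donor-side space);
* protons appear only stoichiometrically; the lumen is treated as
  buffered;
* the Q_B-site plastoquinone exchange (k8f/k8b) runs **only in open
  (Q_A-oxidised) centres by default**, exactly as the reaction is
  written (Q_A Q_B²⁻ + PQ → Q_A Q_B + PQH2). This gating is also what
  produces a distinct I plateau in the simulated transient; the
  Q_A-independent variant is available (`k8_both_qa_states=True`) and
  yields curves without a detectable I step;
* photochemical constants k1f, k1b, k15f, k15b scale linearly with
  photon flux density relative to the reference PFD 3255
  photons m⁻² s⁻¹ (the tabulated values); "low light" is PFD 325.5,
  i.e. one tenth.

Parameters not fixed by the published tables, with defaults and
rationale (all configurable):

| parameter | default | rationale |
|---|---|---|
| PQ pool size | 6 per PSII | typical thylakoid PQ/PSII stoichiometry |
| Pc, Fd totals | 2, 2 per PSII | typical carrier stoichiometries |
| FNR total | 1 per PSII | one terminal complex per chain |
| dark S1:S0 | 0.75:0.25 | standard dark-adapted S-state mix |
| dark Q_B:Q_B⁻ | 0.5:0.5 | standard two-electron-gate dark split |
| φ_open, φ_closed | 1, 5 | F_M/F_0 ≈ 5 with Q_A as the quencher |
| γ_PQ | 0.3 | moderate quenching by oxidised PQ |
| FNR state | active, no activation/sink | k18f ranks low either way |

Fluorescence: F = [φ_open·(Q_A-ox fraction) + φ_closed·(Q_A-red
fraction)]·(1 − γ_PQ·PQ_ox/PQ_total), with an optional P680⁺ quenching
factor (off by default).

The dark-adapted initial state has Q_A fully oxidised (the definition
of the O level). With the default Q_B⁻ split this is not an exact dark
steady state: k6b shuttles a small fraction (k6b/(k6f+k6b) of the
one-electron pool, ≈ 2.4% of PSII) onto Q_A within ~0.3 ms at zero
light. The dark-equilibrium fluorescence is therefore known in closed
form and is used as a test oracle; with the Q_B pool fully oxidised,
darkness gives exactly constant F.

Integration: LSODA with rtol 1e-8, atol 1e-10, output on 60 log-spaced
points per decade over [1e-5, 1] s. A reduced mode (20 points per
decade, rtol 1e-6) exists for quick runs; a full 19-simulation
trajectory set completes in seconds either way. Integrator failures
are reported together with the rate-constant set that caused them.

## O-J-I-P feature detection

F_P is the global maximum of F. J and I are plateau features: interior
local minima of dF/dlog10(t) inside search windows (0.3, 10) ms and
(10, 100) ms, accepted only if their prominence exceeds 2% of the
slope range in the window (guarding against solver ripple); windows
with no qualifying dip report the feature as undetected. t_P is the
argmax time when the maximum is interior; on curves that only
saturate, the literal argmax would sit wherever numerical noise puts
it on the terminal plateau, so t_P is instead placed at the dominant
inflection of the final rise (the largest slope maximum after the last
detected plateau), falling back to the final grid point when the slope
still grows at the end.

Under defaults the intense-light simulation shows t_J ≈ 0.7 ms,
t_I ≈ 29 ms, t_P ≈ 100 ms — inside order-of-magnitude windows around
the canonical ~2/~20/~200 ms landmarks — and the low-light simulation
loses the I feature, as observed experimentally.

## Screening pipeline

A forward screening run is m trajectories × 19 simulations (backward:
15). EEs are computed on F(t) only (a hook allows any species
trajectory via the simulation result). Curve ensembles per trajectory
are exported with 5th/50th/95th percentile envelopes (linear
interpolation between order statistics); EE time courses default to
the fourth trajectory, the conventional choice for the time-course
figures. Rank comparisons between conditions use Spearman correlation
of μ*-ranks plus per-parameter rank shifts. The 30% scale is accepted
for any group/light combination but is only conventionally meaningful
for forward constants under low light. Seeds are recorded in the run
manifest; nothing is shared implicitly between scales or light
regimes.

## Synthetic pseudo-experimental curves

The generator emulates measured O-J-I-P traces as a sum of three
logistic steps in log10(t) with amplitudes (F_J−F_O), (F_I−F_J),
(F_P−F_I), multiplicative Gaussian noise (relative error, reflecting
fluorometer behaviour; additive noise also exposed), and log-spaced
sampling. The times t_J, t_I, t_P are interpreted as **feature times
in the detector's sense** (plateau dips and final-rise inflection).
For a sum of logistics the plateau dips fall near the geometric means
of consecutive step centres, not at the centres themselves, so the
generator solves for centres by a fixed-point iteration on the
noiseless curve until the features land at the requested times; step
widths default to (0.10, 0.15, 0.25) decades. The round trip
generator → detector then recovers the requested times by
construction whenever features are about a decade apart.

What the synthetic curves do not emulate: instrument-specific gain and
saturation, the finite rise time of the excitation light, temperature
or sample heterogeneity, and any connection between curve shape and
underlying rate constants. Tests passing on synthetic curves establish
the plumbing (sampling, noise handling, feature detection), not model
fidelity to real leaves.

## Known limitations

* The ETC model is a documented reconstruction; only structural counts
  and qualitative O-J-I-P phenomenology are expected to match the
  source it emulates, and screening orderings below the headline
  positions are reconstruction-dependent.
* The fluorescence observable ignores PSI fluorescence and
  nonphotochemical quenching.
* 820-nm transmittance, inhibitor treatments (DCMU-like blocks are
  possible by zeroing constants, but DBMIB/MV chemistry is not
  modelled), electric-field effects and downstream carbon metabolism
  are out of scope.
* The σ(b) reference value of the worked example could not be
  reproduced under any aggregation convention tried; see the worked
  example section.
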