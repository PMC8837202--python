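# Methods

This note records the models implemented in `forcejump`, the parameter
choices that matter, what the simulator does and does not emulate, and the
numerical decisions taken where the design was genuinely open.

## Mechanical circuit

All elastic elements are worm-like chains under the interpolation formula

    F(x) = (kBT/Lp) * [ 1/4 (1 - x/Lc)^-2 - 1/4 + x/Lc ],

with persistence length Lp = 1 nm for ssDNA, contour length 0.59 nm per
nucleotide, and kBT = 4.09 pN·nm (296 K; the assay runs at 23 °C).  No
higher-order (Bouchiat-style) correction terms are used — the plain
interpolation formula is the model whose output the rest of the analysis
consumes, and adding terms would change Δx predictions by more than the
solver error.

The bound tether is two springs in parallel: the ssDNA bridge (55 or 70 nt)
and the loading path (24 nt of ssDNA in series with an inextensible 8 nm
protein pair).  Because the proteins sit only on the loading path, the
bridge is pre-stretched by L_prot = 8 nm relative to the loading strand
extension x:

    bound:    F_Tot = F_Load(x) + F_Bridge(x + L_prot)
    unbound:  F_Tot = F_Bridge(x + L_prot)

`solve_bound_state` finds x by Brent root finding on the summed (strictly
increasing) force–extension curve, bracketed on [0, 0.999·Lc_loading],
absolute tolerance 1e−9 nm; monotonicity guarantees uniqueness.  Contour
lengths come from nucleotide counts only (no end-group corrections).

**Slack handling.** The equations say nothing about x < 0.  We treat
extensions below zero as slack with zero force (an entropic strand cannot
push): when the pre-stretched bridge alone carries more than F_Tot at
x = 0 — below ≈1.8 pN (55 nt) or ≈1.3 pN (70 nt) — the bound state
degenerates to the unbound geometry with F_Load = 0 and Δx = 0.  This
matches the assay's relaxed low-force state, where the partners can meet
and bind.

Predicted step: Δx(F_Tot) = x_unbound − x_bound at equal total force.  At
6 pN this gives 4.77 nm (55 nt) and 8.66 nm (70 nt); the longer bridge is
the softer force divider, so it leaves more force on the proteins and
steps farther on rupture.

## Event detection

Each high-force plateau is analyzed independently:

1. **Centering** — subtract the mean of the first five samples.
2. **Noise scale** — eSD = median of all 10-sample sliding-window standard
   deviations.  The median makes the estimate robust to the single step a
   plateau may contain (for iid Gaussian noise the estimator's median is
   ≈0.97 σ).  A floor of 1e−9 nm keeps noiseless synthetic traces
   decodable.
3. **Decoding** — a two-state hidden Markov chain with Gaussian emitters
   at 0 and +4 eSD (SD 1 eSD each), initial state bound, transitions only
   bound→unbound with per-sample probability p_trans, decoded by Viterbi.
   The chain is exactly a single-changepoint model, which the tests
   exploit: the decoder must agree sample-for-sample with an exhaustive
   scan over all candidate changepoints.
4. **Extraction** — lifetime τ = (changepoint index)/200 Hz, i.e. the
   duration preceding the state change; Δx = difference in means over an
   equal number of samples (the binding duration, clipped to what is
   available) before and after the changepoint.  Events shorter than four
   samples (20 ms) are rejected.

**Transition probability.** The per-sample bound→unbound probability is
not a physical constant of the analysis; it sets the detection threshold,
not the changepoint location, for well-separated levels.  Default
p_trans = 1e−3 (log penalty ≈ −6.9); tests verify the decoded location is
unchanged over p_trans ∈ [1e−5, 1e−2] for ≥3.5 eSD steps.

**Emitter centers** are fixed at +4 eSD regardless of the true step, as in
the assay convention; Δx is re-estimated from sample means afterwards, so
a mis-specified center biases only sensitivity, not the reported step.

**Drift and curation screens.** Recorded traces were manually inspected;
we replace that with three declared, reproducible screens:

- *Post-rupture slope*: events whose post-changepoint linear slope exceeds
  2 eSD/s are truncated to a ±0.5 s window around the jump and re-decoded;
  if the slope survives truncation the event is rejected.
- *Step-vs-ramp*: an accepted step must improve the SSE of a linear-trend
  fit by at least 25 eSD² when a step regressor at the changepoint is
  added (a nested-model comparison).  A genuine rupture gains on the order
  of n_pre·Δx²/eSD² ≥ 40 even for the smallest design step; a slow drift
  tail misdecoded as a final level gains only noise-scale (χ² with one
  degree of freedom, ≈14 after selection over ~10³ candidates).  Without
  this screen, molecules with ordinary 0.3–1 nm/s drift contribute
  seconds-long phantom events at forces where true lifetimes are tens of
  milliseconds, corrupting the slip branch of the fit.
- *Instantaneity*: within ±10 samples of the changepoint, at most 5
  median-smoothed (width 5) samples may lie in the middle 30% band between
  the level means.  The 7.5 ms instrument response spreads a true step
  over ~2 such samples; a multi-sample ramp fills the window.  The band
  and count were set from this response-time arithmetic: wider bands or
  raw-sample counting reject an unacceptable fraction of true steps once
  the noise scale approaches Δx/4.
- *Drift rescue*: when full-plateau drift cancels the step entirely (the
  one-way decoder never leaves the bound state, because late samples sit
  far from the +4 eSD emitter), a drift-immune line+step regression scan
  supplies a provisional changepoint, the plateau is truncated around it,
  and the window is re-decoded by Viterbi.  This mirrors the practice of
  truncating drifting plateaus to the region around the jump; Viterbi
  remains the primary decoder in all non-drift paths.

Plateaus that end with the system still bound are discarded rather than
right-censored: plateau dwells are chosen long enough (≥5 s against mean
lifetimes ≤ ~0.8 s) that the discarded fraction is below ~1%, and the
simulator's ground-truth log quantifies the residual bias (the surviving
mean at the 4-sample censoring floor is t₀ + τ̄ by memorylessness; tests
assert this).

## Lifetime statistics and fits

Events pooled by (construct, F_Tot) give groups with mean τ̄, SEM, event
and molecule counts; 1/τ̄ is the off-rate.  Survival curves are
S(t) = 1 − ECDF evaluated at the observed lifetimes; the last point is
moved from 0 to 0.01 *only* on the plotting copy (a semilog display
convention), never in fitting input.  Single-exponential fits
S = A·e^{b·t} use unweighted nonlinear least squares on the survival
points at observed lifetimes, with free amplitude — fitting style matches
the plotted convention; the data do not determine A ≈ 1 exactly because
the shortest observable lifetime is censored at 4 samples.

Survival residuals are strongly autocorrelated (the ECDF is cumulative),
so a sign-runs test rejects even correct single-exponential fits.  The
adequacy diagnostic is therefore a Kolmogorov-style statistic,
max|S − fit|·√n: ≲1 for adequate single-exponential fits, several units
for mixed populations.  The runs p-value is still reported.

The catch-slip Bell fit minimizes weighted residuals of τ̄(F) in lifetime
space, weights 1/SEM² (unit weight for single-event groups, which are
kept and flagged rather than dropped).  Rate-space fitting is available
as a sensitivity option (`weights="unit"` plus transforming inputs), but
lifetime space matches the plotted quantity.  A deterministic 24-point
multi-start grid over (k_c⁰, x_c, k_s⁰, x_s) with sign constraints
(x_c < 0 < x_s) avoids the catch/slip label-swap minimum.  95% CIs are
linearized (1.96 × stderr from the covariance at the optimum); simulated
refits at assay-like n (10 force levels × ~30 events) cover the true x_c
and x_s in well over 85% of replicates.  Data without a rising or falling
branch raise a structured error naming the unidentifiable pathway rather
than returning a degenerate fit.

The critical force uses the closed form
F\* = kBT·ln(−k_c⁰x_c/(k_s⁰x_s))/(x_s − x_c) and raises when no interior
positive-force maximum exists.  Note that rounded literature-style
parameter sets can place F\* a few tenths of a pN away from values
computed from unrounded fits; all recovery checks here compare against
the closed-form F\* of the actual simulation truth.

The binding isotherm Y = Y_max·[S]/(K_D + [S]) is fit by least squares
with data-driven initialization; titrations whose fitted K_D runs beyond
50× the top concentration are declared unidentifiable (no curvature).
The response is treated as the magnitude |ΔF_norm| with no baseline
offset term.

## Simulator

`simulate_session` emulates the force-jump assay's statistical structure:
per cycle, a Bernoulli(p_bind) binding outcome at the 0.5 pN dwell; on
the jump to F_Tot the pair experiences F_Load from the circuit model and
survives τ ~ Exponential(τ̄(F_Load)) under the ground-truth catch-slip
law; the position steps by the circuit-model Δx; Gaussian noise, optional
per-molecule linear drift (rate ~ N(0, 0.5 nm/s)), and a single-pole
7.5 ms low-pass are added.  The low-pass is applied per plateau: the
force jump itself is sub-sample at 200 Hz (~20,000 pN/s) and plateaus
are delimited where the force has settled, so the inter-plateau position
jump must not bleed into the analysis window.

Defaults are the study conditions: 200 Hz, 0.5 pN low force, high forces
{4, 6, 8, 10, 12} pN, 5 s plateaus, both 55 and 70 nt bridges.  Values
the assay description does not pin down were chosen once: noise_sd = 1 nm
(typical point-to-point position noise of a dual-trap instrument at
200 Hz, placing the smallest analyzed step, ≈3.4 nm, above 3 eSD),
p_bind = 0.3 (a plausible fraction of jumps showing an intermediate), and
drift sd 0.5 nm/s to exercise the drift screens.

Not emulated: bead-in-trap Langevin dynamics, trap stiffness and feedback
transients, low-force binding/unbinding kinetics (collapsed to one
Bernoulli draw), rebinding within a high plateau (the unbound state is
absorbing), and tether-to-tether geometry variation.  Passing tests
therefore demonstrate correctness of the analysis chain under the assay's
idealized statistical structure — exponential single-state lifetimes,
instantaneous rupture, stationary Gaussian noise plus linear drift — not
robustness to every instrument pathology.

MST titrations are simulated as 16-point 1:2 dilutions from 40 μM final
(80 μM stock mixed 1:1 with the 50 nM labeled partner) with Gaussian
noise proportional to Y_max.

## Problem sizes

The recovery study simulates 10 corpora (seeds) of 10 molecules per
construct × 50 cycles, ~30 accepted events per force level — the same
order as the recorded data sets (11–57 events per force) — and completes
in well under a minute per corpus on one CPU.  Statistical invariants
(censoring fractions, truncated means) use 10⁴ schedule-only plateaus.

## Known limitations

- Lifetimes are quantized at the 5 ms sample period and biased upward by
  about half a sample plus the 20 ms acceptance floor; at the fastest
  groups this inflates mean lifetimes by ~5%, which propagates to mild
  compression of |x_c|, x_s relative to truth (visible in the recovery
  medians, well inside the stated tolerances).
- Linearized CIs understate uncertainty when k_s⁰ approaches its bound
  (shallow objective); profile likelihood is not implemented.
- The drift screens are declared proxies for manual curation; their
  thresholds are configurable and the defaults were set from the response
  time and noise arithmetic above.
- The unbound-state Δx reference assumes a single tether with known
  bridge length; multi-tether artifacts are out of scope (handled
  upstream by force-extension screening in the assay).
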