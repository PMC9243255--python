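# Methods

This note documents the models, the numerical choices, and what the
synthetic cohorts do and do not emulate. It is the package's own account
of its science; every number quoted here is computed by the test suite or
by `scripts/acceptance.py` at run time.

## Model-free measures

### Phase extraction

All measures operate on instantaneous phases of narrowband BOLD. Each
parcel's series is demeaned, band-passed to 0.008–0.08 Hz with a
second-order Butterworth filter applied forward–backward (zero phase —
required because the phase *is* the analysis object; any filter phase lag
would bias every downstream measure), and Hilbert-transformed. The first
and last `edge_discard` volumes (default 10 per end) are excluded from all
statistics via the phase field's valid window, because both the
forward–backward filter and the Hilbert transform are unreliable near the
series boundary. A constant (zero-variance) parcel has no defined phase;
it is flagged and carried with phase 0 rather than poisoning the kernel
sums with NaNs.

### Local Kuramoto order parameter

The discrete local order parameter at scale λ (mm⁻¹) is the
kernel-weighted complex mean of the phase factors,

    R_n^λ(t) e^{iν_n(t)} = Σ_p [C_np^λ / Σ_q C_nq^λ] e^{iφ_p(t)},
    C_np^λ = exp(−λ r(n,p)).

The self-term (p = n, weight e⁰ = 1) is included in the sums; the sum over
parcels has no reason to exclude the centre parcel, and excluding it would
break the λ→∞ limit (where R_n → 1, the parcel in perfect synchrony with
itself). It is toggleable (`include_self=False`) for sensitivity checks.

The scale grid is {0.01, 0.03, 0.06, …, 0.30} mm⁻¹: 11 scales spanning
~100 mm (λ=0.01) down to ~3 mm (λ=0.30), including the single-scale
readout λ=0.12 used for node-level summaries and the perturbation
measures.

### Derived measures and conventions

- Amplitude turbulence D_λ: *population* standard deviation (ddof=0) of
  the modulus field flattened over nodes and retained time points. At
  least two samples are required; variance of a single observation is
  undefined.
- Information cascade flow ℱ(λ): per node, the Pearson correlation over t
  of R_λ(t+Δt) against R_{λ−Δλ}(t), averaged over nodes. Δt defaults to
  one repetition time and Δλ to the grid step 0.03. Zero-variance nodes
  carry no correlation and are excluded (their count is the caller's to
  log); the lowest scale has no predecessor and therefore no flow. The
  information cascade is the plain mean of the defined flows.
- Transfer correlation A^λ: pairwise correlations over time of the
  modulus, averaged within 20 equal-width distance bins inside the
  inertial subrange, then an OLS fit of log(mean corr) on log(bin centre).
  Real coordinates give measure-zero ties in distance, so "pairs at equal
  distance" must be discretised; bins with non-positive mean correlation
  have no defined logarithm and are dropped, and at least 3 usable bins
  are required. The inertial subrange defaults to 8–34 mm and is
  configurable — the power-law regime has to be chosen, not derived, at
  100-node scale.
- Node-level metastability NLM(n,λ): per-node population std over time of
  the modulus.
- Slope-across-states: at each λ, OLS of the states' mean D_λ against
  their ordinal rank (1..S in the user-stated order). Encoding states as
  ranks is a convention; with two states the slope reduces to the plain
  difference.
- Raw A^λ (and |A^λ|) are reported, never a cosmetic constant-minus
  presentation.

All correlations in the package are Pearson; all standard deviations are
population (ddof=0). Both conventions are deliberate and uniform so that
measures computed by different modules are comparable.

## The whole-brain model

Each parcel is a Stuart–Landau oscillator — the normal form of a
supercritical Hopf bifurcation — diffusively coupled on a structural
connectome C:

    dx_n/dt = (a_n − x_n² − y_n²)x_n − ω_n y_n + G Σ_p C_np (x_p − x_n) + ν η
    dy_n/dt = (a_n − x_n² − y_n²)y_n + ω_n x_n + G Σ_p C_np (y_p − y_n) + ν η

For a_n < 0 the node is a noisy damped oscillator; for a_n > 0 it sits on
a limit cycle of radius √a_n at frequency ω_n/2π. The x component,
subsampled at the repetition time, is the BOLD proxy — no hemodynamic
convolution, matching the modelling practice this package follows.

Parameters and defaults:

- `a = −0.02` for every node during fitting: fixed subcritical operating
  point. G and a trade off monotonically, so fixing a preserves
  between-state differences in the fitted coupling; −0.02 is consistent
  with the subcritical perturbation range [−0.02, 0].
- `ω_n`: per-node spectral peak of the (band-passed) data, via a lightly
  smoothed periodogram restricted to the band. Synthetic cohorts draw
  node frequencies uniformly in 0.02–0.07 Hz.
- `noise_sd ν = 0.01`, noise increment ν·√dt·N(0,1) per component per
  step, so ν matches the model's nominal noise amplitude under the
  discrete scheme.
- `dt = 0.1 s` default, `tr = 2 s` output sampling, first 20 s discarded
  as transient.

### Integrator

The drift is integrated with a Heun (predictor–corrector) step and the
noise added as an Euler increment. Plain Euler–Maruyama was rejected for a
quantitative reason: for a rotating limit cycle, Euler inflates the
stationary radius by ≈ dt·ω²/4 per unit radius (≈5×10⁻³ at dt = 0.1,
ω = 2π·0.05), which visibly distorts the oscillation amplitude the model
fitting depends on. The Heun step's radius bias is O(dt²) (~1×10⁻⁴ at
dt = 0.1, ~3×10⁻⁷ at dt = 0.005), so the closed-form limit-cycle radius
√a is reproduced to 1e−6 at a small step — a property the test suite
checks directly. For additive noise both schemes have the same strong
order; the Heun step simply removes the deterministic bias at no cost to
the noise convention.

Divergence (state norm above 10⁶, or non-finite state) raises an error
naming the step and parameters; the coupling sweep marks a G value invalid
if every repetition diverges, and perturbation trials are retried at most
3 times with fresh derived seeds.

### Fitting G

Functional connectivity as a function of distance, FC(r), is the mean
pairwise Pearson correlation of standardised signals within distance bins
(the Kolmogorov structure function is S(r) = 2(1 − FC(r))). The fit error
between simulated and empirical curves is the RMS difference over bins
inside the inertial subrange. G is swept over a grid (default 0–3 in 0.25
steps, 5 repetitions per value — a desk-scale default; the larger
published-scale sweep 0–7 in 0.1 steps with 100 repetitions is available
through the config); repetition seeds are shared across G values so the
comparison along the grid is paired, and ties break toward smaller G.
Empirical curves are computed on band-passed signals by default (the
band-limited regime is where the model is interpreted); raw-signal curves
are one flag away.

On synthetic data the sweep recovers a known generative G\* = 1.5 on the
default 100-node system within one grid step (exactly, in the seeds the
acceptance script runs). When fitting cohorts generated at G\* = 2.0 vs
0.5, the recovered optima preserve the ordering but the high-coupling
optimum is biased low (≈1.25): the empirical curve averages 10 noisy
subjects and uses estimated rather than true node frequencies. The
package's discriminative claims rest on the ordering, not the absolute
value.

## Perturbation readouts

Two protocols, both applied to the fitted system at its optimal G:

- periodic forcing: F₀cos(ω₀t) and F₀sin(ω₀t) added to the x and y
  equations respectively, F₀ = 5×10⁻⁴ for every node, ω₀ = unweighted
  mean of the node frequencies;
- bifurcation shift: every a_n redrawn uniformly in [−0.02, 0] per trial
  (kept subcritical by construction).

Each trial pairs a perturbed with an unperturbed simulation on the *same*
noise stream (identical seed and draw sequence), so a null perturbation
(F₀ = 0, or a no-op shift) yields exactly identical trajectories and
χ = I = 0 with no sampling error — this is a variance-reduction choice
that makes the perturbation, not the noise realisation, the only source
of difference.

The readout is the local-order modulus at a single scale λ_s = 0.12
(mid-grid; the choice is configurable since nothing pins it down), after
running the simulated signal through the same band-pass → Hilbert →
local-order pipeline as data. With d(trial, node) the time-mean perturbed
minus unperturbed modulus:

    χ = ⟨⟨d⟩_trials⟩_nodes
    I = sqrt( ⟨ Var_trials(d) ⟩_nodes )

χ is signed (a perturbation may lower local order). I places the square
root outside the node average of the across-trial variance — a single
space-averaged variance under one root, not a per-node std averaged; for
two trials with shifts {0, d} everywhere both readings coincide at d/2,
and the implemented form is the variance-under-root definition. n_trials
defaults to 10.

### Lempel–Ziv complexity

The comparison yardstick is normalised LZ76: each node's signal binarised
at its own median (mean optional), sequences concatenated in node order,
phrase count c normalised by the random-sequence asymptote n/log₂(n). An
i.i.d. fair coin of length 10⁴ scores ≈1.04 under this normalisation; a
constant sequence sits at the 2-phrase floor (≈0.02 at n = 1000).

## Statistics

- Wilcoxon rank-sum, two-sided, per scale: exact enumeration of the
  mid-rank statistic over all group assignments when the combined n ≤ 12
  (924 assignments at 6+6 — cheap, and correct under ties, where the
  usual exact tables do not apply); otherwise the tie-corrected normal
  approximation. Type-I error on null groups of 10 vs 10 sits at ~5%
  (3.7–5.2% in the seeds the suite runs).
- FDR: Benjamini–Hochberg step-up. The correction family is the set of
  scales within one measure for one state pair — the narrowest defensible
  reading of "corrected across comparisons"; pooling across measures is a
  caller-side choice.
- KS distance between node-level metastability distributions (all parcels
  × subjects pooled per state), with the two-sample test p-value reported
  alongside.
- Top-quantile node attribution: nodes at or above the (1−q) quantile of
  |mean difference| (q = 0.15 default), tallied per network label, with a
  tie flag when the threshold is attained by more nodes than q·n.

## Synthetic cohorts: what they emulate, and what they don't

The generator reproduces the *design* of a multi-state resting-state
study: 100–1000 parcels with mm-scale 3D geometry (default 100 nodes
uniform in a 70 mm ball — preserving the distance statistics of a
brain-scale parcellation at desk-scale cost), TR = 2 s, 150–450 volumes,
narrowband oscillations with spatially decaying coupling, and groups that
differ only in the generative global coupling G\* — the effect the
analysis is designed to detect. Network labels come from k-means on
coordinates: spatially coherent partitions standing in for resting-state
networks in the attribution step.

What passing tests on these cohorts show: the measures separate states
that differ in coupling, the model fit recovers coupling, and the
perturbation readouts order states by coupling. What they do not show:
robustness to head motion, physiological noise, hemodynamic variability,
lesion-driven signal dropout, or parcellation mismatch — none of which
the generator emulates (no balloon-model convolution, no volumetric
synthesis). Real-data preprocessing is out of scope by design; the
package starts at parcellated time series.

Reproducibility: every generator is a pure function of (inputs, seed);
cohorts written to disk carry a manifest and a JSON sidecar with the
generating parameters and seeds sufficient to regenerate bit-identically.

## Problem sizes used by the default suite

The shipped tests and the acceptance script run at 30–100 nodes, 80–400
volumes, 13-point G grids with 5 repetitions, and 10-trial perturbations.
These sizes were chosen so the full suite completes in about a minute
while every qualitative claim (separation, recovery, ordering,
calibration) is still decided with conventional significance; all of them
scale up through the config for cluster-scale runs.

## Known limitations

- The coupling fit's absolute optimum is biased low on noisy short
  cohorts (see above); between-state ordering is preserved.
- The transfer-correlation fit needs a populated inertial subrange; very
  small parcellations (≲20 nodes) can fail the 3-bin minimum.
- The exact rank-sum enumeration is limited to combined n ≤ 12; beyond
  that the normal approximation's discreteness error is the usual one.
- Susceptibility and information capability are defined through one
  readout scale λ_s; conclusions at other scales require re-running the
  protocol (cheap) rather than any post-hoc rescaling.
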