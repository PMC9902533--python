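# Methods

This note records the models implemented in `digisense`, the choices
made where the design was genuinely open, and what the synthetic-data
generators do and do not emulate.

## Photon traces

Arrival times are integer ticks (default 16 ps) and stay integers
through I/O; all thresholds are converted to ticks by rounding toward
zero, so comparisons are exact on the counter grid. Trace duration is
always explicit input — it is never inferred from the last photon,
because an empty or sparse trace would otherwise silently shrink.
Binning uses half-open intervals `[k·w, (k+1)·w)` with 0-based indices;
the single photon that can land exactly on the closed upper end of the
trace goes into the last bin so that binning at any width conserves the
total count. Unsorted input files are an error, not a sort: timestamp
order is evidence of acquisition integrity.

## Burst detection

**IPT search.** The inter-photon-time sequence is smoothed with a Lee
filter before thresholding. The filter's running mean and variance use
a centred window of `2n+1` samples (`n = 4` by default), truncated at
the edges, with population-variance normalisation; a conditioning shift
by the first sample keeps constant sequences exactly invariant. The
noise scale σ₀ is not prescribed by the underlying method description;
the default is half the IPT threshold — large enough to pull isolated
long gaps inside a dense photon run back under threshold (so single
molecules are not split in two), small enough to leave the burst edges,
where the local variance is huge, untouched. σ₀ is an explicit
parameter for users who need different smoothing.

"A string of at least M photons with IPT below threshold" is read as:
a maximal run of consecutive photons whose `M−1` or more gaps are all
`≤` threshold, emitted when the run holds `≥ M` photons (a run of `k`
qualifying gaps spans `k+1` photons). Photon-count thresholds count
photons, not gaps. Burst boundaries are the first and last photon of
the run. Qualification is `≤` for gaps and strictly `>` for intensity
bins, so a degenerate all-equal binned trace yields zero bursts.

**Intensity search.** For rare, very bright particles on a bulk
background the detector is a per-trace threshold `mean + 5·SD` over the
distribution of all 1-ms bin counts (population SD; with hundreds to
thousands of bins the n vs n−1 distinction is far below the noise).
Bursts are runs of bins strictly above threshold, with no shoulder
extension — the simplest defensible boundary rule; the raw (unfiltered)
bins are used, since the 5-SD rule is defined on the bin-count
distribution itself.

## Electropherograms

Counts and mean intensities are averaged per position across repeats
with the sample (n−1) SD, matching how repeat scatter is quoted in
practice; a single repeat reports SD 0. Region integration is per
repeat first, then mean ± SD, over half-open `[x_min, x_max)` windows
whose bounds are configuration, not constants. Scan direction can
alternate between experiments while electrophoretic deflection cannot;
`flip_positions` re-expresses a scan on the common axis and is a
per-experiment flag in the CLI.

The two-peak decomposition fits two Gaussians plus a constant baseline
by bounded nonlinear least squares. Initialisation is deterministic and
data-driven: centers at the two highest interior local maxima (leftmost
wins ties; fall-backs cover monotone or single-peak profiles), widths
of three grid spacings, baseline at the profile minimum. Area fractions
are normalised to sum to one and are invariant to rescaling the
ordinate. Non-convergence raises with diagnostics; the fit never
silently returns defaults.

## Quantification

The flux conversion `F = (n/t)·(h·d_step)/((π/4)·z·w)` treats the
confocal cross-section as an ellipse of axes *z* and *w*; with the scan
step as the per-position catchment width, the count per trace scales to
the whole chamber. `c = F/(N_A·Q)` uses the exact SI Avogadro constant.
Uncertainties propagate to first order from the repeat-count SD only;
geometry is treated as exact, because the quoted ± derives from repeat
scatter. Negative net counts (control exceeding sample by noise) clamp
to zero with a warning rather than an error.

Assays run on a device variant with an upstream desalting module retain
only part of the analyte in the counted sample stream; a
`recovery_factor` multiplier (default 1.0) is provided for users who
know that retention, and no value is assumed. The equilibrium
back-calculation subtracts `valency × c_complex` from the total probe
(valency defaults to 1; multivalent particles pass their
intensity-ratio valency explicitly).

The confocal dimensions used in the flux formula (`z = 3 µm`,
`w = 0.4 µm`) and the FCS-fit representation (`w0`, `z0 = κ·w0`,
`V_eff`) are kept as independent device-level quantities: the two
parameterisations of the detection volume are not mutually consistent
for the reference device (z/w = 7.5 while κ = 6.0) and no
reconciliation is attempted.

## Binding model

`solve_equilibrium` solves the 1:1 quadratic in a dual-branch stable
form: the complex from `2PA_prod/(b+√(b²−4PA_prod))` and, symmetrically,
each free species from its own quadratic; whichever quantity is
smallest is taken from its stable expression and the rest follow by
exact conservation. Mass action then holds to ~1e-12 relative across
fifteen orders of magnitude of inputs, including the quantitative-
binding limit where the naive root cancels catastrophically.

`dissociation_survival` is `exp(−k_off·t)` under instantaneous,
irreversible washout (no rebinding). The association rate constant has
**no default**: published on-rates span orders of magnitude, and the
only value printed for the reference system (10⁻⁴ M⁻¹ s⁻¹) is
physically implausible for an aptamer–protein pair — the likely
intended value is 10⁴ M⁻¹ s⁻¹. Requiring `k_on` explicitly keeps that
choice visible. The reference description's "~66% dissociated in 45
min" is not reproducible from this closed form with either value and is
not asserted anywhere.

## FCS calibration

The correlator is multi-tau in spirit: each requested lag is estimated
from a binning at `lag/16` (floored at 0.1 µs), shift `k = lag/bin`,
with the symmetric normalisation `⟨n_i n_{i+k}⟩/(⟨n_i⟩⟨n_{i+k}⟩) − 1`.
The model fit minimises *relative* residuals by default — correlation
noise scales with G, and relative weighting is what keeps the weakly
identified axial ratio κ conditioned (uniform weighting is available).
κ can be pinned (`kappa_fixed`) when a curve is too short or noisy to
constrain it, the standard practice for routine calibrations. No
triplet term is included; short-lag points of flickering dyes should be
excluded by the caller. Conventions: `τ_D = w0²/(4D)` (lateral e⁻²
radius), `V_eff = π^{3/2} w0² z0` (1 µm³ = 1 fL).

## Synthetic data

`simulate_trace` draws background photons as a homogeneous Poisson
process and transit events as a Poisson process in time, each emitting
Poisson-distributed photons **uniformly** over the transit window — a
rectangular profile rather than the Gaussian of a real focus, because
burst detection at the operating settings is insensitive to the profile
and the rectangle keeps ground truth unambiguous. Event starts are
drawn in `[0, duration − transit]` so edge truncation never confounds
recovery tests. All generators spawn child seeds deterministically per
repeat and position; identical configurations are bit-identical.

`simulate_scan` inverts the flux relation: a species of concentration
*c* contributes per-position event rates
`F·p(x)·(π/4)·z·w/h` with `F = c·N_A·Q` and `p` a Gaussian elution
profile, so the full pipeline applied to the output recovers *c* within
Poisson error. Elution centers come either from an explicit position or
from `µ·E·t_res` (mobility × effective field × residence time); the
simulator takes the *effective* field directly rather than modelling
the device's 30–40% voltage efficiency.

Default study conditions used throughout the tests mirror the reference
streptavidin assay: 25 pM analyte, 5-s traces, 70 µL/h, 31.7-µm steps,
1 kHz background, ~50 photons per transit over 0.3 ms (the transit a
0.4-µm focus waist implies at the chamber's mm/s linear flow), elution
spread σ = 250 µm as read off the measured peak widths. Under those
conditions a scan carries ~1550 events, so single-scan recovery is
Poisson-limited at ~2.5% relative.

What the generators do **not** emulate: diffusional blur and flow
dispersion of the elution profile, detector dead time and afterpulsing,
fluorophore photophysics (blinking, bleaching), Joule heating and
electroosmotic drift. Passing recovery tests therefore demonstrate the
correctness of the counting and conversion chain, not robustness to
those instrument effects. Event pile-up *is* present in the simulation
(overlapping transits merge into one burst, ~0.5–1% undercount at the
default densities) and is deliberately left uncorrected, as in the real
analysis.

`simulate_fcs_trace` runs Brownian dynamics of point emitters in a
periodic box (8 lateral radii per side) with a 3D Gaussian detection
profile, in units of the lateral radius; it exists to exercise the
correlator end to end, not to model photophysics.

## Numerical and degenerate-input conventions

- Thresholds to ticks: round toward zero; gap qualification `≤`,
  intensity bins `>`.
- Fewer than two photons: inter-photon times are an empty sequence, not
  an error; fewer than two bins: intensity search refuses (SD
  undefined).
- Empty burst sets summarise as count 0 with NaN location statistics.
- Two-Gaussian and diffusion fits: bounded least squares, deterministic
  data-driven starts, `FitError` with diagnostics on non-convergence.
- Volume fractions above 1 are returned unclipped with a warning.
- The dense-phase FUS/RNA printed ratio of the reference system is
  internally inconsistent (1414.6/3.5 ≈ 404, printed as 40); the
  package returns the computed ratio of whatever inputs it is given and
  asserts nothing about that figure.

## Problem sizes

The test suite and simulators are sized for a laptop-class single CPU:
oracle-equivalence runs use 100 traces of ≤10⁴ photons; closed-loop
recovery uses 50 seeded single-repeat scans of 57 positions × 5 s;
FCS noise calibration uses 100 replicate curves of 60 log-spaced lags;
the equilibrium property check uses 10⁵ random triples. The full suite
completes in well under a minute.
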