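# Methods

`conformo` models and analyzes single-pair FRET experiments on freely
diffusing molecules that exchange between conformational states, together
with the binding thermodynamics and structure-based dye geometry that
surround such an experiment.  This note documents the models, the
numerical choices, and what the synthetic data do and do not emulate.

## Photon-level simulator (`conformo.simulate`)

**Physical model.** Labelled molecules diffuse freely (Brownian motion,
diffusion coefficient `D`) through a confocal detection volume described
by a 3D Gaussian profile, `w(x,y,z) = exp(-2(x²+y²)/wr² - 2z²/wz²)`.
The detected photon rate of a molecule is `peak_brightness × w` per
excitation color; donor and acceptor lasers alternate fast compared to
every diffusion time scale, so the excitation gate is drawn per photon
with deterministic labels rather than from explicit pulse trains (the
alternation rate, 26.67 MHz, and the ~18 ns interleave delay are carried
as metadata).

Each molecule carries a conformational state from an exact (Gillespie)
continuous-time Markov chain between two dynamic states, plus an
optional non-interconverting third state occupied by a fixed fraction of
molecules.  A state is a Gaussian distance distribution; the molecule's
quasi-static distance is redrawn from it every `static_redraw_time`
(default 10 ms), and a fast per-photon Gaussian linker jitter (default
5 Å standard deviation) is added on top.  Per photon: transfer happens
with probability `E(R) = 1/(1+(R/R0)⁶)`; donor photons draw microtimes
from the FRET-quenched exponential decay `τ_D(1-E)`, sensitized acceptor
photons add the acceptor decay to the donor delay; polarization channels
are drawn from the time-dependent anisotropy `r(t) = r0·exp(-t/θ)`
evaluated at the emitting dye's own excited-state delay.  Donor
cross-talk (`beta`), direct acceptor excitation (`alpha` pathway) and the
relative detection efficiency (`gamma`) are applied as per-photon
misassignment/thinning, so the downstream correction formulas can be
exercised end to end.  Uniform Poisson background is added per channel.
Microtimes roll over at the gate window (for an exponential decay the
wrapped distribution on `[0, T)` equals the truncated one, which is what
the lifetime estimator assumes).

**Defaults.** The simulator defaults encode the in-silico validation
conditions used throughout: 2000 s in a 5 µm³ periodic box with 10
molecules, `D = 1 µm²/s`, `wr = 200 nm`, `wz = 1000 nm`, `R0 = 53 Å`,
donor-only lifetime 3.8 ns, `r0 = 0.4`, Gaussian state widths of 5 Å
scale, 5 Å linker jitter and a 10 ms redraw time.  Peak brightness
(150 kHz at focus) and the acceptor-excitation brightness ratio (0.6)
are not prescribed anywhere; they were chosen once to give realistic
bursts of 20–250 donor-gate photons per millisecond bin and clean
stoichiometry separation, and are exposed in the configuration.

**Two generation modes.** `trajectory` integrates all molecules with a
fixed time step (default 1 µs, which is 10⁻⁴ of the lateral diffusion
time `wr²/4D = 10 ms`) in the periodic box.  `event` mode simulates only
passages through the observation region — an ellipsoid of 1.5 PSF waists,
where the detection weight has fallen to 1.1% of peak, well below the
rate a burst search can sustain — with entry points uniform per unit
area (the diffusive flux from a uniform bath through any surface is
uniform per area) and otherwise identical stepping and photon physics.
Event mode therefore reproduces trajectory-mode burst-size and FRET
statistics (verified by two-sample KS tests in the suite) while skipping
the empty-box time; passages are laid on a common time axis with 220 ms
spacing so they can never overlap, and passages are generated until the
requested number carries at least 50 detected photons.  A passage is
capped at 200 ms.  Event mode deliberately contains no coincident
molecules; trajectory mode at high concentration does, which is one of
the reasons real data are messier than these simulations.

**What the synthetic data do not emulate:** acceptor dark states and
blinking, photobleaching, IRF structure beyond an optional Gaussian
(default off), detector afterpulsing and dead time, and scattering
backgrounds with non-uniform microtimes.  Passing tests therefore show
correctness of the analysis chain for the stated photophysics, not
robustness to every experimental artefact.

## Burst analysis (`conformo.bursts`)

The all-photon sliding-window search pools both gates and all four
channels; a photon is in a burst region when at least 5 photons fall in
the half-open 500 µs window centred on it, and maximal runs with at
least 50 photons become bursts (all thresholds configurable).  The
implementation is O(n log n) via sorted searches and is tested for exact
equality against an O(n²) brute-force scan.

ALEX-2CDE is implemented with an exponential kernel (default time
constant 100 µs) and small-sample-corrected no-bias self-densities, and
is normalized so a well-interleaved burst scores near 0 and a fully
gate-segregated burst near 100; single-gate bursts are flagged with the
maximal score.  The default acceptance threshold is 12.

Corrected FRET efficiency and stoichiometry use the standard two-color
formulas with background subtraction over the burst duration
(last-photon minus first-photon time), direct excitation `alpha`, donor
cross-talk `beta` and detection-efficiency `gamma`; out-of-range values
are preserved (shot noise is information, and PDA consumes raw proximity
ratios anyway).  Burst-wise lifetimes come from a maximum-likelihood
single-exponential model on the finite microtime window with an optional
uniform background fraction and an optional binned IRF convolution
(default off).  Steady-state anisotropies use the G-factor-corrected
count ratio, and the Perrin relation `r = r0/(1+τ/θ)` is fitted with
`r0` fixed at 0.4.

Static FRET lines average the lifetime moments over a Gaussian distance
distribution (default 6 Å width) — the observed lifetime axis is the
fluorescence-weighted mean `⟨τ²⟩/⟨τ⟩` while the efficiency axis is
`1 - ⟨τ⟩/τ_D` — and reduce exactly to `E = 1 - τ/τ_D` at zero width;
dynamic FRET lines trace the same moments for a two-state occupancy
mixture between hand-picked endpoint lifetimes.

## Photon distribution analysis (`conformo.pda`)

Accepted bursts are re-cut into bins of 0.2, 0.5, 0.75 and 1 ms
(trailing partial bins discarded); bins keep their donor-gate photon
count `F` and acceptor share, and only bins with 20–250 photons and a
raw stoichiometry inside `[0.3, 0.8]` (configurable; removes donor-only,
acceptor-only and acceptor-photophysics bins) are retained.  The
empirical `F` distribution is used as-is — no parametric count model.

**Forward model.** A state maps a distance to an apparent acceptor
probability `ε(R) = (γE + β(1-E)) / (γE + β(1-E) + (1-E))`; acceptor
counts are binomial in `F` given `ε`, optionally convolved with
truncated-Poisson background counts in both channels.  Because the
shot-noise part depends only on the dataset, it is precomputed once per
(dataset, bin duration) as a kernel matrix over a 201-point `ε` grid;
evaluating a model reduces to building a mixture weight vector over that
grid plus one matrix product.  Pure Gaussian states are deposited
*exactly* (the `ε(R)` map is monotone, so cell masses are differences of
Gaussian CDFs); zero-width states bypass the grid entirely and use the
exact binomial.

**Fast linker motion.** The per-photon dye-linker jitter redraws the
distance photon by photon, so each photon's acceptance probability is the
jitter-averaged ``eps_eff(R) = E[eps(R + delta)]``; because the jitter is
independent per photon, bin counts remain exactly binomial in this
smoothed probability.  ``PdaModel.linker_width`` (Å, an input constant —
the known simulator value or the FRET-line linker width, never fitted)
applies this Gaussian smoothing to the monotone ``eps(R)`` table.

**Dynamics.** Within a bin of length `T` the two dynamic states
contribute the occupancy-weighted average
`ε̄ = (T₁ε₁ + (T-T₁)ε₂)/T`, integrated over the exact occupancy-time law
of a stationary two-state chain: point masses
`P(T₁=T) = p₁e^{-k₁₂T}`, `P(T₁=0) = p₂e^{-k₂₁T}` and a continuous part
expressed through exponentially scaled modified Bessel functions
(stable at arbitrarily fast exchange; derived by summing over the number
of completed dwells).  Both rates zero gives the two-point stationary
distribution by convention.  The continuous part is integrated on an
adaptive grid restricted to the region where the (log-concave) density
is non-negligible — 97 nodes during fitting, 257 for reference
histograms — and its weight is renormalized so the law integrates to 1
exactly; Gaussian state widths use 25-node (fitting) Gauss–Hermite
quadrature.  These resolutions were set by a convergence study against
direct Monte-Carlo sampling (10⁶ bins): the reference settings reach a
pooled reduced chi-square near 1, and the fitting settings differ from
the reference by well under the statistical noise of any realistic
dataset.

**Global fit.** All bin durations of all datasets are fitted together by
Nelder–Mead on the summed Pearson chi-square (expected-count weights,
bins with expectation below 4 excluded), with log/logit parameter
transforms, 5 seeded restarts by default, and the documented linking:
state distances and the width fraction global, rates (dynamic) or areas
(static) per dataset — 10 free parameters for a two-dataset three-state
comparison.  Goodness criteria are a reduced chi-square below 3 and a
Wald–Wolfowitz runs test on the weighted residuals.  95% confidence
intervals of the rates are profile-likelihood scans (rate fixed on a
multiplicative grid, everything else re-optimized, `Δχ² = 3.84`
crossing interpolated in log-rate); the fitting literature this package
follows reports only that relative CIs were computed, so profile
likelihood is this package's choice.  Dwell times are reciprocal exit
rates, censored above 5 ms where the underlying rates are no longer
reliably determined; equilibrium distance distributions are the
fraction-weighted state Gaussians normalized to unit area.

**Clustered bins and goodness-of-fit calibration.** PDA treats time bins
as independent draws, but consecutive bins of one burst share a dwell
(at 1/ms exchange, a 1 ms dwell spans five 0.2 ms bins) and share the
quasi-static distance draw (10 ms redraw).  The *marginal* forward model
is unaffected — the 0.5 ms histogram of a full-scale correct-model fit
reaches a reduced chi-square of 1.0 — but the short-duration histograms
are over-dispersed (chi2_red up to ~7 at 0.2 ms) and their neighbouring
residuals are serially correlated, which miscalibrates plain Poisson
chi-square and sign-runs tests there.  Goodness of fit is therefore
judged on the global reduced chi-square of the simultaneous fit
(criterion < 3) together with a cluster-robust, block-averaged runs test
at the shortest duration.  The same clustering exists in real diffusing-
molecule data; it slightly widens true parameter scatter relative to the
nominal profile confidence intervals.

A second, smaller approximation: PDA conditions on the observed bin
count ``F`` with state-independent mixture weights, but with a detection
efficiency ``gamma != 1`` the high-efficiency state is dimmer in the
donor gate (rate ∝ ``1-(1-gamma-beta)E``), so near the minimum-count
acceptance threshold the state weights tilt with ``F``.  The fit absorbs
most of this into areas/rates — recovered rates stay well inside their
confidence bounds — but at very high bin counts the residual tilt is
statistically detectable.  This is shared by standard PDA practice,
which also conditions on ``F`` without state-dependent brightness.

A note on units: interconversion rates are 1/ms throughout.  Where the
surrounding literature quotes CI quality thresholds "for k > 0.25 s⁻¹"
while discussing millisecond-scale exchange, this package treats the
intended unit as 1/ms; the discrepancy is surfaced here rather than
silently normalized.

**Study-condition scales.** The full-scale recovery experiment uses
event-mode simulation sized so that every bin duration carries at least
3000 accepted bins (2000 photogenic passages, ~5·10⁵ donor-gate photons),
matching the stated validation scale.  The rate-window sweep
(k ∈ {0.05, 0.15, 1, 10, 30}/ms) uses bin-level Monte-Carlo data
(exact Markov occupancy + binomial emission, 3000–9000 bins per
duration, one replicate per rate) — the same generative law as the
photon-level pipeline after rebinning, at a fraction of the cost.

## Thermodynamics and kinetics (`conformo.thermo`)

The ITC model is the standard one-site perfusion-cell isotherm: total
concentrations follow the cumulative dilution product, the bound
concentration is the positive root of the binding quadratic, and the
differential heat per injection corrects for the displaced volume with
the mid-point rule.  Fitting estimates `n`, `Kd` (on a log scale) and
`ΔH` by least squares; `ΔG = -RT·ln(1/Kd)` (R = 1.9872 cal/mol/K) and
`-TΔS = ΔG - ΔH` follow exactly, and the Gibbs identity is enforced on
every parameter container.  Fits with a Wiseman c outside a wide window
are flagged low-confidence, not rejected; simulated schedules that
cannot approach saturation carry a warning flag.  The default synthetic
schedule (20 × 2 µl into 200 µl, 10 µM cell / 200 µM syringe) mirrors
typical small-volume calorimetry.

Temperature dependence: `Δcp` is the linear-regression slope of
`ΔH(T)`, extrapolated to the 60 °C reference; the Murphy–Freire
coefficients (a = 31.4, b = -8.44 cal mol⁻¹ Å⁻²; c = -0.26,
d = 0.45 cal mol⁻¹ K⁻¹ Å⁻²) link `(ΔH_r, Δcp)` to polar/nonpolar buried
surface as a regular 2×2 linear system, inverted exactly.  Buried area
is negative in this convention; residue equivalents divide by 56 Å²
(polar) or 34 Å² (apolar) and are reported as magnitudes.

Stopped-flow traces are single-exponential least-squares fits;
`kon` is the slope of `kobs` versus concentration, `koff` comes from a
displacement trace, and `Kd = koff/kon`.

## Structure mapping (`conformo.structmap`)

PDB parsing goes through biotite (highest-occupancy altloc resolution,
waters excluded by default, hetero atoms on request).  SASA is
Shrake–Rupley sphere sampling (960 Fibonacci points by default, 1.4 Å
probe, ProtOr group radii; element radii selectable), cross-checked in
the suite against Biopython's independent implementation.  Relative
accessibility normalizes by the published theoretical maximum ASA per
residue type (Tien et al. 2013 scale as shipped with Biopython) — a
deliberate use of the field-standard reference table instead of
constructing extended tripeptides internally — and classification uses
the exposure thresholds >25% (exposed) and <10% (buried).  Buried
surface between conformations is the plain SASA difference over protein
atoms with a per-residue breakdown.

The accessible volume is the single-radius (AV1) model: a cubic grid
(default 1 Å) around the attachment atom, clearance to the nearest atom
surfaces from a k-d tree, a Dijkstra flood fill through path-free space
(clearance > linker_width/2, 26-connectivity) and acceptance of
dye-clearance points within the linker length; positions are uniform.
The attachment atom never clash-blocks its own linker, and the
attachment residue's side chain is excluded by default (the dye replaces
it).  Dye geometries default to common maleimide values (donor: 20 Å
linker; acceptor: 22 Å; width 4.5 Å; radius 3.5 Å) — assumptions, not
measurements, and exposed in `DyeParameters`.  The FRET-averaged
distance converts the mean efficiency over (sub-sampled, seeded) AV
position pairs back through the Förster relation,
`⟨R_DA⟩_E = R0(1/⟨E⟩-1)^{1/6}`.  AV3 (three dye radii), mmCIF input and
structure superposition are out of scope.

The reference open/closed-state predictions (inter-dye distances and
the ~980 Å² buried-surface difference for the EF-Tu nucleotide states)
require the public coordinates 1EFC and 1EXM, which are not
redistributed with the package; the corresponding acceptance tests look
for them under `data/structures/` and fail with instructions otherwise.
All other structure tests run on synthetic pseudo-protein geometry
(`conformo.structmap.synthetic`) with constructed ground truth.

## Known limitations

- Dynamic PDA supports exactly two exchanging states plus one static
  state; no lifetime-based dynamics analysis.
- Event-mode simulation contains no multi-molecule coincidences and
  truncates passages at 1.5 waists / 200 ms.
- The lifetime estimator is single-exponential; multi-exponential donor
  environments bias it by construction.
- ITC is strictly 1:1; no competitive or multi-site schemes.
- AV1 treats the dye as a single sphere; sterically anisotropic dyes are
  approximated.
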