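# Methods

This note documents the models behind each module, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices a maintainer would want to know.

## Ion transport (GHK analysis)

**Model.** The GHK voltage equation with activities equal to
concentrations (mM), monovalent K⁺/Na⁺ and Cl⁻ only. Constants default to
T = 298 K, F = 96485 C/mol, R = 8.314 J/(K·mol); temperature is
overridable per `SolutionPair`. Divalents (Ca, Mg) and guanidinium are
carried in solution definitions for bookkeeping but never enter the
quotient — KCR permeability analysis treats them as non-permeant. The
chloride terms follow the standard convention ([Cl]i in the numerator);
every selectivity analysis here uses P_Cl = 0, so the convention does not
affect any reported number.

**Inversion.** With P_Cl = 0 the two-cation equation is inverted in
closed form. Degenerate inputs are handled explicitly rather than
clamped: E_rev at the K⁺ Nernst potential (infinite ratio) and gradients
admitting no positive root raise diagnostic errors; the fully symmetric
0/0 case returns the symmetric solution 1.0. Proportional outer/inner
solutions make the ratio structurally unidentifiable — the property-based
round-trip test excludes that manifold.

**Reversal from I–V data.** Per-step photocurrent amplitudes ("peak" =
largest-magnitude baseline-subtracted excursion during light; "steady" =
mean of the final 10 % of the light window) form the I–V table. A single
zero crossing is resolved by piecewise-linear interpolation between the
bracketing steps; with no crossing, the two steps nearest zero current
define a linear extrapolation, and the result is tagged accordingly.
Multiple crossings are an error listing every crossing, never a silent
choice. Junction-potential correction is a user-supplied additive offset
carried as a flag; Henderson-equation computation is out of scope.

**Filtering.** The Gaussian low-pass uses σ_t = √(ln 2)/(2π·f_c), which
gives |H(f_c)| = 2^(−1/2) (−3 dB) exactly for the continuous kernel;
edges are reflected. The precondition f_s > 2 f_c is enforced.

**Exponential kinetics.** Photocurrent segments are fitted as
offset + Σ aᵢ·exp(−t/τᵢ) (up to three terms) by Nelder–Mead simplex over
log τ with eight log-spaced multi-starts (seeded jitter, default seed
20230830) and the conditionally linear amplitudes profiled out at every
step (variable projection). Convergence tolerance is 1e−10 on the
relative SSE; τ values return sorted ascending; total non-convergence
raises an error carrying the best-so-far parameters.

**ΔF/F.** The photobleaching trend is a double exponential fitted on
samples outside the stimulation window and the 10 s rebound window; an
optional quantile clip can suppress residual positive transients but is
off by default because clipping also distorts a genuinely decaying
baseline. The trend is subtracted with the mean level preserved, a 0.5 Hz
Gaussian low-pass applied, and ΔF/F = (F − F₀)/F₀ computed against the
mean of the 5 s before stimulation. Peak-inhibited amplitude is the
stimulus-window minimum minus the baseline ΔF/F; rebound is the maximum
in the 10 s after stimulus offset. Filter edge effects make step-response
metrics accurate to ~1 %, not machine precision.

## Photocycle

**Model.** First-order kinetics dc/dt = A c with an absorbing ground
state; ΔA(λ, t) = Σ_s c_s(t)·Δε_s(λ). Propagation is exact via
eigendecomposition (the Bateman solution for chains); a (near-)defective
generator — coincident eigenvalues, eigenvector condition number above
1e10 — falls back to LSODA at rtol 1e−10 with a warning.

**Default scheme.** Eight intermediates in two parallel irreversible
chains K₁→L₁→M₁→N₁→ground and K₂→L₂→M₂→N₂→ground, excited population
split 0.5/0.5 between K₁ and K₂. The paired-intermediate connectivity is
a stated modelling assumption, fully configurable via JSON and never
hard-coded into fitting. Default rates are log-spaced
(2·10⁵…2·10² s⁻¹ and 6·10⁴…6·10¹ s⁻¹) so all eight relaxation
eigenvalues are pairwise ≥ 3.3× separated and resolvable on a 1 µs–10 s
grid.

**Species spectra.** Gaussian difference bands (species band minus the
521 nm dark-state bleach), FWHM 30 nm. Class centers sit at the probe
wavelengths used for the K, L/N, M₁ and M₂ intermediates (617, 480, 384,
404 nm); within a class the two chain members are offset by 20 nm — the
spacing of the resolved M₁/M₂ pair — so synthetic species remain
spectrally distinguishable.

**SVD rank.** Components count as significant while sᵢ/s₁ ≥ 0.01 and the
lag-1 autocorrelation of the spectral singular vector ≥ 0.8 (standard
flash-photolysis practice; both thresholds configurable).

**Global fit.** Variable projection on the SVD-compressed kinetics
(rank n+2): the simplex optimizes shared log τ from log-spaced
multi-starts, a Levenberg–Marquardt polish follows, and the DAS are
computed on the full wavelength grid. τ pairs collapsing within 5 % raise
an identifiability warning.

**Target fit.** Free rates on a fixed topology, optimized by LM over log
rates with species-associated difference spectra profiled linearly (also
on the SVD-compressed kinetics; final spectra and residual on the full
grid). Initialization inverts the global fit's timescales and assigns
them to free edges in species order (early intermediates fastest), with
seeded multi-start jitter. Structural over-parameterization (more free
rates than non-ground species) is an error; collapsed fitted rates and a
rank-deficient profiled Jacobian append warnings — an irreversible chain
with fully free spectra determines the rate *set*, and the assignment to
edges only up to exchange, which is exactly degenerate at equal rates.

**Statistical design of the recovery conditions.** With free spectra the
target fit is equivalent to multi-exponential analysis, which is
notoriously ill-conditioned. A Cramér–Rao analysis of the default scheme
at SNR 30 (SNR = peak |ΔA| / noise SD) shows that ~12 samples per decade
leave 1σ rate errors of 7–14 % and admit noise-favored distant optima;
at 400 samples per decade (2801 points — the density of a log-rebinned
digitizer trace) the worst-edge error drops to 3–8 % and the landscape
becomes effectively unimodal. The generator therefore defaults to the
dense grid; this is a statement about the data density required for
8-rate target analysis, and real sparse datasets should not expect
comparable precision.

**Pyranine differencing.** The no-dye trace is linearly resampled onto
the dye trace's grid and subtracted. The signed lag is the difference of
half-rise times (first crossing of the midpoint between initial and
final values, linearly interpolated); a reference that never crosses is
an error.

## Spectra

λmax is the grid argmax; optional 3-point parabolic refinement gets
within 0.5 nm of a dense-grid oracle for 20–60 nm-wide bands. Ties break
toward the shortest wavelength with a warning; flat spectra and edge
peaks are errors. Shifts are reported on the raw argmax by default so the
integer-grid fixtures give exact integers; refinement is opt-in.

Fixture presets are single Gaussian bands (FWHM 100 nm, unit peak,
250–750 nm at 1 nm): centers 521 (WT *Hc*KCR1), 486 (WT *Hc*KCR2),
508 (D105N), 386 (D229N) nm. The centers are the measured dark-state
values; the band shape is synthetic and carries no claim about real
lineshapes.

Titrations fit A(pH) = A_acid + (A_base − A_acid)/(1 + 10^{n(pKa − pH)})
with Jacobian-based standard errors; a midpoint outside the sampled range
is flagged extrapolated, and a residual RMS above 5 % of the response
span flags a poor fit (e.g. a double transition). The 4-parameter
logistic uses the same machinery; `normalize_to` divides by the response
at a reference x (the 4 °C incubation in a thermostability series) and
`log_x` fits concentration series on log₁₀ x, reporting the midpoint on
the linear scale.

## Retinal isomers

Mole fractions are (Aᵢ/εᵢ)/Σ(Aⱼ/εⱼ) with the published ε₃₆₀ table for
the eight oxime species (all-trans/13-cis/11-cis/9-cis × 15-syn/anti).
The 15-syn/anti split is kept internally; a reducer sums pairs per
C-isomer. Peak integration is trapezoidal over user-defined disjoint
retention windows with a linear baseline between window endpoints
(the integration method of the original chromatography software is not
specified; linear endpoint baselining is the conservative default);
negative corrected areas clip to zero with a warning.

## Trajectory metrics

Selections are `and`-joined equality clauses over atom-table columns
(`resi 222 and name OH`), with `+` for alternatives; centroids are
unweighted. Distances are computed without periodic imaging — wrapping is
unsupported and a sanity check warns when frame-to-frame jumps exceed
half the coordinate extent. Default cutoffs follow common MD-analysis
conventions and are configurable: 3.5 Å ion–water-oxygen first shell,
4.0 Å salt-bridge min-pair, 5.0 Å site binding; boundary distances count
inclusively.

The tight/loose classifier uses hysteresis (enter tight below the low
threshold, loose above the high threshold, otherwise hold; leading frames
undefined), so chatter inside the dead band produces no transitions.
Auto-thresholding takes the two largest histogram modes ± 0.5 Å and
refuses unimodal histograms; manual thresholds always take precedence.
No claim is made that auto-thresholds reproduce any published occupancy
fraction. Binding events are maximal runs within cutoff, dropping runs
shorter than the dwell minimum; with dwell 1 the bound fraction equals
contact occupancy by construction.

## Synthetic data

Every generator is a pure function of (parameters, seed) — regeneration
is bit-identical — and returns a `SyntheticTruth` record sufficient to
score recovery without re-reading generator code. Noise is additive
Gaussian; SNR definitions are written into the truth record. One global
seed namespace (default 20230830) with fixed per-generator offsets.

- **I–V families** use the GHK *flux* (constant-field current) equation
  per ion so the noiseless zero-current voltage coincides analytically
  with the GHK voltage-equation reversal; this flux form is a
  generator-side assumption only — the analysis side never depends on it.
  Gating is mono-exponential (τ_on 10 ms, τ_off 20 ms), the default grid
  −96…+4 mV in 10 mV steps.
- **Photocurrents** are gated multi-exponential traces; the off-decay
  components are the ground truth for kinetics fitting, with optional
  desensitization during light.
- **Trajectories** use a minimal topology (TYR 222 OH probe against a
  TRP 102 anchor, one K⁺, waters, an ASP 116/THR 120 site). The probe
  distance follows an exactly discretized two-state Markov chain with
  0.2 Å Gaussian jitter; shell waters keep persistent directions; the
  ion follows an explicit binding schedule with per-state hydration
  counts. Frames emulate 200 ps save intervals. None of this pretends to
  be force-field physics: it reproduces the *observables'* statistics
  (state occupancies, coordination counts, contact runs), which is what
  the metric code consumes.

What passing tests show, and what they do not: synthetic recovery
demonstrates the estimators are correct and well-calibrated under their
stated noise models. Real recordings add baseline drift, series
resistance, instrument response, spectral baselines and force-field
artifacts that are explicitly out of scope here.

## Numerical choices and limitations

- All fits operate in log-parameter space (τ, rates) for positivity and
  conditioning; ties and degeneracies warn rather than fail where a
  defensible convention exists, and fail loudly where none does.
- The eigen-propagator clips populations at −1e−8 to suppress roundoff
  negatives; anything more negative is passed through for the caller to
  see.
- CSV round trips are stable to 12 significant digits; XYZ coordinates
  to fixed 1e−6 Å formatting.
- The photocycle module assumes irreversible first-order steps and a
  single photoexcitation at t = 0; excitation-pulse deconvolution,
  reversible steps at equilibrium, anisotropy and temperature dependence
  are not modelled.
- `fit_target_scheme` cannot resolve the chain-permutation ambiguity of
  sequential schemes from one dataset; the reported assignment reflects
  the data-driven initialization (fast rates on early intermediates).
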