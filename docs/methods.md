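# Methods

## Scope

`camfret` implements two things: (1) the quantitative analysis pipeline for
ratiometric FRET kinase-sensor experiments — plate-reader CaM dose-response
runs, somatic multiplexed FRET/Ca²⁺ trace kinetics, dendritic-spine
quantification, frequency tuning and pharmacological dose-response — and
(2) a mechanistic synthetic-data generator that stands in for the
unavailable raw recordings, so the pipeline can be validated end-to-end
against known ground truth and against the published summary statistics.

## The kinase activation model

Subunits of the holoenzyme occupy three states: autoinhibited
(fraction 1 − B − P), Ca²⁺/CaM-bound (B), and autonomous (P; T286-
phosphorylated, active after CaM dissociation):

    dB/dt = k_on·cam·(1 − B − P) − k_off·B − k_auto·B·(B + P)
    dP/dt = k_auto·B·(B + P) − k_dephos·P
    cam   = cam_tot · ca^h / (ca^h + K_cam^h)

Assumptions and rationale:

* **Minimality.** This is the smallest scheme that exhibits the two
  signatures the assays measure: supra-linear frequency dependence (via the
  inter-subunit autophosphorylation term k_auto·B·(B+P): a bound subunit
  must meet an active neighbour) and persistence of activation after the
  Ca²⁺ transient (via the slowly dephosphorylated P state). Holoenzyme
  geometry, CaM trapping as a separate state, inhibitory T305/306
  phosphorylation and intracellular diffusion are deliberately out of scope.
* **Mass conservation.** Autophosphorylation converts B into P, so
  A = B + P ∈ [0, 1] for any input; this invariant is asserted on random
  protocols in the test suite.
* **Arbitrary Ca²⁺ units.** Absolute neuronal Ca²⁺ and CaM concentrations
  are unknown; the Ca²⁺ axis (and K_cam with it) is an arbitrary unit fixed
  by the Ca²⁺ model below, and cam_tot = 1 in neurons by convention. Only
  relative, between-genotype statements survive this convention, which is
  all the phenotyping requires. In the lysate assay, cam_tot is the added
  CaM concentration in µM and the Ca²⁺ step saturates the Hill term, so the
  CaM axis there is physical.

Integration is fixed-step classical Runge–Kutta on the Ca²⁺ grid
(dt = 2 ms, always ≤ one tenth of the frame interval); halving the step
changes A(t) by < 0.1 % sup-norm (tested).

## The Ca²⁺ model

Each uncaging pulse adds a fixed increment that decays mono-exponentially
toward baseline; increments superpose and the total is clipped at a
saturation ceiling at pulse instants. Defaults (pulse amplitude 0.07 a.u.,
tau 2.0 s, ceiling 1.6 a.u.) were chosen once so that (i) the rendered
Ca²⁺-indicator response under 50 pulses @ 20 Hz peaks near ΔF/F₀ ≈ 2 with a
sub-second half-rise, and (ii) the per-frequency plateau levels
(2.5/5/10/20 Hz → ≈ 0.39/0.74/1.47/1.6 a.u.) straddle the genotype
half-activation constants, which is what makes frequency tuning emerge from
the kinase model rather than being painted on. The indicator reads Ca²⁺
linearly (gain 1.25 per a.u.).

## Rendering and noise

CFP = cfp₀(1 + g·A), YFP = yfp₀(1 − g·A) around a baseline ratio of 0.55,
RFP linear in Ca²⁺; constant background (100 counts on a 1000-count
channel baseline), optional mono-exponential photobleaching, Gaussian
per-frame noise, and additive positive artifact spikes in every channel at
frames whose exposure window overlaps an uncaging pulse (stray 355-nm
light raises all detectors). Somatic acquisition is 25 Hz / 10 ms
exposure; spine acquisition 4 Hz / 100 ms.

Noise is split into two components with different roles:

* **Frame noise**, SD 4 counts (0.4 % of baseline). The assay's peak metric
  is a max-over-window statistic, so frame noise biases it upward; at 0.4 %
  the residual bias through the full pipeline is ~2 % (it was the dominant
  error at higher settings). This corresponds to the shot-noise-limited
  regime of the bright somatic ROIs the assay uses.
* **Between-neuron variability**, the dominant spread in real cohorts:
  lognormal mean-one factors on the FRET response gain (CV 0.15), the
  indicator gain (CV 0.15) and the CaM off-rate (CV 0.08), drawn per neuron
  from a seeded stream (`default_rng([base_seed, i])`), making cohorts
  bit-reproducible.

## Genotype presets and calibration

All genotypes share the kinetic scaffold (k_on = 1.0 /(µM·s),
k_off = 0.35 /s, k_dephos = 0.05 /s, h = 4, fret_gain = 0.25); genotypes
differ through K_cam and k_auto (plus baseline_ratio / fret_gain for the
elevated-baseline mutant and a per-genotype Ca²⁺-response scale for mutants
with reduced evoked Ca²⁺; the T286 proline mutant has k_auto = 0, since a
proline cannot be phosphorylated).

WT and P212L are **calibrated**: `calibrate_preset` adjusts (K_cam, k_auto)
until the *noise-free* full-pipeline outputs under the somatic protocol
match the published group means — peak ΔR/R₀ 0.28 / half-decay 7.4 s for
WT, 0.44 / 11.0 s for P212L — to within 0.3 % (a Nelder–Mead stage handles
the frame-quantized half-time objective, followed by a bounded
least-squares polish; calibration fails loudly above 10 % residual).
Calibrating through the pipeline, not on the latent activation curve,
matches the targets in exactly the units the assay reports. Everything
else — half-rise times, the entire 30-pulse frequency-tuning surface, the
plate-assay ordering, F50, the memantine curves — is then a prediction of
the calibrated model, not a fit. The other eight mutants are encoded as
documented qualitative shifts around WT (facilitated mutants: lower K_cam,
slightly higher k_auto; near-WT mutant: unit shifts; attenuated/elevated-
baseline mutants as above); they reproduce phenotype classes, not printed
numbers.

The memantine model is a multiplicative reduction of the per-pulse Ca²⁺
increment, factor 1/(1 + dose/IC50_sim) with IC50_sim = 15 µM, solved once
so that the simulated indicator response at 10 µM is 0.6 of vehicle (the
observed attenuation at that dose); `calibrate_memantine_ic50` re-derives
it.

## Analysis pipeline decisions

Processing order is background subtraction → artifact repair → 5-point
centered rolling average per raw channel → ratio → baseline normalization,
following the assay description; robustness to the alternative order
(ratio before smoothing) is asserted (< 1 % peak change on noise-free
data), not assumed.

* **Artifact detection** (threshold value unstated in the assay): a frame
  is artifactual when any raw channel exceeds its local median + 5×MAD over
  a ±1 s window *and* the frame lies within one frame of a scheduled pulse;
  without a schedule the gate is dropped. Flagged frames are linearly
  interpolated from the nearest clean neighbours in all channels (edge
  frames take the nearest clean value). On simulated truth the detector
  reaches ≥ 95 % recall at ≤ 1 % false positives for 10×noise artifacts.
  Interpolating across contaminated frames during a steep rise slightly
  advances fast half-rise estimates (visible for P212L, ~0.2 s); peak and
  decay metrics are unaffected.
* **Half-times** use the midpoint definitions with strict comparisons
  (frames exactly at half-peak belong to neither set); a trace that never
  decays below half-peak before the recording ends is reported
  undetermined and excluded from group means rather than extrapolated.
* **Peak window** is exactly 20.0 s ("about 20 s" in the assay),
  configurable; the baseline window is recording start to stimulus onset.
* **Dose point**: the three frames strictly before the EGTA-addition frame
  (the addition frame itself may be disturbed).
* **Probe equalization** returns multiplicative factors normalizing each
  well's blank-corrected direct-YFP read to the group minimum — dilution
  with empty-vector lysate can only reduce signal, so factors are ≤ 1.
  Expression groups (low/high) are carried as labels; cross-group
  comparisons are not performed.
* **Spine QC**: the post-stimulation window for the 85 %/90 % darkening
  filter is the same 5-frame window used for the peak (the assay leaves it
  unstated); the darkening filter is evaluated before the dim-indicator
  filter so every spine lands in exactly one category. "Sigma (radius) = 1"
  Gaussian filtering is σ = 1 px truncated at 4σ; the default cellular-mask
  threshold is border median + 5×MAD of the baseline acceptor image.
* **F50** is the log-frequency linear interpolation of the mean-amplitude
  curve at half its maximum. Interpolating the curve values (rather than
  taking the midpoint of the bracketing frequencies) is required for the
  statistic to order genotypes on the coarse 4-frequency grid.
* **Statistics** wrap scipy/statsmodels/pingouin: Student's unpaired t by
  default (Welch behind a flag), two-way ANOVA with per-concentration
  Tukey (studentized-range on the genotype cells within each
  concentration; no extra correction across concentrations), mixed
  between/within ANOVA for tuning (sphericity correction off by default),
  Dunnett many-to-one for doses (cross-checked against an independent R
  reference to ~1e-3), two-sample KS for spine distributions. The Hill
  inhibition fit is descriptive plumbing reported alongside — never instead
  of — the per-dose Dunnett contrasts.

## What the generator does and does not emulate

It emulates: pulse-train-evoked Ca²⁺ transients with saturation, saturable
CaM-dependent activation with slower autonomy-driven decay, uncaging-light
artifacts, shot/read noise, photobleaching, expression-level spread,
spine/shaft geometry with sensor enrichment, plate Ca²⁺/EGTA steps with
blank wells, and NMDAR-level pharmacological attenuation.

It does not emulate: indicator binding kinetics (the simulated Ca²⁺
half-decay, ~1.4 s, is shorter than the ~3 s the indicator reports in
neurons), spatial diffusion or spine-specific biochemistry (spine stacks
reuse somatic activation dynamics, so spine response amplitudes are not
calibrated), motion, bleed-through, or focus drift. Passing tests therefore
demonstrate that the pipeline recovers what it claims from data with these
statistical properties — not that the model is a complete account of
neuronal CaMKII signalling.

## Problem sizes

The validation cohorts mirror the published group sizes: 19 neurons per
genotype for the somatic protocol, 16 for the 30-pulse protocols; plate
simulations use 3–4 replicate wells per (genotype, concentration); null
calibrations of the statistics layer use 200 simulated datasets. The full
suite and the benchmark script each complete in a few minutes on one CPU.

## Known limitations

* Half-time metrics are frame-quantized (±half a frame interval); the
  calibrator works around this, but very fast kinetics at 4 Hz spine
  sampling are coarsely resolved.
* The P212L faster-rise phenotype emerges from its lower K_cam; whether the
  real mutation acts through CaM affinity (K_cam/k_on) or unbinding (k_off)
  is not identifiable from summary metrics, and the preset encodes one of
  the equivalent choices.
* Mutant presets other than WT/P212L are phenotype-class encodings; their
  quantitative outputs should not be compared to printed per-mutant
  numbers.
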