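# Methods

This note documents the models implemented in `aerodose`, the defaults and
units they use, what the synthetic-data generator does and does not emulate,
and the numerical choices that were genuinely open.

## Size-distribution representation

The pipeline's atom is a diameter-binned number-concentration snapshot on a
strictly increasing edge grid (metres everywhere in memory and on disk;
nm/μm only in display). Per-bin concentration (particles·cm⁻³) is the native
storage; the spectral-density dialect dN/dlog₁₀Dp is exposed as a property
(per-bin = density × Δlog₁₀Dp), matching how impactor data are conventionally
plotted. Bin midpoints are geometric means of adjacent edges. The default
grid has 14 log-spaced channels spanning 6 nm–10 μm, the span covered by a
cascade-impactor plus diffusion-charger instrument pair; channel edges are
configurable because real devices differ in their stage layout.

## Number → mass conversion

Per bin, mass (μg·m⁻³) = N·(π/6)d³·ρ(d)·10¹⁵, the constant folding
cm⁻³ → m⁻³ (10⁶) and kg → μg (10⁹). The default density model is the
mass–mobility power law for turbofan nonvolatile exhaust soot,
ρ_eff = 11.92·d^(2.76−3) kg·m⁻³ with d in metres. The unit of d in this law
was verified numerically: metres give ≈ 992 kg·m⁻³ at 10 nm decaying to
≈ 330 kg·m⁻³ at 1 μm — the physically expected range for fractal soot
aggregates — whereas nm or μm produce absurd densities. A constant-density
model and arbitrary callables are accepted for sensitivity work.

Quadrature: d³ρ(d) is evaluated at bin midpoints. On the coarse default
14-channel grid (0.23 decades per bin) this midpoint rule overestimates the
total mass of a GSD ≈ 1.8 mode by several percent; the error falls
quadratically with channel width and is below 1% per refinement step from
~56 channels on. This is intrinsic to processing channelized data (a device
reports bins, not the underlying mode) and is left uncorrected; analyses
sensitive to absolute mass should use finer grids.

## Respirable convention

Penetration efficiency 1 − Φ(ln(d/4.25 μm)/ln 1.5): the simplified
cumulative-lognormal form of the standard respirable convention (median cut
4.25 μm, GSD 1.5). Applying it to a mass distribution yields m_PM4; the
result carries a flag so the convention cannot be folded in twice.

## Simplified lung deposition model

Closed-form fits for the reference light-exercise adult (no nose/mouth
switch), d in μm, natural logs; all coefficients live in one table
(`deposition.ICRP_CONSTANTS`):

* IF = 1 − 0.5(1 − 1/(7.6×10⁻⁴ d^2.8 + 1))
* HA = IF·(1/(1+exp(6.84+1.183 ln d)) + 1/(1+exp(0.924−1.885 ln d)))
* TB = (0.00352/d)·(exp(−0.234(ln d+3.40)²) + 63.9·exp(−0.819(ln d−1.61)²))
* AL = (0.0155/d)·(exp(−0.416(ln d+2.84)²) + 19.11·exp(−0.482(ln d−1.362)²))

Validity range 0.001–100 μm; out-of-range diameters raise rather than
extrapolate, so callers must pre-filter grids.

Known internal imprecision of the fits, reproduced deliberately rather than
patched: the four curves were fitted independently, and HA+TB+AL exceeds IF
by up to ~1% (worst near 1 nm and ~8 μm). No capping is applied — capping
would silently change the published model. Likewise the AL curve is
unimodal only up to ~0.2 μm (diffusion peak near 20 nm); above ~0.26 μm it
turns up again toward the coarse sedimentation mode near 4 μm.

LDSA = Σ N·πd²·AL(d), reported in cm²·m⁻³ (1 μm²·cm⁻³ = 10⁻² cm²·m⁻³). An
optional 20–400 nm band restriction mimics the response window of
diffusion-charger monitors; the default integrates the full grid, and the
two provenances (device-internal vs computed) should not be assumed
interchangeable.

## Exposure and dose summaries

Event windows are half-open [start, end) time slices. Within a window the
per-bin concentration is the arithmetic mean over snapshots (trapezoidal
weights for non-uniform timestamps; identical for uniform sampling). From
the mean distribution:

* n, m, m_PM4 — total number, mass, respirable mass concentrations;
* deposited dose rates DR_N, DR_m = Σᵢ concᵢ·V·DFᵣ(dᵢ) summed over the three
  regions, at V = 25 L·min⁻¹ (light-exercise adult default);
* regional shares = each region's fraction of total deposited, normalized to
  100% (they sum to 100 by construction, regardless of distribution shape);
* per-event totals = DR × window duration.

DR_N/DR_m are defined as **deposited** (HA+TB+AL) rates so that
particles-per-event = DR_N × t holds as an identity; the raw inhaled rates
(concentration × ventilation, no deposition weighting) are available
separately as `inhaled_dose_rates`. Field exposure tables built by other
groups sometimes mix the two conventions and are then internally
inconsistent row by row; this package freezes the deposited-dose reading and
does not attempt to reconcile such tables.

The mouse route bypasses the human curves entirely: alveolar dose =
concentration × duration × ventilation × scalar alveolar mass fraction, with
defaults 1.8 L·h⁻¹ (resting mouse) and 0.096 (alveolar mass fraction of the
exposure distribution). Workday equivalence divides an instilled bolus by
the per-workday deposited dose and rounds to the nearest integer (the raw
ratio is returned alongside).

## Synthetic aerosol generator

The generator defines the study conditions for every downstream test. It
emulates:

* multimodal lognormal number size distributions (exact per-bin integrals
  via CDF differences; GSD = 1 is the monodisperse degenerate case);
* an event timeline — a steady background track plus non-overlapping
  foreground windows (plane-leaving, plane-arriving, fuel-truck) with step
  or instant-rise/exponential-decay temporal profiles;
* instrument artifacts — rebinning onto device channels by log-diameter
  overlap (exact for nested edges), multiplicative lognormal counting noise
  (ln-space sigma per reading, independent across channels and steps), and
  hard saturation with a clipped-fraction report. Scalar devices report the
  grid-integrated total and saturate at 10⁶ cm⁻³; channelized devices at
  10⁸ cm⁻³.

Preset scenarios encode order-of-magnitude levels only (background
~2×10⁴ cm⁻³, engine-event peaks ~10⁷–10⁸ cm⁻³, apron background bimodal at
<20 nm and ~140 nm totalling 2.2×10⁴ cm⁻³): no deposited raw record exists
to calibrate them further, and they are labeled illustrative. The generator
does **not** emulate shelter ventilation dynamics, impactor collection
efficiency curves (sharp cuts only), charge/detection physics, instrument
drift, or correlated noise — so green tests demonstrate the correctness of
the computation chain under the assumed statistical structure, not the
fidelity of any specific field campaign.

Randomness: every operation takes an explicit seed; the pipeline derives
child seeds from one root via `SeedSequence(root, spawn_key=(stream,))`
(stream 0 truth, 1 channelized device, 2 scalar device, 3 scalar fixtures).
Identical inputs and seed give bit-identical outputs.

## Composition tables

CSV columns `analyte, value, uncertainty, unit`. The token `ND` means not
detected; slash pairs `x/y` are replicate measurements kept individually and
summarized as the mean of detected replicates, with a flag when replicates
disagree on detection (the convention for such mixed pairs is not
standardized; both raw values are always retained). ΣPAH sums detected
values with ND = 0 and reports the ND count. The combined
benzo(b)+benzo(k)fluoranthene entry is a single analyte, as reported by the
GC-MS panel. Profile comparison emits per-analyte ratios for mutually
detected analytes (ND pairs flagged, never ratioed) with a default 3×
enrichment filter.

The packaged metal table transcribes a semi-quantitative ICP-MS panel whose
source formatting is ambiguous in a few cells (run-together digit groups);
the entries used in tests (notably Cu, and the Mg/Al/Cu/Zn/Sr/Pb enrichment
pattern) are unambiguous.

## Dose–response trend statistic

For dose groups (meanᵢ, semᵢ, nᵢ) with centered scores
cᵢ = doseᵢ − Σnᵢdoseᵢ/Σnᵢ: contrast L = Σnᵢcᵢmeanᵢ,
SS_linear = L²/Σnᵢcᵢ², SS_between = Σnᵢ(meanᵢ−grand)²,
SS_within = Σ(nᵢ−1)(semᵢ√nᵢ)². Two normalizations are reported side by
side because published "alerting R²" values do not always state which was
used: `between_r2` = SS_linear/SS_between (equals the R² of an OLS fit of
group means on dose for equal n) and `total_r2` =
SS_linear/(SS_between+SS_within). Dose scores default to actual instilled
masses, not ranks. Degenerate all-equal-means layouts report R² = 0 with a
flag instead of 0/0. Requirements: ≥ 3 groups, distinct doses/scores.

The packaged day-1 lavage cell-count series use n = 6 per group, including
the pooled vehicle control (its true pooled n is larger but unreported);
the total-variance R² for the neutrophil series lands at ≈ 0.83 (jet
shelter), within the 0.76–0.95 band reported for such series, and this band
comparison is logged rather than asserted.

## Degenerate inputs and tie-breaks

* Empty series, empty scenarios, windows outside the sampled span, and
  windows catching no snapshot raise with the offending label.
* `geometric_summary` floors values below a detection limit (default: the
  smallest positive observation) before the log transform and reports the
  floored count; GSD uses the sample (n−1) denominator and is 1 for n = 1.
* Double application of the respirable filter raises.
* Monodisperse modes assign all number to the bin containing the GMD
  (half-open bin membership).
* Deposition and density laws are applied to the instrument-native diameter
  without aerodynamic↔mobility conversion; the `diameter_kind` field
  preserves provenance and this is a documented limitation.

## Problem sizes

Tests and the acceptance script run the two-cycle shelter scenario at 5–10 s
steps (360–720 snapshots on 14 channels), 1000-draw scalar series for GM/GSD
recovery, and 10⁴-draw property tests — sizes chosen so the whole suite
exercises every code path in seconds while keeping Monte-Carlo tolerances
a small multiple of the standard error.
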