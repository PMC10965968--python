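# Methods

`snarephys` packages two inference engines used to study how tomosyn-family
inhibitors act on the neuronal membrane-fusion machinery: (1) analysis of
single-molecule optical-tweezers recordings of SNARE/template-complex folding,
and (2) kinetic modelling of synaptic vesicle release measured by hypertonic
sucrose and stimulus trains. This note documents the models, the defaults and
why they were chosen, what the synthetic data emulate, and the numerical
choices that matter.

## Dumbbell mechanics

The construct is a series dumbbell: trapped bead — DNA handle — protein
(unfolded polypeptide in series with a folded core) — trapped bead. Chain
elasticity uses the Marko–Siggia interpolation

F(x) = (kBT/P) [ ¼(1 − x/L)⁻² − ¼ + x/L ],

with the extensible correction x/L → x/L − F/S applied to the DNA handle only
(`stretch_modulus S`); unfolded polypeptide is treated as inextensible. This
is the standard treatment for kbp-scale handles and short peptides; the exact
WLC partition function buys nothing at the forces of interest (2–20 pN).

Defaults (all configurable through `DumbbellConfig` / the JSON `RunConfig`):

| parameter | default | note |
|---|---|---|
| DNA persistence length | 50 nm | canonical B-DNA value |
| DNA contour length | 770 nm | ~2.3 kbp handle |
| DNA stretch modulus | 1000 pN | typical for dsDNA |
| peptide persistence length | 0.6 nm | field-standard for unfolded polypeptide |
| contour per residue | 0.365 nm/aa | crystallographic Cα–Cα spacing |
| folded-core offset | 2.0 nm | rigid extension of a folded four-helix core |
| 1/k₁ + 1/k₂ (traps) | 10 nm/pN | two ~0.2 pN/nm traps; enters only the fixed-separation ensemble |
| temperature | 296 K | room temperature; kBT = 4.087 pN·nm |

The inverse (extension at force) is obtained by bracketed Brent root finding
with 1e-9 nm tolerance and a 200-iteration cap. Stretching energy uses the
closed-form Marko–Siggia integral for inextensible chains and 48-point
Gauss–Legendre quadrature of the root-solved force for extensible chains;
both agree with adaptive quadrature to better than 1e-6 relative.

## Energy landscape, occupancies, rates

A folding state n is (l_n, G_n, c_n): unfolded contour length, zero-force
free energy relative to the fully unfolded reference (in kBT), and core
offset. In the fixed-force ensemble the total energy is

V_n(F) = G_n + [E_handle(F) + E_peptide(F; l_n) − F·x_n(F)] / kBT,

occupancies are Boltzmann over V_n (computed with log-sum-exp; stable to
±700 kBT), and transition rates follow Kramers' form
k = A·exp(−(V‡ − V_from)) with the transition state parameterized like a
folding state (l‡ between the contours of the connected pair). Detailed
balance k_fwd/k_rev = exp(−ΔV) holds exactly by construction. States form a
sequential chain; direct transitions skipping a state are disallowed, which
matches the observation that direct transitions between the outermost states
are negligible.

The attempt frequency A is shared per ensemble and log-parameterized where
fitted; the measurements constrain only barrier-height/prefactor
combinations, so A is a scale choice, not an inference target.

### Zero-force extrapolation

`fit_landscape` minimizes weighted least squares over the force-dependent
state extensions (σ = 0.2 nm), occupancies on the logit scale (σ = 0.3) and
— when the series carries measured rates and the starting ensemble defines
barriers — log transition rates (σ = 0.3), with G_n (non-reference states)
and l_n (all states) free, plus barrier energies and a shared log attempt
frequency in the rate-aware case. Extensions pin the contour lengths; the
force dependence of the logit occupancies then determines the zero-force
energies; rates constrain only barrier/prefactor combinations (G‡ and ln A
are exactly degenerate at fixed barrier contour), which is why the recovery
pipelines, whose targets are state energies, run the fit without rate terms
by starting from a barrier-free data-driven ensemble. The zero-force
unfolding energy of state n is reported as G_ref − G_n (reference = largest
contour, fixed at 0), i.e. the fitted G evaluated at F = 0 with the trap term
dropped.

Starting values come from the data (`initial_ensemble_from_series`): contours
inverted from the median-force extensions, energies from the observed
occupancy ratios minus the model stretch terms. Standard errors come from
seeded bootstrap resampling of the force rows (default 200 replicates;
resamples with fewer than 3 distinct forces are redrawn). Non-convergence is
flagged on the result, never raised; the Jacobian condition number is
reported.

## Trajectory segmentation

Constant-force extension recordings are segmented with a Gaussian-emission
HMM. Baum–Welch and Viterbi are delegated to `hmmlearn`; the wrapper owns
initialization (means spread between the 0.1 and 99.9 percentiles, which
places a component near rare extreme states), seeded jittered restarts after
degenerate solutions (vanishing emission sd or an empty state), the full
per-iteration log-likelihood history (asserted non-decreasing in tests), and
the sorted-by-extension state convention. Convergence: ΔlogL < 1e-8 or 500
iterations. For recordings longer than 1.2 M samples, EM runs on the leading
window of that length and the whole trace is Viterbi-decoded with the
estimated parameters — the standard two-pass treatment for long recordings.

Dwells are maximal runs of the Viterbi path; the first and last (censored)
dwells are excluded from lifetime means. Rates are transition counts over
occupancy time, k_ij = N_ij / T_i, which is robust when rates are far below
the sampling rate; the per-sample transition matrix is retained for
validation only. No missed-event correction is applied: at ≤100 s⁻¹ rates
and 10 kHz sampling the bias is small, though it is visible as a mild
(~10–15%) underestimate of fast-rate ratios in the timescale-separation
recovery. State-count selection uses BIC over candidate fits (ties go to the
smaller model).

Rip detection in pulling curves thresholds the lagged difference of a
5-sample boxcar-smoothed extension at 6 × 1.4826 × MAD above the ramp
baseline, with a 2 nm minimum jump and merging of crossings closer than
5 samples. The force reported is the one immediately before the jump.

## Synthetic trajectories

State dynamics are simulated as an exact (event-driven) continuous-time
Markov chain and rendered through the dumbbell model at the instrument's
acquisition chain: 20 kHz with 1.2 nm white Gaussian noise, mean-filtered to
10 kHz (slow two-state systems are filtered further where noted). Each
generator draws from a named substream of one seed, so adding a generator
never shifts another's stream; outputs are bit-reproducible.

Truth parameters are the reported measurement values frozen in
`fixtures.REFERENCE_VALUES` (unfolding energies 5.1/3.1/2.6/23/35 kBT,
lifetimes 0.014/0.7/1.6 s, extension steps 5.4/1.5 nm, ~400-fold CTD/NTD
rate separation, fusion-barrier shifts −1.11/−0.77 RT, Hill Kd 1.3/1.7 mM).
Contour-length differences between fixture states are solved so the dumbbell
model reproduces the reported extension steps at 5 pN, the center of the
reported formation-force range. The reported lifetimes and rates of the
template-complex system are not mutually consistent as one rate matrix
(plausibly summarized at different forces); they are kept as separate
per-quantity truths. The lifetime-recovery simulation builds its CTMC
directly from the reciprocal lifetimes, splitting the unreported branching of
the middle state evenly. Barrier heights in Kramers-driven fixtures are
anchored so the pair's geometric-mean rate at the measurement force equals
the documented scale (fast open-syntaxin exit; CTD hopping 100 s⁻¹ with the
NTD pair exactly 400-fold slower).

What the synthetic data do not emulate: instrument drift, bead rotation and
hydrodynamics, 1/f noise, force-clamp feedback artifacts, missed-event
structure beyond finite sampling, and day-to-day tether variability. Passing
recovery tests therefore demonstrates correctness of the inference chain
under the model's own assumptions, not robustness to every artifact of real
recordings.

## Vesicle-state model

A single primed pool R (nC) obeys dR/dt = k₁ − k₋₁R − k₂(t)R with
k₂(t) = k₂,rest·exp(β·c(t)); the sucrose drive c(t) rises as
1 − exp(−(t−onset)/τ) during the 7 s application and decays exponentially
with the same τ afterwards. This saturating form is the minimal choice
consistent with barrel perfusion and is config-swappable. The recorded
current is the release charge rate k₂(t)·R(t); carrying the pool in charge
units avoids a quantal-size parameter during fitting (the mini charge enters
only the 0 mM resting rate, k₂ = mini frequency × mini charge / RRP).
Integration uses LSODA with 1e-9 nC absolute tolerance.

Defaults (control-like): k₁ = 0.02 nC/s, k₋₁ = 0.04 s⁻¹,
k₂,rest = 6×10⁻⁴ s⁻¹, τ = 0.4 s, giving a resting pool of ~0.49 nC —
typical of an autaptic culture. 250 and 500 mM sucrose differ only through β
(k₂,max = 0.35 and 3.5 s⁻¹ control-like); the tomosyn-deficient condition
multiplies k₂,max by e^1.11 (250 mM) or e^0.77 (500 mM) with the pool
unchanged. Fitting frees (k₁, β, τ) in log space and fixes (k₋₁, k₂,rest),
which a single trace cannot constrain; the fit reports the
priming-corrected RRP (the model's resting pool), k₂,max, and barrier shifts
via ΔEa = −ln(k₂,max/k₂,reference) in RT units.

## Train metrics and calcium dependence

EPSC amplitudes and charges are positive magnitudes of inward currents. PPR
is A₂/A₁; the short-term-plasticity ratio is A₅/A₁ of a 10 Hz, 5-pulse
train; recovery fraction is the recovery-pulse amplitude over the first train
amplitude. The back-extrapolated RRP regresses cumulative released charge on
time over the last 20 pulses of an 80-pulse 40 Hz train (steady-state
portion); the intercept is the pool, the slope the refill rate. mEPSC
detection uses a 1 s block-median baseline, a 4-MAD threshold on a 0.5 ms
smoothed residual, a 1 ms minimum event width (rejects single-sample noise
spikes) and 5 ms minimum separation. Calcium dependence is fitted with the
Hill equation A·cⁿ/(Kdⁿ + cⁿ) on responses normalized to the 2 mM flanking
response; the Hill coefficient of the synthetic truth is 2 (reported as
unchanged between genotypes but not printed — a documented assumption).

## Problem sizes of the recovery checks

Recoveries run at desk scale rather than the full experimental recording
bank: 5 forces × 80 s for the three-state template system (~40–120 slow
transitions per force); 5 × 30 s (CTD) and 5 × 240 s (NTD, ≥50 slow dwells
per side); one 900 s recording for the lifetime/offset analysis (~300
completed dwells of each bounding state); 10 noisy trace pairs at SNR 20 for
the fusion-barrier shift; 600 s at 2 kHz for the CTD/NTD separation; 20
replicates for the Hill Kd. At these sizes the recovered values sit well
inside the tolerances stated in the tests.

## Known limitations

- The HMM assumes Gaussian emissions and exponential dwells; non-Markovian
  dynamics or drift would bias lifetimes.
- No missed-event correction; rate ratios involving ~100 s⁻¹ rates at 2 kHz
  effective sampling are mildly underestimated.
- The landscape fit treats per-force observations as independent; serial
  correlation within a trace is absorbed into the residual weights.
- The vesicle model has one pool; slowly-releasable or calcium-coupled pools
  are out of scope, as are barrel-perfusion fluid dynamics.
- FEC simulation is quasi-static (rates evaluated at the instantaneous
  force); loading-rate-dependent barrier reshaping is not modelled.
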