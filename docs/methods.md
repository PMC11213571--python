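# Methods

## Scope and data model

The package analyzes whole-cell current-clamp recordings organized as
per-cell *sweep bundles*: a 10-s zero-current recording (spontaneous
activity / resting potential), a family of 1-s de- and hyperpolarizing
current steps delivered from a −60 mV holding potential, current ramps, and
a 5-ms hyperpolarizing pulse for the membrane time constant. Units are
canonical internally (mV, pA, s) and reported on the conventional scales
(MΩ, pF, ms). Sweeps are kept on a strictly uniform time grid at 10–20 kHz;
sweeps containing NaN samples are rejected rather than repaired, because
interpolation would corrupt the slope-based criteria below. The on-disk
format is a versioned JSON manifest plus one TSV table per sweep; SWC is
used for reconstructions.

## Feature definitions and estimator conventions

**AP detection.** Candidate peaks are local maxima above a −20 mV floor
(the floor exists only to keep noise peaks from seeding events; the
scientific criterion is the slope). The onset is the first sample of the
contiguous pre-peak run where the centered-difference dV/dt on the *raw*
trace reaches 5 V/s; no smoothing is applied by default because the
criterion is defined on the raw slope. The offset is the first post-peak
sample at or below the onset voltage. Events whose offset is not reached
before the next onset or the sweep end are flagged truncated and excluded
from per-cell averages. Amplitude is onset-to-peak; duration is
onset-to-offset (not a half-width).

**AHP.** The trough is the minimum between the AP offset and the next
onset (or end of the stimulus). The end is found with a 50-ms window slid
sample-by-sample from the trough; the first window whose ordinary
least-squares slope magnitude is ≤ 0.005 V/s marks the end (its left
edge). The magnitude of the slope is used, which makes the criterion
robust to noise-induced sign flips in an almost-flat recovery. The search
is implemented with O(n) running sums; tests verify exact agreement with a
brute-force per-window `polyfit` scan. If the criterion is never met
before the next spike, the AHP is flagged unbounded and excluded from
averages.

**Rate-matched AP statistics.** AP and AHP metrics are averaged over the
events of the step sweep whose evoked rate (spike count over the 1-s step)
is closest to the cell-type target rate and within ±0.3 Hz of it (1 Hz for
serotonergic-like, 2 Hz for dopaminergic-like cells); ties break toward
lower current. The first-spike delay is measured on the same sweep.

**Passive properties.** Steady-state voltage is the mean from 0.5 s after
step onset to step offset. Input resistance is the OLS slope of
steady-state voltage vs. injected current over steps whose steady state
lies in [−90, −50] mV; sweeps with evoked spikes are additionally
excluded, since their steady-state mean is spike-contaminated (the
estimator flags that contamination explicitly). Sag is the mean of
(steady state − minimum of the first 0.5 s) over steps that settle at
−90 ± 5 mV, clamped at zero for monotone responses. The time constant
comes from a single-exponential fit `v = K0 + K1·exp(−(t − t0)/K2)` to the
pulse recovery, from 1 ms after the negative peak until the voltage first
returns to the pre-pulse baseline; τ = K2. This offset-exponential
parametrization is the only dimensionally consistent reading of the
fitted form (K2 must carry time units to be a time constant). The
return-to-baseline point is judged on a 1-ms boxcar-smoothed copy of the
trace so that a single noise excursion cannot truncate the fit window; the
fit itself uses raw samples. Fits that do not converge, or give τ outside
(0.1, 500) ms, are unresolved. Capacitance is C = τ/R (ms/MΩ → nF,
reported in pF), an exact identity whenever both inputs exist.

**Missingness.** Every estimator degrades to an explicit "unresolved"
status; the per-cell panel carries presence flags and never silently
substitutes zeros. Downstream, the classification uses complete-case rows
(no imputation rule is defined for this workflow) and reports how many
cells were excluded.

## Classification

Panels are standardized per feature (mean 0, sample SD 1; zero-variance
features raise an error naming the column), decomposed by PCA on the
standardized data (equivalently, correlation PCA), and clustered by
agglomerative Ward linkage on Euclidean distances over the leading
components: the five-feature panel (first-spike delay, AP drop rate,
maximal rise rate, AHP duration, capacitance) on the first two components
with k = 2; the twenty-feature panel on the first three with k = 4. The
twenty features are the panel's numeric fields plus event-level values
(AP threshold/peak/trough voltages, a rebound-spiking indicator, the rate
at the largest step, the minimum voltage of the deepest hyperpolarizing
step, and the spontaneous rate with silent cells scored as a true 0 Hz).
PCA signs follow the convention that each component's largest-magnitude
loading is positive, which makes results deterministic across platforms;
cluster labels are stable under permutations of cells and features up to
relabeling. Purity against known labels is computed by optimal cluster-to-
type assignment (Hungarian algorithm).

## The synthetic-data generator

`raphephys.synth` integrates an adaptive leaky integrate-and-fire model
with exponential-Euler updates on a 0.05-ms grid, decimated to the
bundle's sampling rate (20 kHz by default):

- **Membrane**: C·dV/dt = g_L(E_L − V) + I_h + I_A − w − w_AHP + I(t),
  with g_L = 1/R. For a passive configuration the exponential-Euler update
  reproduces the closed-form RC response to machine precision, which the
  tests exploit as an oracle.
- **AP template**: at threshold crossings a stylized waveform is pasted
  (linear rise at the phenotype's rise rate to the peak, linear fall
  through the onset voltage to the reset), giving exact ground truth for
  amplitude, duration, rise rate, and — via a peak reduction proportional
  to the instantaneous supra-holding current — for the ramp-evoked
  amplitude droop.
- **AHP current** w_AHP: incremented at each spike, exponentially
  decaying; sets AHP amplitude and duration.
- **Adaptation** w: subthreshold coupling a·(V − E_L) plus a per-spike
  increment b with its own time constant.
- **A-type-like current** I_A = −w_max·act(V)·h_A: instantaneous sigmoidal
  activation with depolarization and a slowly relaxing inactivation gate
  h_A that is de-inactivated (primed) at rest. On a depolarizing step the
  primed current clamps the voltage below threshold until it inactivates,
  producing the long, ramping first-spike delays and the
  delay-vs-amplitude monotonicity characteristic of dopaminergic-like
  cells.
- **Ih-like conductance**: sigmoidal activation below −80 mV with a 150-ms
  time constant and −30 mV reversal; produces sag during hyperpolarizing
  steps (monotone in g_h) and post-inhibitory rebound, including rebound
  spiking in the interneuron-like preset.
- **Noise**: additive Gaussian measurement noise on the voltage
  (SD 0.2 mV by default), applied after integration so the dynamics are
  deterministic given parameters and only the recorded trace is noisy.

Because the steady-state I–V curve of a cell with an A-type current can be
non-monotone, the analytic rheobase is computed as the largest
steady-state current barrier between holding and threshold, which reduces
to g·(θ − E_L) for the plain integrate-and-fire case — the closed form the
tests check.

**Protocols.** `make_protocols` provides the fixed default grid (−100 to
+150 pA in 25-pA increments). Recordings in this preparation scale step
amplitudes per cell to a test pulse, and `make_adapted_protocols` emulates
that: hyperpolarizing steps computed to settle near −90/−80/−72 mV (so the
sag measurement has a qualifying step), two subthreshold fractions of the
analytic rheobase, and a ladder of rheobase multiples from 0.93 to 1.85
dense enough that a sweep evoking one or two spikes — the rate-matched
sweep — exists for every phenotype. The sub-unity rungs matter because
adapting cells fire transiently below their asymptotic rheobase.

**Phenotypes.** Four presets span the qualitative profiles relevant to
dorsal-raphe recordings: *serotonergic* (R = 250 MΩ, C = 80 pF, fast
300 V/s rise, long AHP, short delay, negligible droop), *dopaminergic*
(R = 500 MΩ, C = 35 pF, slow rise, shorter AHP, strong A-current delay,
0.08 mV/pA droop, sag), *interneuron-like* (fast narrow spikes, strong Ih
with rebound spiking), and *slow-regular* (serotonergic-like firing with
intermediate passive properties). Cohort builders add between-cell
lognormal variability (CV 0.12) on the passive and AHP/adaptation
magnitudes and draw each cell's intrinsic drive as a lognormal multiple
(σ = 0.3) of its from-rest rheobase, with the population median chosen so
the fraction of spontaneously active cells matches the preset condition
(0.37 for serotonergic and 0.58 for dopaminergic cells under control
conditions, configurable per group to emulate lesion effects). Group
effects are multiplicative or additive shifts on any parameter.

**What the generator does and does not emulate.** It reproduces the
protocol structure, the qualitative phenotype contrasts, measurement
noise, and between-cell variability, so passing tests demonstrate that the
estimators implement their definitions correctly and that the
classification pipeline separates types under realistic effect sizes. It
does not emulate biophysically detailed spike shapes, electrode artifacts,
access-resistance drift, synaptic bombardment, or slow pacemaker dynamics
— real spontaneous serotonergic firing is slower and more regular than the
generator's (whose active cells fire at roughly 0.5–7 Hz), and silent
cells rest closer to threshold than real neurons do. Conclusions about
estimator robustness to those phenomena require real recordings.

## Statistics

Group comparisons follow the gated workflow: each group is tested for
normality with a Kolmogorov–Smirnov test at α = 0.05 using parameters
estimated from the sample (the common-practice variant; no Lilliefors
correction — a deliberate choice, logged at run time, since the gate is
then conservative and routes borderline data to the rank-based tests).
Two groups are compared by unpaired t-test (gate passed) or Mann–Whitney U
(gate failed; exact vs. asymptotic p-values selectable, `auto` by
default); three or more by one-way ANOVA or Kruskal–Wallis. Groups with
fewer than three values fail the gate with a warning. No multiple-testing
correction is applied; every comparison is reported so users can apply
their own. Percentages of spontaneously active cells are computed with
half-away-from-zero integer rounding (11/30 → 37). Null simulations in the
acceptance suite confirm the gated two-group test's type-I error stays
near the nominal 5% (accepted band 2–9% over 1000 replicates).

## Morphometrics

Soma contours are simple 2-D polygons; area uses the shoelace formula (via
the polygon library), perimeter the ring length, and the major/minor axes
come from the ellipse with the same area and second central moments as the
polygon (the image-analysis "fit ellipse" convention, chosen over Feret
diameters to match the tracing workflow); axis lengths are 4√λ of the
covariance eigenvalues. Circularity is 4π·area/perimeter², which is the
orientation of the ratio consistent with the stated range (0, 1] and the
value 1 for circles; the reciprocal form sometimes printed for this index
is simply its inverse. Dendritic trees are analyzed in 3-D SWC
coordinates: primary dendrites are children of the soma root,
bifurcations are non-soma nodes with ≥2 children (a node with c > 2
children counts as c − 1 bifurcations and is logged), terminations are
non-soma leaves, so terminations = bifurcations + stems for binary trees.
Both the total dendritic length and the per-primary-dendrite lengths are
emitted, since either convention appears in practice.

## Numerical choices and problem sizes

dV/dt uses centered differences on the raw grid. The AHP window slope uses
mean-centered running sums (numerically safe for 10⁵-sample sweeps). The
τ fit is a bounded Levenberg–Marquardt (trust-region) fit seeded by a
log-linear estimate. With the default −50 pA pulse the deflection is only
≈2 mV, so single-trace τ estimates under 0.3 mV noise carry a few percent
of irreducible spread; recovery claims are therefore stated for the
Monte-Carlo mean over 100 noisy realizations (the noiseless fit is exact
to <1%). Determinism: all randomness flows through seeded NumPy
generators; identical seeds give bit-identical bundles, panels, and
reports. The acceptance runs use 50 seeds of 30 + 40 cells for the
two-type classification and 10 seeds of 4 × 12 cells for the four-type
classification, sizes at which the simulation-plus-extraction loop stays
comfortably within a desktop-scale compute budget while the purity
estimates are already stable.

## Known limitations

- The rebound-oscillation phenomenon is represented only as a boolean
  rebound-spiking indicator; its frequency content is not quantified.
- The twenty-feature panel is a documented, configurable choice; other
  reasonable enumerations of "all extracted parameters" exist.
- Input resistance measured on cells with active subthreshold
  conductances is an effective (chord) resistance and intentionally
  differs from the generator's leak parameter R; exact parameter-recovery
  guarantees are stated for the passive configuration only.
- The postinhibitory hypoexcitability of dopaminergic-like cells is
  visible in simulated traces but has no dedicated panel field.
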