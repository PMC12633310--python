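# Methods

`fretpharm` implements the quantitative analyses behind a single-molecule
study of ligand-induced GPCR dimerization: the smFRET trace-analysis chain
(detection → corrections → quality control → population quantification)
together with the supporting pharmacology fits and nanocluster statistics.
Because the underlying microscopy and biosensor raw data are not public,
every stage is validated by parameter recovery on synthetic data generated
by the package's own simulators at the study's reported conditions.

## The smFRET model

A surface-immobilized receptor labelled with a donor/acceptor dye pair is
imaged on a dual-view TIRF detector at 100 ms per frame: an 80 s
donor-excitation block (800 frames) followed by a 1 s direct
acceptor-excitation block used to confirm that an acceptor dye is present.
The conformational sensor is modelled as a two-state continuous-time Markov
process with state-specific transfer efficiencies `(E_low, E_high)` and
exchange rates `k_lo_hi`, `k_hi_lo`; the stationary occupancy of the high
state is `k_lo_hi / (k_lo_hi + k_hi_lo)`. For the TM4–TM6 activation
sensor, TM6 outward movement (activation) increases the inter-dye distance,
so the **active state is the low-FRET component**; the simulator's defaults
place the states at E = 0.4 (active) and 0.8 (inactive). Inter-protomer
dimer sensors are static single-state emitters (TM5 sites near E ≈ 0.9,
helix-8 sites near E ≈ 0.5).

Intensities follow the convention in which the corrected efficiency
`E = Ia / (Ia + γ·Id)` recovers the ground-truth state efficiency: a
molecule with photon budget `I` in a state with efficiency `E` emits ideal
donor signal `I·(1−E)` and ideal acceptor signal `I·E·γ`, where γ is the
per-molecule detection-correction factor (ratio of acceptor to donor
detection efficiency × quantum yield). γ is drawn log-normally around 1
(spread 0.15, truncated to (0, 5]); the acceptance band applied during QC
is 0.5–2.5. Donor leakage adds `0.07·Id` to the raw acceptor channel.
Each dye bleaches once, after an exponential waiting time (defaults:
acceptor 1/30 s⁻¹, donor 1/60 s⁻¹, so most acceptors bleach within the
record while the donor usually survives long enough to read out γ).
Camera noise is additive Gaussian per channel with
`sd = I / (SNR·√2)`, making the realized signal-to-noise of the summed
intensity approximately the configured `SNR` (default 10). Poisson shot
noise and Gaussian read noise are available in the movie renderer;
EMCCD excess-noise gain is omitted because none of the corrections invert
the noise model. Blinking is suppressed (matching a COT-containing imaging
buffer) and is not simulated by default.

One deliberate idealization: the direct-excitation (red) block reports
**acceptor presence**, not acceptor survival. Physically a bleached
acceptor is dark under direct excitation, but the selection criteria
*require* an acceptor bleach within the record, so a strictly physical red
block would veto exactly the molecules the analysis keeps. Since the red
block exists to reject donor-only impurities, identity is modelled
directly.

## Trace analysis

1. **Leakage correction.** `Ia ← Ia_raw − 0.07·Id`, linear and reversible.
2. **Step detection.** Penalized least-squares changepoint segmentation
   (PELT, ℓ2 cost; exact for the chosen penalty) with penalty
   `10·σ̂²·ln n`, σ̂ the robust noise level from first differences
   (MAD/√2). A tiny penalty floor keeps the noiseless case well posed.
   Placements agree with exhaustive enumeration — the test suite checks
   this against a brute-force ≤2-step oracle.
3. **Bleach classification.** A segment is "background" when its mean is
   within 4 standard errors of zero (so genuine FRET levels on long
   segments are never mistaken for background). A channel has bleached
   when a trailing run of background segments exists; "single-step"
   additionally requires that background was never visited earlier
   (no blinking/recovery).
4. **γ estimation.** `γ = ΔIa/ΔId` across the acceptor bleach using
   20-frame windows on each side, excluding the bleach frame ± 2.
   Because both channels share the same underlying state path, the
   estimator is exact (to noise) even when the molecule switches state
   inside the window. Fewer than 10 usable frames on either side, or a
   non-positive denominator, makes γ undefined and fails the criterion.
5. **Selection criteria.** (1) SNR ≥ 5, where SNR = mean total intensity
   over the pre-bleach window divided by the residual sd after step-wise
   idealization of the total (insensitive to state transitions);
   (2) single-step acceptor bleach before any donor bleach; (3) γ within
   0.5–2.5; (4) anticorrelated donor/acceptor fluctuations: Pearson
   correlation of the frame-to-frame differences ≤ −0.2, computed over a
   window that **extends through the acceptor bleach step**. The bleach is
   the canonical anticorrelated event; restricting the window to strictly
   pre-bleach frames would reject every static single-state molecule
   (e.g. the inter-protomer sensors) since independent channel noise is
   uncorrelated. (5) single-step donor bleach, vacuously true when the
   donor never bleaches. Every trace receives a report with each
   criterion recorded; acceptance is their conjunction.
6. **Efficiency and histogram.** `E = Ia/(Ia + γ·Id)` per frame over
   frames 0 … (acceptor bleach − 1). Values are binned into 30 intervals
   over [−0.25, 1.25] (left-closed, right-open; last bin closed);
   out-of-range values are dropped from the numerator but count in each
   molecule's normalization, so per-molecule vectors sum to ≤ 1 and to 1
   when all values are in range. The ensemble histogram is the unweighted
   mean over molecules — a 100-frame molecule counts as much as a
   10,000-frame one.
7. **Two-Gaussian fit.** Nonlinear least squares of
   `a₁N(μ₁,σ₁) + a₂N(μ₂,σ₂)` to bin centers vs. averaged frequencies,
   initialized at the two tallest well-separated histogram modes
   (fallback 0.35/0.75), σ initialized at 0.1, bounds μ ∈ [−0.25, 1.25],
   σ ∈ [0.02, 0.5]. State populations are **component areas** normalized
   to their sum (amplitude-based fractions would be an alternative
   reading; areas are the package's choice and are what the recovery
   tests validate). A component with area fraction < 0.03 or width at
   the floor flags the fit degenerate and records a single-Gaussian
   fallback. Frame-level state idealization assigns each frame by
   posterior odds under the fitted components (ties to the lower-mean
   state) followed by a 5-frame median filter.

## Movie processing

Spot detection finds strict local maxima within a 5-pixel square
neighborhood above a robust threshold, with sub-pixel refinement by
intensity centroid (PSF fitting is unnecessary: positions only place
photometry apertures). Detection runs on the average of the first 10
donor-block frames. Channel registration fits a least-squares affine map
over fiducials matched by mutual nearest neighbor within 5 px after a
coarse FFT cross-correlation shift; ≥ 3 non-collinear matches are
required. Donor-only spots are excluded when the mapped acceptor-channel
position shows no direct-excitation signal. Photometry sums a circular
aperture (default radius 3 px) per frame; background is the median pixel
value of the surrounding 35-px-diameter region (aperture excluded) scaled
to aperture area, stored separately so the correction is reversible.
Spots whose background region is truncated by the channel border are
flagged, not dropped. With a 1-px PSF and a 4-px aperture the
render/extract round trip conserves counts to ≲ 0.1 %; the default 3-px
aperture loses a few percent to the PSF tail, which cancels in E because
both channels share the aperture geometry.

## Pharmacology models

All fits are unweighted least squares (replicate-level rows enter
individually). Dose–response uses the three-parameter logistic
`R = bottom + (top − bottom)/(1 + 10^(logEC50 − log10 C))`; zero doses are
excluded from the log-domain fit and only anchor the bottom initial value.
Biosensor kinetics are fit per phase — association
`R(t) = R_eq(1 − e^(−k_obs t))`, dissociation `R(t) = R₀e^(−k_off t)` —
with `k_on` from the linear regression `k_obs = k_on·C + k_off` and
`K_D = k_off/k_on`; equilibrium responses additionally feed a Langmuir
steady-state fit `R_eq = R_max·C/(K_D + C)` (concentrations are rescaled
internally so nanomolar-scale constants do not stall the optimizer).
Radioligand saturation subtracts a through-origin linear nonspecific
component before the one-site fit; competition fits a logistic IC50 and
converts via the classical Cheng–Prusoff relation
`K_i = IC50/(1 + L/K_d)`. Double-referencing (blank injection and
reference surface subtraction) is explicit pre-processing. Ensemble FRET
ratios integrate acceptor over donor emission windows after donor
normalization and are scale-invariant by construction.

## Cluster and mass statistics

Nanoclusters are single-linkage connected components under a Euclidean
cutoff (default 30 nm ≈ 3× a gold-nanoparticle label diameter; the
grouping rule and cutoff are configuration, since no canonical choice
exists). Size distributions are compared with a two-sided Mann–Whitney
rank-sum test (exact for small tie-free samples, normal approximation
with tie correction otherwise; identical constant samples return p = 1 by
convention). Mass-photometry event lists are decomposed by a 1-D
Gaussian-mixture EM with a user-chosen component count
(monomer/dimer/tetramer hypotheses, not automatic selection) and an
optional constraint tying means to integer multiples of a shared monomer
mass; the EM log-likelihood is non-decreasing by construction and the
unconstrained fit is cross-checked against an independent mixture
implementation in the tests.

## Problem sizes and reproducibility

Recovery runs use 300 molecules × 10 seeds per smFRET condition,
150 molecules for the static dimer sensors, 10-concentration × 4-replicate
dose designs over 20 seeds, and the study's stated concentration series
for kinetics (30 nM–10 µM, 180 s association / 300 s dissociation) and
equilibrium SPR (0.6–10 µM). All randomness flows from one integer seed
through `numpy.random.SeedSequence` spawning; identical seeds give
bit-identical outputs.

## Limitations

The simulators omit triplet photophysics, blinking (by default), optical
aberrations, drift, and spectral crosstalk beyond a constant leakage term,
so passing recovery tests demonstrates correctness of the analysis chain
under the stated noise model — not robustness to every artifact of real
recordings. The anticorrelation and SNR definitions, the γ estimator, the
area-based population readout, and the posterior-odds state idealization
are field-standard choices where the procedure admits alternatives; each
is configurable and documented above. Cluster statistics make no claim of
numerical agreement with any particular imaging dataset: the grouping
cutoff is physical configuration, not an inferred quantity.
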