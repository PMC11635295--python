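# Methods

This note records the models, conventions and design choices behind
`nirsdoc`, in the order the pipeline applies them, together with what the
synthetic-data checks do and do not establish about real recordings.

## Optical model and MBLL conversion

Concentration changes couple to optical density through
ΔOD(λ) = [ε(λ,HbO)·ΔHbO + ε(λ,HbR)·ΔHbR]·DPF(λ)·L, solved per sample as a
2×2 linear system.  The shipped extinction table (cm⁻¹ mM⁻¹ at 730/850 nm:
HbO 0.390/1.058, HbR 1.102/0.691) is a conventional two-wavelength default
with HbR dominating below the ~808 nm isosbestic point; DPF defaults to 6.0
at both wavelengths and L to 3 cm.  No partial-volume correction is applied
(factor 1), so concentrations are *relative* μM.  None of the downstream
quantities depend on the overall linear scale: Pearson correlations, and
therefore every network metric, are invariant to per-channel affine maps.

The optical-density baseline I₀ is the **geometric** temporal mean per
channel and wavelength, i.e. ΔOD(t) = −(log₁₀I(t) − mean log₁₀I).  This
zero-mean-log convention makes the forward model (concentrations →
intensity) and the MBLL inversion an exact round-trip pair for zero-mean
concentration series, which the test suite verifies to < 10⁻⁹ relative
error.  An arithmetic-mean baseline would differ by a per-channel additive
constant; correlations would be unaffected either way.

## Channel quality control

Pruning runs on pre-band-pass data (the cardiac band must be intact).  A
channel is bad if **any** rule fires:

* **SNR** — temporal mean / temporal SD of raw intensity per wavelength,
  channel SNR = min over wavelengths; threshold 2.
* **Correlation** — maximum Pearson r against the other channels ≤ 0.
  Two robustness refinements, both configurable: the correlation signal is
  HbT with drift removed (0.01 Hz high-pass), because very-low-frequency
  drift carries only a handful of effective degrees of freedom per
  recording and produces large spurious correlations of arbitrary sign;
  and only channels passing the other two rules serve as partners, because
  a noise-dominated channel correlates with anything at random sign and
  cannot certify another channel's validity.
* **Cardiac** — on the 850 nm intensity spectrum (Welch, 60 s segments,
  median-averaged so motion-spike broadband energy cannot mimic a peak):
  bad if the 0.8–1.6 Hz power fraction is < 0.05 **and** no local spectral
  peak exceeds 5× the median power over 0.5–2.5 Hz.

Pruned channels are dropped (never interpolated); ROI means and group-mean
FC renormalise over the surviving channels, and a region with < 2 active
channels yields a missing value rather than zero.

## Denoising

* Band-pass: Butterworth order 3 (configurable), applied forward–backward
  (zero phase, effective order 6), passband 0.01–0.1 Hz.  HbO and HbR are
  filtered; HbT is recomputed as their sum so HbT = HbO + HbR holds exactly
  after every stage.
* PCA motion correction: across channels, per chromophore, on the full
  filtered series; default 1 component removed (a target variance fraction
  may be given instead).  Removing the leading component also removes most
  of the shared scalp/systemic signal, which is the intended behaviour of
  the correction.
* Stable segment: the contiguous 5-min window minimising the summed
  across-channel energy of the first difference of HbT; ties go to the
  earliest offset, and a fixed offset can be forced for reproducibility.

## Networks

Thresholding keeps the k = round_half_up(s·N(N−1)/2) largest **raw** (not
absolute) correlations at each sparsity s in 0.05…0.80 (step 0.05); rank
ties at the cutoff resolve lexicographically by channel pair, so edge sets
are bit-reproducible.  Metrics on the binary graph: Lp averages finite
shortest-path lengths over ordered pairs (**connected-pairs convention**,
with the excluded-pair count reported — at sparsity 0.05 most graphs are
disconnected and a convention is unavoidable); Cp uses the triangle
formula with node term 0 for degree < 2; Eg sums 1/d with 1/∞ = 0; Eloc
averages the global efficiency of each node's induced neighbourhood.
Curves are summarised by the trapezoidal AUC over [0.05, 0.80] (a constant
curve m gives 0.75·m; sum×step would differ only in endpoint weights).
Distances use breadth-first search (scipy.sparse.csgraph); the tests check
exact agreement with an independent Floyd–Warshall + exhaustive-enumeration
oracle and with networkx on random graphs.

## Statistics and classification

Group comparisons are classical pooled-variance two-sample t-tests
(df = n₁+n₂−2, two-tailed; Welch selectable) with Cohen's d pooled over the
same df.  No multiple-testing correction is applied by default, matching
standard practice for a 10-feature exploratory table; a Benjamini–Hochberg
option exists and the output flags which convention was used.

Classification is leave-one-out: z-score standardisation is refit inside
every fold and applied to the held-out subject, so no information leaks.
KNN (k = 3, Euclidean) breaks distance ties by training index and vote
ties by the single nearest neighbour; LDA is the two-class equal-covariance
Gaussian discriminant with empirical priors, refusing silently
ill-conditioned pooled covariances unless a documented ridge
(λ·mean diag·I) is supplied.  Both are deterministic, so the repeat loop
(default 20) yields identical repeats and the mean equals a single run; the
loop exists because repeated-computation averaging is part of the
evaluation protocol.  MCS is the positive class for
accuracy/sensitivity/specificity.

## CRS-R

Score strings `total(d₁d₂d₃d₄d₅d₆)` parse into the six subscales
(auditory 0–4, visual 0–5, motor 0–6, oromotor 0–3, communication 0–3,
arousal 0–3) with the total validated against the digit sum.  The MCS
column (auditory 3–4 ∨ visual 2–5 ∨ motor 3–6 ∨ oromotor 3 ∨
communication 1–3) and the VS column (all of: auditory ≤ 2, visual ≤ 1,
motor ≤ 2, oromotor ≤ 2, communication 0) are mutually exclusive and
exhaustive over the stored ranges, which `diagnose` asserts.  The
communication subscale clinically tops at 2, but the printed MCS bound
reads "1 to 3"; the stored 0–3 range accepts both conventions verbatim.
Applied to the shipped 18-patient reference table, the rule labels the four
patients with visual = 2 (recorded UWS) as MCS; the agreement flag surfaces
this deliberately rather than "correcting" either side.

## Synthetic cohort generator

The generator defines the study conditions under which every statistical
guarantee is demonstrated.

**Latent coupling.**  Each subject draws a coupling graph with expected
edge density given by its group (defaults: 0.45 MCS-like, 0.22 UWS-like).
Edges fill within-region pairs (the montage's six modules; the two
doubly-listed channels resolve to their left-hemisphere region so L_PFC and
L_OC are clean modules) before spending the remainder on random
between-region pairs.  A uniformly random graph could not work here: at a
fixed thresholded edge count, any exchangeable correlation structure yields
a uniformly random graph for both groups and hence identical metric
distributions.  Concentrating low-density coupling locally is also the
physiologically meaningful choice — the UWS phenotype is loss of
long-range integration with preserved short-range coupling — and it makes
UWS-like thresholded networks fragment into regional clusters (low Eg)
while MCS-like networks stay integrated.

**Mixing model.**  Band-limited (0.01–0.1 Hz) HbT signals are
s = row-normalised (I + γA) z with iid Gaussian z and
γ = (1 − √(1−c²))/c, so an isolated coupled pair has population
correlation exactly c (default coupling c = 0.6) and the full population
correlation matrix is available in closed form for oracle tests.
Uncoupled channels with no common neighbour are exactly uncorrelated;
common-neighbour pairs acquire the indirect correlation any mixing model
implies (an *exactly* sparse strong correlation matrix is impossible — its
positive-definiteness bounds equal couplings by 1/|λ_min(A)|).

**Confounds.**  Added to every channel: a shared systemic 0.01–0.1 Hz
component (0.5 μM), near-phase-coherent cardiac (~1 Hz, 0.6 μM),
respiratory (0.2–0.6 Hz, 0.2 μM) and Mayer-wave (~0.1 Hz, 0.25 μM)
sinusoids with per-channel amplitude jitter and small phase scatter
(coherence mirrors the physiology — systemic pulsations arrive nearly
simultaneously across the scalp — and gives channel pairs the stable
positive correlation floor real recordings show), independent slow drift
(< 0.01 Hz, 0.5 μM), white sensor noise (0.15 μM), and Poisson motion
spikes (0.2/min, 8 μM, 1 s boxcars shared across channels with random
gains).  HbT splits 70/30 into HbO/HbR plus a small antiphase residual,
and the forward optical model (with lognormal per-optode gains) produces
strictly positive intensities.

**Planted defects** map one-to-one onto the QC rules: `low_snr`
multiplies intensity by low-frequency lognormal gain noise (SNR ≈ 1.3);
`no_cardiac` omits the cardiac sinusoid; `anticorrelated` replaces the
channel with −2× a region-balanced common reference (mean of region means,
oscillations included).

**Calibration.**  Densities, coupling and the noise table were fixed once
so that the default cohort's Eg-AUC group effect sits in the intended
moderate-effect regime: at the tightest Monte-Carlo conditions (330-s
recordings) the empirical cohort-level Cohen's d is ≈ 1.1–1.2, rising with
recording length (≈ 2 at 420 s, and far larger at the full 20-min length)
as segment selection gains slack to avoid motion spikes and estimation
noise falls.  Clinical cohorts carry between-patient variability the
generator does not model, so full-length synthetic effects are much
stronger than clinically reported ones.  Known divergences from the
clinical report this generator emulates: the Cp/Eloc group contrasts are
stronger than observed clinically (a by-product of the modular mechanism
that produces the Eg contrast), and the Lp contrast under the
connected-pairs convention is weak and unstable, because fragmented
low-sparsity graphs *shorten* the connected-pairs average — a known
artifact of that convention.

## Monte-Carlo problem sizes

Chosen so each suite runs in minutes on one CPU; all are package defaults
stated here as the package's own design choices.

* Graph-metric oracle: 100 random graphs, N ≤ 12, densities 0.1–0.9.
* QC detection: 100 cohorts × 4 subjects at 600-s duration (at 300–400 s
  the in-band processes carry so few degrees of freedom that pairwise
  correlation signs are not reliably testable).
* t-test calibration: 2,000 disjoint 8-vs-10 label resamplings from a
  200-subject null pool (single generator condition, exchangeable labels).
* Power: 200 independent default cohorts (8 vs 10) at 420-s duration.
* Classification: 200 label permutations; hybrid-ordering comparison over
  50 replicate cohorts at 330-s duration.

## What passing tests show — and what they do not

The synthetic checks establish that the implementation is faithful
(formulas, conventions, round trips, leakage-free cross-validation) and
that the statistical machinery is calibrated and powered *under the
generator's assumptions*: Gaussian band-limited signals, linear mixing,
sinusoidal confounds, stationary coupling.  Real DOC recordings violate
several of these (non-stationarity, heterogeneous DPF and optode coupling,
non-sinusoidal physiology, unknown true networks), so passing here does
not certify clinical performance — it certifies that any failure on real
data would come from the data model, not from the pipeline's mechanics.

## Known limitations

* No short-separation-channel regression, spline/wavelet motion
  correction, or HRF modelling; no biophysical head model.
* Binary networks only; weighted variants and nodal/meso-scale metrics
  (centrality, modularity, small-worldness) are out of scope.
* The CRS-R rule reproduces the printed criteria verbatim, including their
  disagreement with recorded diagnoses at visual = 2.
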