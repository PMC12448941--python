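# Methods

This note documents the scientific and numerical choices behind
`tractgain`: what each stage computes, the assumptions it rests on, what
the synthetic generators do and do not emulate, and where the design was
genuinely open.

## Signal conditioning

Depth-electrode LFPs are assumed to arrive as multichannel sessions
(channels × time, µV) with per-channel metadata: subject, hemisphere, lead,
region label, contact index.  The conditioning chain is:

1. **Mains notch** at 60 Hz and its five harmonics (120–360 Hz).  Each
   notch is a second-order IIR (`iirnotch`) with quality factor Q = 30
   (≈ 2 Hz bandwidth at 60 Hz), cascaded as SOS and applied
   forward-backward, so attenuation at the notch centers is effectively
   doubled and the net phase shift is zero.  Second-order zero-phase
   notches are the conventional choice for mains removal; topology and
   order are configurable.
2. **High-pass** at 1 Hz: 4th-order Butterworth, zero-phase, removing
   electrode drift.  Consequently true DC is unobservable; see "DC gain"
   below.
3. **Decimation** (optional): FIR anti-alias + downsample.  FIR rather
   than the Chebyshev IIR default because the IIR's passband ripple
   doubles under the zero-phase pass and exceeds 1 %.  All analysis
   features live far below 1 kHz, so decimating 24 kHz clinical recordings
   to 3 kHz loses nothing and keeps spectral estimation desk-scale.
4. **Bipolar montage**: within each lead, contacts sorted by contact index
   and subtracted pairwise (contact_k − contact_{k+1}), giving K−1 derived
   channels per K-contact lead and cancelling any lead-wide common signal
   exactly.  "Adjacent" is interpreted as along-shaft neighbors; the
   2–3-contacts-per-row circumferential geometry of the physical lead is
   not reconstructed because contact coordinates are not part of the input.

## Transfer-function estimation

For an ordered bipolar pair x → y, H(ω) = CPSD(x,y) / (PSD(x) + ε) with
Welch averaging: Hann window, 50 % overlap, window length 4 s at the
analysis rate (0.25 Hz resolution — fine enough to place a 1.5 Hz
peak-frequency exclusion on a meaningful grid).  ε defaults to
10⁻⁶ × median PSD(x); it bounds |H| when input power vanishes and biases
the estimate only where PSD(x) is comparable to ε.  |H| is pointwise
non-increasing in ε, and scaling y by c scales |H| by c — both are tested
properties.

Feature extraction:

* ω_p is the argmax of |H| over the grid (optionally restricted to
  ω ≥ min_freq); peak gain is reported both linear and in dB
  (20·log₁₀), so either convention can be consumed downstream.
* **DC gain** is |H| at the lowest available grid frequency (the 0 Hz
  Welch bin).  With a 1 Hz high-pass the true DC response is not
  observable; the lowest-bin convention is stated rather than hidden.
* **ω_f** is the first downward crossing of dc_gain·10^(−3/20) above the
  DC bin, interpolated linearly in (frequency, log₁₀ magnitude) between
  the straddling bins; ties break toward the lower frequency.  If no
  crossing exists within the grid (e.g. a flat response), ω_f, floor gain
  and PF ratio are flagged undefined (NaN) — not an error.
* PF ratio = log₁₀(peak gain / floor gain), where the floor gain is the
  threshold value at the interpolated crossing.

Per-pathway aggregation over all SISO pairs between two regions (same
hemisphere) defaults to the mean, with undefined roll-offs excluded;
median and max reducers are provided because the choice of per-pathway
reducer is genuinely open; the mean is the simplest defensible default.  Per-pair records are always retained for audit.
Phase and delay are deliberately out of scope.

## Tract metrics

FA follows the standard eigenvalue-dispersion formula (bounded in [0, 1],
invariant under uniform eigenvalue scaling); Ad = λ₁; L is the polyline
arc length; N is the streamline count divided by the effective
micro-contact disc area π·(1.5 mm)² — the only area the acquisition
geometry defines.  Per-pathway FA/Ad are unweighted means over
per-streamline tensor samples (length- or volume-weighting would need
information the inputs do not carry); pathway length is the mean arc
length.  Eigenvalue units are taken as given (the printed mm²/s
convention); no unit conversion is attempted.  Empty tract sets are
flagged "no connection" rather than erroring.

## Statistical chain

* **Outlier pass** (single-pass): per subject, mean and SD of each outcome
  feature (PF ratio, maximum gain) are computed once on the incoming
  table; rows deviating by more than 3 SD in either feature are removed.
  The rule is applied to the outcome features rather than the predictors
  by default; the feature set is configurable.  Single-pass (not
  iterative) trimming keeps n predictable.
* **Peak-frequency exclusion**: rows with ω_p < 1.5 Hz are removed because
  the spectrum near the 1 Hz high-pass edge is distorted.  Every removal
  is logged with its reason.
* **VIF screen**: VIF_j = 1/(1−R²_j) from regressing predictor j on the
  others plus an intercept; threshold 5; perfect collinearity reports
  ∞.  The replication policy drops Ad when the FA/Ad pair is flagged
  (their collinearity is structural); a generic policy iteratively drops
  the largest VIF.
* **Mixed model**: outcome ~ FA + N + L + (1 | subject), REML.  The fit
  profiles the REML likelihood over the single variance ratio
  θ = σ_b²/σ_ε²; for the random-intercept model the GLS coefficients,
  residual variance, block inverses (V_i⁻¹ = I − θ/(1+n_iθ)·J) and
  log-determinants are closed-form given θ, so the optimization is a
  bounded 1-D search (|log θ| ≤ 14, xatol 10⁻¹⁰) with an explicit boundary
  check at θ = 0 (flagged, with a warning, as a boundary fit).  A
  single-subject table falls back to OLS with a notice.
* **Satterthwaite df** are computed exactly for this model class: the
  expected REML information I_jk = ½ tr(P V_j P V_k) of (σ_b², σ_ε²) is
  accumulated blockwise, and each coefficient's df is
  2(c′Cc)²/(g′I⁻¹g) with g_j = c′C(X′V⁻¹V_jV⁻¹X)Cc.  The implementation
  is validated against R `lmerTest` (coefficients and SEs to ~10⁻⁴
  relative, df to ~1 %).
* **Multiplicity**: Bonferroni, p_adj = min(1, m·p), with m defaulting to
  the number of non-intercept predictors per outcome (3); counting
  outcomes as well (m = 6) is a defensible alternative, so m is
  configurable.
* **R²** is marginal: var(Xβ̂)/(var(Xβ̂)+σ_b²+σ_ε²).  Bare "R²" is
  ambiguous for mixed models (marginal vs conditional vs squared
  correlation), so the variant is reported by name and the variance
  components needed for the others are stored.

## Synthetic generators

The generators encode the study conditions the analysis assumes and make
every stage testable against known truth.

* **Sessions**: sources are 1/f ("pink") noise — LFP-like spectra — with a
  white option, since spectral slope affects Welch variance but not the
  estimator's expectation.  The first lead carries a unit-SD source u; the
  second carries v = filter(u), a resonant band-pass (`iirpeak`, unit peak
  gain at its center, scaled to peak magnitude 5 at 20 Hz by default, the
  analytic response stored as ground truth).  Contacts are running sums of
  identical bipolar sources, so the montage recovers u and v exactly and
  every cross-lead bipolar pair is linked by the known filter.
  Contaminants: independent per-contact sensor noise (survives the
  montage, SD 0.05), one common-mode component per lead and a mains
  contaminant (60 Hz fundamental, harmonics decaying as 1/k to 360 Hz) —
  both cancelled by the montage, the mains also by the notch.  Defaults:
  fs = 24 kHz (the clinical rate), 120 s, 2 leads × 10 contacts.
* **Tract sets**: prolate triples (λ₂ = λ₃) solved in closed form so each
  triple's FA equals the target exactly (λ₁ jittered ±10 % around 1.35);
  streamlines are smooth constant-step random walks with arc lengths drawn
  in the tracking bounds [10, 200] mm.
* **Coupled cohort**: 12 subjects × 73 pathway observations (876 rows — a
  balanced stand-in for the ~880-observation, 12-patient scale of clinical
  depth-recording cohorts).  Outcome = β₀ + β_FA·FA + β_N·N + β_L·L +
  b_subject + ε with b ~ N(0, 3²), ε ~ N(0, 8²) and default
  β = (34.63, 6.12, 1.44, −0.01), magnitudes representative of
  structure-function coupling effects reported for pallidothalamic
  pathways.  FA ~ U(0.2, 0.6); mean diffusivity ~ N(0.90, 0.02), chosen so
  Ad ≈ 1.35 at FA = 0.40 — typical tract-level values in this territory
  (×10⁻³ mm²/s convention); Ad is the λ₁ of the same triple that produces
  FA, so the FA–Ad correlation (~0.98, VIF ≈ 22) arises mechanically
  rather than from a correlation knob.  Counts ~ DiscreteUniform[1, 150],
  lengths ~ U(10, 200) mm (the tracking bounds).

What the generators do **not** emulate: nonstationarity, artifacts beyond
the modeled contaminants, volume conduction, electrode geometry, crossing
fibres, raw diffusion-weighted images (tensors enter at the eigenvalue
level), or any nonlinearity of transmission.  Passing tests therefore
demonstrate that the pipeline's estimators are correct for
linear-time-invariant transmission with the modeled noise structure — not
that real recordings satisfy those assumptions.

## Problem sizes

Test and demonstration runs use scaled sessions (1–3 kHz sampling, 1–4
minutes) chosen so that Welch estimates still average ≥ 60 segments at
0.25 Hz resolution — the regime where the estimator's accuracy claims
(± 5 % of the analytic response in the passband) are meaningful.  The
mixed-model recovery study uses 200 seeded replicates of the full
12 × 73 cohort.  The end-to-end pipeline runs the signal chain on two
demonstration subjects and the statistical chain at full cohort scale;
generating 880 complete LFP sessions would add compute without adding
verification power.

## Known limitations

* The empirical transfer function assumes LTI transmission; gains can also
  reflect common input to both regions rather than directed transmission.
* The DC-gain convention (lowest Welch bin) interacts with the 1 Hz
  high-pass; roll-off features near the high-pass edge should be read with
  care (hence the 1.5 Hz exclusion upstream of the statistics).
* The mixed model supports a single random intercept per subject — the
  structure the analysis specifies — not random slopes or crossed effects.
* EDF export quantizes to 16 bits and truncates to whole seconds; the
  internal `.npz` container is the lossless path between stages.
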