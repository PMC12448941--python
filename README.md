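# tractgain

Structure–function coupling in deep brain circuits: does the microstructure
of a white-matter pathway predict how well intrinsic neural activity is
transmitted along it?

`tractgain` is a tested, reusable pipeline for researchers working with
depth-electrode (sEEG) local field potentials and diffusion tractography.
It conditions multichannel LFP recordings, estimates empirical transfer
functions between bipolar channel pairs, summarizes each directed pathway
by two transmission features, computes the standard diffusion-tensor tract
metrics, and relates the two sides with random-intercept linear
mixed-effects models.  Because clinical recordings of this kind cannot be
shared publicly, the package ships a first-class synthetic-data module that
generates seeded sessions, tract sets and cohort tables with known ground
truth, so every stage is verifiable end to end.

## The model

**Functional side.**  Recordings are notch-filtered at 60 Hz and its five
harmonics, high-pass filtered at 1 Hz, and re-referenced to an
adjacent-contact bipolar montage (all filters zero-phase).  For every
ordered pair of bipolar channels x → y the empirical SISO transfer
function is the regularized cross-spectral ratio

```
H(ω) = CPSD(x, y) / (PSD(x) + ε)
```

with Welch-averaged spectra (Hann window, 50 % overlap, 0.25 Hz resolution
by default) and ε a small regularization constant (default 10⁻⁶ × median
PSD).  Only the magnitude |H(ω)| is analyzed.  Two features summarize each
pair:

* **maximum gain** P₁ = |H(ω_p)| at the peak frequency ω_p, and
* **peak-to-floor ratio** PF = log₁₀(|H(ω_p)| / |H(ω_f)|), where the
  roll-off frequency ω_f is the first point at which |H| falls 3 dB below
  the DC gain (half power).

Pathway-level values aggregate all SISO pairs between two regions
(mean by default; median/max available).

**Structural side.**  From tensor eigenvalues λ₁ ≥ λ₂ ≥ λ₃ and streamline
geometry:

```
FA = √(1/2) · √((λ1−λ2)² + (λ2−λ3)² + (λ3−λ1)²) / √(λ1² + λ2² + λ3²)
Ad = λ1          N = streamline count / contact area       L = arc length
```

with the contact area fixed to the 3 mm-diameter effective disc of a
micro-contact.

**Association.**  After per-subject 3-SD outlier removal and exclusion of
observations whose gain peaks below 1.5 Hz (too close to the high-pass
edge), variance inflation factors screen the predictors; FA and Ad are
structurally collinear (λ₁ enters the FA formula), so Ad is dropped and FA
kept.  Each outcome is then fitted by REML as

```
outcome ~ FA + N + L + (1 | subject)
```

with Satterthwaite degrees of freedom for the coefficient t-tests,
Bonferroni-adjusted p-values, and marginal R² (fixed-effect variance over
total variance).

## Worked example

```python
import numpy as np
from tractgain import (SimulationConfig, simulate_lfp_session, notch_filter,
                       highpass_filter, bipolar_montage, pathway_features,
                       simulate_coupled_dataset, filter_observations,
                       compute_vif, drop_collinear, fit_lme)

# a 4-minute two-lead session whose GPi -> VoaVop transmission is a known
# band-pass filter with peak magnitude 5 at 20 Hz
cfg = SimulationConfig(fs=1200.0, duration=240.0, filter_gain=5.0, filter_freq=20.0)
session, truth = simulate_lfp_session(cfg, seed=1)
bipolar = bipolar_montage(highpass_filter(notch_filter(session)))
features, per_pair = pathway_features(bipolar, "GPi", "VoaVop",
                                      window_len=int(4 * bipolar.fs))
row = features.iloc[0]
print(f"estimated peak gain {row.peak_gain_db:.2f} dB at {row.omega_p:.2f} Hz "
      f"(truth: {truth.true_peak_gain_db:.2f} dB at {truth.true_peak_freq:.1f} Hz)")
print(f"PF ratio {row.pf_ratio:.3f} over {row.n_pairs} SISO pairs")

# cohort-scale coupled table and the mixed-effects chain
table, gt = simulate_coupled_dataset(SimulationConfig(), seed=1)
filtered, audit = filter_observations(table)
vifs = compute_vif(filtered[["fa", "ad", "n_per_area", "length"]])
design, dropped = drop_collinear(filtered[["fa", "ad", "n_per_area", "length"]], vifs)
print(f"removed {len(audit)} rows; VIF(fa)={vifs['fa']:.1f}, dropped {dropped}")
res = fit_lme(filtered, "pf_ratio", predictors=tuple(design.columns))
i = res.terms.index("fa")
print(f"beta_FA = {res.params[i]:.2f} [{res.conf_int[i,0]:.2f}, {res.conf_int[i,1]:.2f}], "
      f"t = {res.tvalues[i]:.2f} (df = {res.df[i]:.0f}), true beta_FA = {gt.true_beta[1]}")
```

which prints

```
estimated peak gain 13.96 dB at 20.00 Hz (truth: 13.98 dB at 20.0 Hz)
PF ratio 1.828 over 81 SISO pairs
removed 2 rows; VIF(fa)=22.3, dropped ['ad']
beta_FA = 6.52 [1.85, 11.19], t = 2.74 (df = 861), true beta_FA = 6.12
```

The Welch estimator recovers the generating filter's peak gain to within
0.02 dB and its peak frequency to the grid bin; the VIF screen flags the
mechanical FA–Ad collinearity and drops Ad; and the mixed model's FA
coefficient brackets the generating value (6.12) inside its 95 % CI, with
Satterthwaite df reflecting that FA varies within subjects.

## Command line

```
tractgain simulate session|tracts|coupled --seed 1 --out dir
tractgain preprocess --in session.npz --notch 60 --harmonics 5 --highpass 1 --out bipolar.npz
tractgain tf --in bipolar.npz --region-a GPi --region-b VoaVop --out features.tsv
tractgain dti --tracts tracts.tsv --out metrics.tsv
tractgain associate --observations obs.tsv --sd 3 --min-peak-freq 1.5 --out report/
tractgain run-all --config cfg.yaml --seed 1 --out rundir
```

`run-all` executes the whole chain and writes `features.tsv`, `tracts.tsv`,
`observations.tsv`, `filter_audit.tsv`, `report.json`, `table_results.tsv`,
the resolved configuration and a log; identical configuration and seed
reproduce `report.json` byte for byte.  Exit codes: 0 success,
2 configuration error, 3 data error.

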