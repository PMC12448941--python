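"""Seeded synthetic inputs with known ground truth.

Three generators make every downstream stage testable without patient data:

* :func:`simulate_lfp_session` — a multichannel depth-recording session in
  which bipolar derivations of one lead are linked to those of another lead
  by a known linear time-invariant band-pass filter, contaminated by
  per-contact sensor noise, one lead-wide common-mode component and a 60 Hz
  mains sinusoid plus harmonics.  The generating filter's analytic frequency
  response is the oracle for the transfer-function stage.
* :func:`simulate_tract_set` — streamline polylines with tensor eigenvalue
  triples (λ1 ≥ λ2 = λ3 > 0) solved in closed form so that each triple's
  fractional anisotropy hits a target exactly.
* :func:`simulate_coupled_dataset` — a per-pathway observation table with a
  known subject-clustered linear coupling
  ``y = β0 + β_FA·FA + β_N·N + β_L·L + b_subject + ε`` used to validate the
  mixed-effects stage (coefficient recovery, CI coverage).  Axial
  diffusivity is the λ1 of the same triple that produces FA, so the strong
  FA–Ad collinearity arises mechanically rather than from a correlation
  knob.

All generators are deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (
    DEFAULT_CONTACT_AREA_MM2,
    ChannelInfo,
    GroundTruth,
    RecordingSession,
    TractSet,
)
from .errors import ConfigurationError, DataError, InsufficientDataError

__all__ = [
    "SimulationConfig",
    "simulate_lfp_session",
    "simulate_tract_set",
    "simulate_coupled_dataset",
    "eigenvalues_for_fa",
]

# classic 1/f ("pink") shaping filter coefficients (Paul Kellet's economy form)
_PINK_B = [0.049922035, -0.095993537, 0.050612699, -0.004408786]
_PINK_A = [1.0, -2.494956002, 2.017265875, -0.522189400]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults mirror the recording and cohort scale the analysis assumes:
    24 kHz sampling, 12 subjects with ~73 pathway observations each
    (880 observations total), two leads of 10 micro-contacts, and a
    band-pass transmission filter with peak magnitude 5 at 20 Hz.
    ``true_beta`` is (intercept, FA, N, L) on the feature scale.
    """

    n_subjects: int = 12
    pathways_per_subject: int = 73
    fs: float = 24000.0
    duration: float = 120.0
    true_beta: tuple[float, float, float, float] = (34.63, 6.12, 1.44, -0.01)
    random_intercept_sd: float = 3.0
    residual_sd: float = 8.0
    sensor_noise_sd: float = 0.05
    common_mode_sd: float = 1.0
    line_amp: float = 1.0
    fa_range: tuple[float, float] = (0.2, 0.6)
    seed: int = 0
    # session geometry
    n_contacts: int = 10
    leads: tuple[tuple[str, str], ...] = (("GPi", "L"), ("VoaVop", "L"))
    subject_id: str = "sim01"
    # transmission filter linking the leads
    filter_kind: str = "peak"  # "peak" (resonant band-pass) or "identity"
    filter_gain: float = 5.0
    filter_freq: float = 20.0
    filter_q: float = 2.0
    source_kind: str = "pink"  # "pink" or "white"
    line_base_freq: float = 60.0
    line_n_harmonics: int = 5
    # tract generation
    axial_default: float = 1.35
    md_mean: float = 0.90
    md_sd: float = 0.02
    fibre_length_range: tuple[float, float] = (10.0, 200.0)
    contact_area: float = DEFAULT_CONTACT_AREA_MM2

    def validate(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ConfigurationError("fs and duration must be positive")
        highest = max(
            self.line_base_freq * (self.line_n_harmonics + 1),
            self.filter_freq,
        )
        if self.fs <= 2 * highest:
            raise ConfigurationError(
                f"fs = {self.fs} Hz must exceed twice the highest simulated "
                f"frequency ({highest} Hz)"
            )
        lo, hi = self.fa_range
        if not (0 <= lo <= hi < 1):
            raise ConfigurationError("fa_range must satisfy 0 <= low <= high < 1")
        for name in ("random_intercept_sd", "residual_sd", "sensor_noise_sd",
                     "common_mode_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.source_kind not in ("pink", "white"):
            raise ConfigurationError("source_kind must be 'pink' or 'white'")
        if self.filter_kind not in ("peak", "identity"):
            raise ConfigurationError("filter_kind must be 'peak' or 'identity'")


def _source_noise(n: int, rng: np.random.Generator, kind: str) -> np.ndarray:
    """Unit-SD white or 1/f source signal (pink resembles LFP spectra)."""
    w = rng.standard_normal(n + 10000)
    if kind == "pink":
        w = signal.lfilter(_PINK_B, _PINK_A, w)
    x = w[10000:] if len(w) > n else w
    return x / x.std()


def _design_transmission_filter(cfg: SimulationConfig):
    """SOS of the lead-to-lead transmission filter and its true peak."""
    if cfg.filter_kind == "identity":
        return None, 1.0, 0.0
    b, a = signal.iirpeak(cfg.filter_freq, cfg.filter_q, fs=cfg.fs)
    sos = signal.tf2sos(b * cfg.filter_gain, a)
    # iirpeak has unit gain at its center frequency by construction
    return sos, cfg.filter_gain, cfg.filter_freq


def simulate_lfp_session(
    config: SimulationConfig, seed: int | None = None
) -> tuple[RecordingSession, GroundTruth]:
    """Simulate one multichannel session with known lead-to-lead transmission.

    The first lead carries a unit-SD source u(t); every other lead carries
    the filtered source v = filter(u).  Contacts are built so that adjacent
    differences (the bipolar montage) recover u or v exactly: contact j is
    the running sum of the lead's bipolar sources, plus a lead-wide
    common-mode component, a mains contaminant shared by all contacts, and
    independent per-contact sensor noise.  Hence every ordered bipolar pair
    (first lead → other lead) is linked by the known filter response.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    n = int(round(config.fs * config.duration))
    if n < 2**14:
        raise InsufficientDataError(
            f"duration x fs = {n} samples; at least {2**14} needed for "
            "meaningful spectral estimation"
        )
    if config.n_contacts < 2 or len(config.leads) < 2:
        raise ConfigurationError("need >= 2 leads with >= 2 contacts each")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t = np.arange(n) / config.fs

    u = _source_noise(n, rng, config.source_kind)
    sos, gain, f0 = _design_transmission_filter(config)
    v = u if sos is None else signal.sosfilt(sos, u)

    # mains contaminant shared across the whole session
    line = np.zeros(n)
    for k in range(1, config.line_n_harmonics + 2):
        phase = rng.uniform(0, 2 * math.pi)
        line += (config.line_amp / k) * np.sin(
            2 * math.pi * config.line_base_freq * k * t + phase
        )

    samples = []
    channels = []
    K = config.n_contacts
    for lead_idx, (region, hemi) in enumerate(config.leads):
        src = u if lead_idx == 0 else v
        common = config.common_mode_sd * _source_noise(n, rng, config.source_kind)
        for j in range(K):
            base = (K - 1 - j) * src  # running sum of identical bipolar sources
            noise = config.sensor_noise_sd * rng.standard_normal(n)
            samples.append(base + common + line + noise)
            channels.append(
                ChannelInfo(
                    subject=config.subject_id,
                    hemisphere=hemi,
                    lead=f"L{lead_idx}",
                    region=region,
                    contact=j,
                )
            )

    session = RecordingSession(samples=np.vstack(samples), fs=config.fs, channels=channels)
    truth = GroundTruth(
        seed=seed,
        filter_kind=config.filter_kind,
        filter_sos=sos,
        filter_gain=gain,
        filter_freq=f0,
        true_peak_gain=gain,
        true_peak_gain_db=20 * math.log10(gain) if gain > 0 else -math.inf,
        true_peak_freq=f0,
    )
    return session, truth


def eigenvalues_for_fa(
    fa: float,
    axial: float | None = None,
    md: float | None = None,
) -> tuple[float, float, float]:
    """Closed-form prolate eigenvalue triple (λ1, m, m) with exact FA.

    With λ2 = λ3 = m, FA = (λ1 − m) / sqrt(λ1² + 2m²).  Fixing either the
    axial eigenvalue λ1 or the mean diffusivity MD = (λ1 + 2m)/3 yields a
    quadratic whose admissible root is::

        m = MD (1 − f/s),  λ1 = MD (1 + 2f/s)           (fixed MD)
        m = λ1 (1 − f·s) / (1 − 2f²)                    (fixed λ1)

    with s = sqrt(3 − 2f²).  FA = 1 needs a degenerate m = 0 triple and is
    rejected.
    """
    f = float(fa)
    if not 0 <= f < 1:
        raise DataError(f"target FA must be in [0, 1), got {f}")
    s = math.sqrt(3.0 - 2.0 * f * f)
    if md is not None:
        m = md * (1.0 - f / s)
        l1 = md * (1.0 + 2.0 * f / s)
        return l1, m, m
    if axial is None:
        raise ConfigurationError("provide either axial or md")
    denom = 1.0 - 2.0 * f * f
    if abs(denom) < 1e-12:
        m = axial / 4.0  # limit of the quadratic at f = 1/sqrt(2)
    else:
        m = axial * (1.0 - f * s) / denom
    return float(axial), m, m


def _random_streamline(rng: np.random.Generator, length: float, step: float = 0.5) -> np.ndarray:
    """Smooth 3-D random-walk polyline with exact arc length ``length`` mm."""
    n_steps = max(2, int(round(length / step)))
    step = length / n_steps  # constant segment length -> exact arc length
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    dirs = [d]
    for _ in range(n_steps - 1):
        d = d + 0.15 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        dirs.append(d)
    start = rng.uniform(-10, 10, size=3)
    pts = start + np.vstack([np.zeros(3), np.cumsum(np.array(dirs) * step, axis=0)])
    return pts


def simulate_tract_set(
    config: SimulationConfig,
    target_fa: float,
    n_streamlines: int,
    seed: int | None = None,
    region_pair: tuple[str, str] | None = None,
) -> TractSet:
    """Tract set whose every eigenvalue triple hits ``target_fa`` exactly.

    λ1 is jittered across streamlines around ``config.axial_default`` and
    λ2 = λ3 solved in closed form per triple, so the per-pathway mean FA
    equals the target to numerical precision.  Streamline arc lengths are
    drawn within ``config.fibre_length_range`` (the tracking bounds).
    ``n_streamlines = 0`` returns an empty set flagged "no connection".
    """
    config.validate()
    if not 0 <= target_fa < 1:
        raise DataError(
            f"target_fa must be in [0, 1); FA = 1 requires degenerate zero "
            f"eigenvalues (got {target_fa})"
        )
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    pair = region_pair or (config.leads[0][0], config.leads[1][0])

    if n_streamlines == 0:
        return TractSet(streamlines=[], eigenvalues=np.empty((0, 3)),
                        region_pair=pair, contact_area=config.contact_area)

    triples = []
    lines = []
    lo, hi = config.fibre_length_range
    for _ in range(n_streamlines):
        axial = config.axial_default * rng.uniform(0.9, 1.1)
        triples.append(eigenvalues_for_fa(target_fa, axial=axial))
        lines.append(_random_streamline(rng, rng.uniform(lo, hi)))
    return TractSet(
        streamlines=lines,
        eigenvalues=np.array(triples),
        region_pair=pair,
        contact_area=config.contact_area,
    )


def simulate_coupled_dataset(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-pathway observation table with known subject-clustered coupling.

    Each outcome column (``pf_ratio`` and ``peak_gain``) follows

        y = β0 + β_FA·FA + β_N·N + β_L·L + b_subject + ε

    with independent per-outcome random intercepts b ~ N(0, σ_b²) and
    residuals ε ~ N(0, σ_ε²).  FA is uniform on ``fa_range``; the axial
    diffusivity is λ1 of a prolate triple with jittered mean diffusivity,
    which makes FA and Ad strongly positively correlated by construction.
    """
    config.validate()
    if config.n_subjects < 2 or config.pathways_per_subject < 2:
        raise ConfigurationError("need n_subjects >= 2 and pathways_per_subject >= 2")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    beta = np.asarray(config.true_beta, dtype=float)
    outcomes = ("pf_ratio", "peak_gain")
    intercepts = {
        out: rng.normal(0.0, config.random_intercept_sd, size=config.n_subjects)
        for out in outcomes
    }

    rows = []
    all_fa = []
    for i in range(config.n_subjects):
        subj = f"S{i + 1:02d}"
        m = config.pathways_per_subject
        fa = rng.uniform(*config.fa_range, size=m)
        md = np.clip(rng.normal(config.md_mean, config.md_sd, size=m), 0.3, None)
        s = np.sqrt(3.0 - 2.0 * fa**2)
        ad = md * (1.0 + 2.0 * fa / s)  # λ1 of the same triple: mechanical FA-Ad coupling
        counts = rng.integers(1, 150, size=m)
        n_per_area = counts / config.contact_area
        length = rng.uniform(*config.fibre_length_range, size=m)
        fixed = beta[0] + beta[1] * fa + beta[2] * n_per_area + beta[3] * length
        omega_p = rng.uniform(2.0, 40.0, size=m)
        rec = {
            "subject": subj,
            "hemisphere": np.where(np.arange(m) % 2 == 0, "L", "R"),
            "pathway": [f"GPi->VoaVop#{j}" for j in range(m)],
            "fa": fa,
            "ad": ad,
            "n_per_area": n_per_area,
            "length": length,
            "omega_p": omega_p,
        }
        for out in outcomes:
            eps = rng.normal(0.0, config.residual_sd, size=m)
            rec[out] = fixed + intercepts[out][i] + eps
        rows.append(pd.DataFrame(rec))
        all_fa.append(fa)

    table = pd.concat(rows, ignore_index=True)
    truth = GroundTruth(
        seed=seed,
        true_beta=tuple(beta),
        subject_intercepts={
            out: {f"S{i + 1:02d}": float(b) for i, b in enumerate(intercepts[out])}
            for out in outcomes
        },
        pathway_fa=np.concatenate(all_fa),
    )
    return table, truth
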