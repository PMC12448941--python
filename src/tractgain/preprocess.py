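"""Recording conditioning: notch, high-pass, decimation, bipolar montage.

The conditioning chain mirrors standard depth-recording practice: mains
interference is notched at 60 Hz and its five harmonics (120–360 Hz), slow
drift is removed with a 1 Hz high-pass, and adjacent micro-contacts within
each lead are subtracted pairwise (bipolar montage) to cancel lead-wide
common-mode noise.  All IIR filters are applied forward-backward
(``sosfiltfilt``) so the net phase shift is zero.

Both plain functions operating on :class:`~tractgain.containers.RecordingSession`
objects and scikit-learn style transformer classes are provided; the classes
compose with ``sklearn.pipeline.Pipeline``.
"""

from __future__ import annotations

import warnings
from collections import defaultdict

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import BipolarPair, BipolarSession, RecordingSession
from .errors import ConfigurationError

__all__ = [
    "notch_filter",
    "highpass_filter",
    "decimate",
    "bipolar_montage",
    "NotchFilter",
    "HighpassFilter",
    "Decimator",
    "BipolarMontage",
    "make_preprocess_pipeline",
]


def design_notch_sos(base_freq: float, n_harmonics: int, q: float, fs: float) -> np.ndarray:
    """Cascade of second-order IIR notches at base_freq and its harmonics.

    ``n_harmonics = 5`` with ``base_freq = 60`` notches 60, 120, 180, 240,
    300 and 360 Hz.  Every notch must sit below Nyquist.
    """
    if base_freq <= 0 or q <= 0:
        raise ConfigurationError("base_freq and q must be positive")
    top = base_freq * (n_harmonics + 1)
    if top >= fs / 2:
        raise ConfigurationError(
            f"highest notch {top} Hz is at or above Nyquist ({fs / 2} Hz)"
        )
    sections = []
    for k in range(1, n_harmonics + 2):
        b, a = signal.iirnotch(base_freq * k, q, fs=fs)
        sections.append(signal.tf2sos(b, a))
    return np.vstack(sections)


def notch_filter(
    session: RecordingSession,
    base_freq: float = 60.0,
    n_harmonics: int = 5,
    q: float = 30.0,
) -> RecordingSession:
    """Zero-phase notch at ``base_freq`` and its harmonics on every channel."""
    sos = design_notch_sos(base_freq, n_harmonics, q, session.fs)
    out = signal.sosfiltfilt(sos, session.samples, axis=-1)
    return session.with_samples(out)


def highpass_filter(session: RecordingSession, cutoff: float = 1.0, order: int = 4) -> RecordingSession:
    """Zero-phase Butterworth high-pass removing drift below ``cutoff`` Hz."""
    if cutoff <= 0:
        raise ConfigurationError(f"high-pass cutoff must be positive, got {cutoff}")
    if cutoff >= session.fs / 2:
        raise ConfigurationError("high-pass cutoff must be below Nyquist")
    sos = signal.butter(order, cutoff, btype="highpass", fs=session.fs, output="sos")
    out = signal.sosfiltfilt(sos, session.samples, axis=-1)
    return session.with_samples(out)


def decimate(session: RecordingSession, factor: int, min_analysis_freq: float = 500.0) -> RecordingSession:
    """Anti-alias filter and downsample by an integer factor.

    The post-decimation Nyquist must stay above ``min_analysis_freq`` so the
    analysis band (well below 1 kHz for LFP transfer functions) survives.
    """
    if int(factor) != factor or factor < 1:
        raise ConfigurationError(f"decimation factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    if factor == 1:
        return session.with_samples(session.samples.copy())
    new_fs = session.fs / factor
    if new_fs / 2 <= min_analysis_freq:
        raise ConfigurationError(
            f"decimation to {new_fs} Hz puts Nyquist at or below the "
            f"analysis band ({min_analysis_freq} Hz)"
        )
    x = session.samples
    # scipy recommends keeping single-stage factors modest; chain stages
    while factor > 1:
        step = factor if factor <= 12 else 8
        while factor % step:
            step -= 1
        # FIR keeps the passband flat (IIR Chebyshev ripple doubles under
        # the zero-phase forward-backward pass and exceeds 1%)
        x = signal.decimate(x, step, axis=-1, ftype="fir", zero_phase=True)
        factor //= step
    return session.with_samples(x, fs=new_fs)


def bipolar_montage(session: RecordingSession) -> BipolarSession:
    """Subtract adjacent contacts within each lead (contact_k − contact_{k+1}).

    Contacts are ordered by contact index along the lead shaft; each lead
    with K contacts contributes K−1 derived channels inheriting the lead's
    region label.  Single-contact leads are skipped with a warning.
    """
    by_lead: dict[tuple, list[int]] = defaultdict(list)
    for i, ch in enumerate(session.channels):
        by_lead[(ch.subject, ch.hemisphere, ch.lead)].append(i)

    rows: list[np.ndarray] = []
    pairs: list[BipolarPair] = []
    for key in by_lead:
        idx = sorted(by_lead[key], key=lambda i: session.channels[i].contact)
        if len(idx) < 2:
            warnings.warn(f"lead {key[2]} has a single contact; skipped in bipolar montage")
            continue
        for a, b in zip(idx[:-1], idx[1:]):
            ch_a, ch_b = session.channels[a], session.channels[b]
            rows.append(session.samples[a] - session.samples[b])
            pairs.append(
                BipolarPair(
                    subject=ch_a.subject,
                    hemisphere=ch_a.hemisphere,
                    lead=ch_a.lead,
                    region=ch_a.region,
                    contact_a=ch_a.contact,
                    contact_b=ch_b.contact,
                )
            )
    samples = np.vstack(rows) if rows else np.empty((0, session.n_times))
    return BipolarSession(samples=samples, fs=session.fs, pairs=pairs)


class _SessionTransformer(BaseEstimator, TransformerMixin):
    """Base for session-to-session transformers (duck-typed X = session)."""

    def fit(self, X: RecordingSession, y=None):
        self._validate(X)
        return self

    def _validate(self, X: RecordingSession) -> None:  # pragma: no cover - trivial
        pass

    def fit_transform(self, X, y=None, **fit_params):
        return self.fit(X, y).transform(X)


class NotchFilter(_SessionTransformer):
    """Zero-phase mains notch at ``base_freq`` and its ``n_harmonics`` harmonics."""

    def __init__(self, base_freq: float = 60.0, n_harmonics: int = 5, q: float = 30.0):
        self.base_freq = base_freq
        self.n_harmonics = n_harmonics
        self.q = q

    def fit(self, X: RecordingSession, y=None):
        self.sos_ = design_notch_sos(self.base_freq, self.n_harmonics, self.q, X.fs)
        return self

    def transform(self, X: RecordingSession) -> RecordingSession:
        return notch_filter(X, self.base_freq, self.n_harmonics, self.q)


class HighpassFilter(_SessionTransformer):
    """Zero-phase Butterworth high-pass (default 1 Hz, order 4)."""

    def __init__(self, cutoff: float = 1.0, order: int = 4):
        self.cutoff = cutoff
        self.order = order

    def fit(self, X: RecordingSession, y=None):
        if self.cutoff <= 0:
            raise ConfigurationError("high-pass cutoff must be positive")
        self.sos_ = signal.butter(self.order, self.cutoff, btype="highpass",
                                  fs=X.fs, output="sos")
        return self

    def transform(self, X: RecordingSession) -> RecordingSession:
        return highpass_filter(X, self.cutoff, self.order)


class Decimator(_SessionTransformer):
    """Anti-aliased integer-factor downsampler."""

    def __init__(self, factor: int = 1, min_analysis_freq: float = 500.0):
        self.factor = factor
        self.min_analysis_freq = min_analysis_freq

    def transform(self, X: RecordingSession) -> RecordingSession:
        return decimate(X, self.factor, self.min_analysis_freq)


class BipolarMontage(_SessionTransformer):
    """Adjacent-contact subtraction within each lead."""

    def transform(self, X: RecordingSession) -> BipolarSession:
        return bipolar_montage(X)


def make_preprocess_pipeline(
    base_freq: float = 60.0,
    n_harmonics: int = 5,
    q: float = 30.0,
    highpass_cutoff: float = 1.0,
    highpass_order: int = 4,
    decimate_factor: int = 1,
):
    """sklearn Pipeline running notch → high-pass → decimate → bipolar montage."""
    from sklearn.pipeline import Pipeline

    return Pipeline(
        [
            ("notch", NotchFilter(base_freq, n_harmonics, q)),
            ("highpass", HighpassFilter(highpass_cutoff, highpass_order)),
            ("decimate", Decimator(decimate_factor)),
            ("bipolar", BipolarMontage()),
        ]
    )
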