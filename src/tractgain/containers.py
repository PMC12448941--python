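"""In-memory containers shared by every pipeline stage.

A :class:`RecordingSession` holds the raw multichannel depth-electrode time
series together with per-channel metadata (subject, hemisphere, lead, region
label, contact index).  Preprocessing turns it into a
:class:`BipolarSession`; the transfer-function stage consumes bipolar pairs
and emits :class:`TransferFunctionEstimate` / :class:`TFFeatures`; the
structural side lives in :class:`TractSet` / :class:`TractMetrics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError

#: Effective seed area of a micro-contact: a 3 mm diameter disc.
DEFAULT_CONTACT_AREA_MM2 = math.pi * 1.5**2


@dataclass(frozen=True)
class ChannelInfo:
    """Metadata for one monopolar micro-contact channel."""

    subject: str
    hemisphere: str
    lead: str
    region: str
    contact: int
    impedance_class: str = "high"


@dataclass
class RecordingSession:
    """Multichannel time series plus sampling rate and channel metadata.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in µV (units are carried through, never converted).
    fs : float
        Sampling rate in Hz.
    channels : sequence of ChannelInfo
        One entry per row of ``samples``; contact indices must be unique
        within a lead.
    """

    samples: np.ndarray
    fs: float
    channels: list[ChannelInfo]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise DataError("samples must be a 2-D (channels x time) array")
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        self.channels = list(self.channels)
        if len(self.channels) != self.samples.shape[0]:
            raise DataError(
                f"{len(self.channels)} channel entries for "
                f"{self.samples.shape[0]} signal rows"
            )
        seen = set()
        for ch in self.channels:
            key = (ch.lead, ch.contact)
            if key in seen:
                raise DataError(f"duplicate contact {key} within a lead")
            seen.add(key)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_times / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "RecordingSession":
        """Copy of the session with new sample data (and optionally rate)."""
        return RecordingSession(samples=samples, fs=self.fs if fs is None else fs,
                                channels=list(self.channels))

    def channels_df(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.channels])


@dataclass(frozen=True)
class BipolarPair:
    """One derived bipolar channel: contact_a minus contact_b of a lead."""

    subject: str
    hemisphere: str
    lead: str
    region: str
    contact_a: int
    contact_b: int


@dataclass
class BipolarSession:
    """Bipolar-montage derivation of a :class:`RecordingSession`."""

    samples: np.ndarray
    fs: float
    pairs: list[BipolarPair]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise DataError("samples must be a 2-D (channels x time) array")
        self.pairs = list(self.pairs)
        if len(self.pairs) != self.samples.shape[0]:
            raise DataError("pair metadata does not match sample rows")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    def channel_indices(self, region: str, hemisphere: str | None = None) -> list[int]:
        """Row indices of bipolar channels in a region (optionally one hemisphere)."""
        return [
            i
            for i, p in enumerate(self.pairs)
            if p.region == region and (hemisphere is None or p.hemisphere == hemisphere)
        ]


@dataclass
class TransferFunctionEstimate:
    """Empirical SISO frequency response H(ω) = CPSD(x,y) / (PSD(x) + ε)."""

    freqs: np.ndarray
    H: np.ndarray
    psd_x: np.ndarray | None = None
    cpsd_xy: np.ndarray | None = None
    epsilon: float = 0.0
    input_channel: BipolarPair | str | None = None
    output_channel: BipolarPair | str | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.H = np.asarray(self.H)
        if self.freqs.ndim != 1 or self.freqs.shape != self.H.shape:
            raise DataError("freqs and H must be 1-D arrays of equal length")
        if self.freqs[0] < 0 or np.any(np.diff(self.freqs) <= 0):
            raise DataError("frequency grid must be strictly increasing and start >= 0")
        if not np.all(np.isfinite(self.H)):
            raise DataError("non-finite transfer function values")
        if self.psd_x is not None:
            self.psd_x = np.asarray(self.psd_x, dtype=float)
            if np.any(self.psd_x < 0):
                raise DataError("PSD must be non-negative")

    @classmethod
    def from_response(cls, freqs: np.ndarray, H: np.ndarray) -> "TransferFunctionEstimate":
        """Wrap an analytic or externally computed response for feature extraction."""
        return cls(freqs=np.asarray(freqs, float), H=np.asarray(H))

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.H)


@dataclass
class TFFeatures:
    """Scalar signal-transmission features of one directed channel pair.

    ``pf_ratio`` is log10(|H(ω_p)| / |H(ω_f)|) where ω_p is the frequency of
    maximum gain and ω_f the roll-off frequency (first 3 dB drop below the
    DC gain).  When the response never crosses 3 dB below DC within the grid,
    ``rolloff_defined`` is False and ω_f / floor_gain / pf_ratio are NaN.
    """

    peak_gain: float
    peak_gain_db: float
    omega_p: float
    dc_gain: float
    omega_f: float
    floor_gain: float
    pf_ratio: float
    rolloff_defined: bool = True

    def as_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class TractSet:
    """Streamline polylines and per-streamline tensor eigenvalues for one pathway."""

    streamlines: list[np.ndarray]
    eigenvalues: np.ndarray
    region_pair: tuple[str, str] = ("", "")
    contact_area: float = DEFAULT_CONTACT_AREA_MM2

    def __post_init__(self) -> None:
        if self.contact_area <= 0:
            raise DataError("contact area must be positive")
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise DataError("each streamline must be an (n>=2, 3) polyline")
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float).reshape(-1, 3)
        if len(self.streamlines) != self.eigenvalues.shape[0]:
            raise DataError("one eigenvalue triple per streamline required")

    @property
    def n_streamlines(self) -> int:
        return len(self.streamlines)

    @property
    def is_empty(self) -> bool:
        """True when the pathway carries no reconstructed connection."""
        return self.n_streamlines == 0


@dataclass
class TractMetrics:
    """Per-pathway structural summary: FA, axial diffusivity, N per area, length."""

    fa: float
    ad: float
    n_per_area: float
    length: float
    n_streamlines: int = 0
    empty: bool = False

    def as_dict(self) -> dict:
        return dict(vars(self))


@dataclass
class GroundTruth:
    """Known generating parameters of a synthetic dataset (seed-reproducible)."""

    seed: int
    filter_kind: str | None = None
    filter_sos: np.ndarray | None = None
    filter_gain: float | None = None
    filter_freq: float | None = None
    true_peak_gain: float | None = None
    true_peak_gain_db: float | None = None
    true_peak_freq: float | None = None
    true_beta: tuple[float, ...] | None = None
    subject_intercepts: dict | None = None
    pathway_fa: np.ndarray | None = None

    def magnitude_response(self, freqs: Sequence[float], fs: float) -> np.ndarray:
        """Analytic |H| of the generating filter on an arbitrary grid."""
        from scipy import signal

        freqs = np.asarray(freqs, dtype=float)
        if self.filter_kind == "identity" or self.filter_sos is None:
            return np.ones_like(freqs)
        _, h = signal.sosfreqz(self.filter_sos, worN=freqs, fs=fs)
        return np.abs(h)
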