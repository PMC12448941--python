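"""Empirical SISO transfer functions and their transmission features.

For a directed pair of bipolar channels x → y the empirical transfer
function is the regularized cross-spectral ratio

    H(ω) = CPSD(x, y) / (PSD(x) + ε)

with Welch-averaged spectral densities (Hann window, 50 % overlap by
default) and a small regularization constant ε that keeps |H| finite when
the input spectrum approaches zero.  Only the magnitude |H(ω)| is analyzed;
phase and delay are out of scope here.

Two scalar features summarize transmission for each pair:

* the maximum gain |H(ω_p)| (peak gain, also reported in dB), and
* the peak-to-floor ratio PF = log10(|H(ω_p)| / |H(ω_f)|) where ω_f is the
  roll-off frequency — the first frequency at which |H| drops 3 dB below
  the DC gain (half power).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator

from .containers import BipolarSession, TFFeatures, TransferFunctionEstimate
from .errors import ConfigurationError, DataError, EmptyPathwayError, InsufficientDataError

__all__ = [
    "estimate_spectra",
    "estimate_transfer_function",
    "extract_features",
    "pathway_features",
    "TransferFunctionEstimator",
]

#: Half-power drop defining the roll-off frequency, in dB.
ROLLOFF_DB = 3.0

_FEATURE_COLUMNS = [
    "peak_gain", "peak_gain_db", "omega_p", "dc_gain",
    "omega_f", "floor_gain", "pf_ratio", "rolloff_defined",
]


def _welch_params(fs: float, window_len: int | None, overlap: float, n: int):
    if window_len is None:
        window_len = int(round(4 * fs))  # 0.25 Hz resolution
    window_len = int(window_len)
    if not 0 <= overlap < 1:
        raise ConfigurationError(f"overlap must be in [0, 1), got {overlap}")
    if n < 2 * window_len:
        raise InsufficientDataError(
            f"record of {n} samples is shorter than 2 windows of {window_len}"
        )
    return window_len, int(round(window_len * overlap))


def estimate_spectra(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    window_len: int | None = None,
    overlap: float = 0.5,
    window: str = "hann",
):
    """Welch PSD of ``x`` and CPSD between ``x`` and ``y`` on a shared grid.

    Returns ``(freqs, psd_x, cpsd_xy)`` with resolution ``fs / window_len``.
    The CPSD convention is ``E[conj(X(ω)) · Y(ω)]`` so that for y = h * x the
    ratio CPSD/PSD recovers the filter response h.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D arrays of equal length")
    nperseg, noverlap = _welch_params(fs, window_len, overlap, x.size)
    freqs, psd_x = signal.welch(x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)
    _, cpsd_xy = signal.csd(x, y, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap)
    return freqs, psd_x, cpsd_xy


def estimate_transfer_function(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    epsilon: float | str = "auto",
    window_len: int | None = None,
    overlap: float = 0.5,
    window: str = "hann",
    input_channel=None,
    output_channel=None,
) -> TransferFunctionEstimate:
    """Regularized empirical transfer function H = CPSD(x,y) / (PSD(x) + ε).

    ``epsilon="auto"`` uses 1e-6 × median PSD(x); ``epsilon=0`` is allowed
    only when the input has power everywhere on the grid.
    """
    freqs, psd_x, cpsd_xy = estimate_spectra(x, y, fs, window_len, overlap, window)
    if epsilon == "auto":
        eps = 1e-6 * float(np.median(psd_x))
    else:
        eps = float(epsilon)
        if eps < 0:
            raise ConfigurationError("epsilon must be >= 0")
    if eps == 0 and np.any(psd_x == 0):
        raise DataError("epsilon = 0 with zero-power input bins: division degenerates")
    H = cpsd_xy / (psd_x + eps)
    return TransferFunctionEstimate(
        freqs=freqs, H=H, psd_x=psd_x, cpsd_xy=cpsd_xy, epsilon=eps,
        input_channel=input_channel, output_channel=output_channel,
    )


def extract_features(tfe: TransferFunctionEstimate, min_freq: float | None = None) -> TFFeatures:
    """Peak gain, peak frequency, DC gain, roll-off frequency and PF ratio.

    The DC gain is |H| at the lowest available grid frequency (a 1 Hz
    high-pass makes true DC unobservable; the 0 Hz Welch bin stands in).
    The roll-off frequency is the first downward crossing of
    ``dc_gain · 10^(-3/20)`` above the DC bin, located by linear
    interpolation of log-magnitude between the straddling bins.  If no
    crossing exists within the grid the roll-off features are flagged
    undefined (NaN) rather than raising.
    """
    mag = tfe.magnitude
    freqs = tfe.freqs
    if np.all(mag == 0):
        raise DataError("all-zero transfer function magnitude: features undefined")

    dc_gain = float(mag[0])
    lo = 0 if min_freq is None else int(np.searchsorted(freqs, min_freq))
    if lo >= freqs.size:
        raise ConfigurationError("min_freq is above the frequency grid")
    ip = lo + int(np.argmax(mag[lo:]))
    peak_gain = float(mag[ip])
    omega_p = float(freqs[ip])

    threshold = dc_gain * 10 ** (-ROLLOFF_DB / 20.0)
    omega_f = floor_gain = pf_ratio = float("nan")
    defined = False
    if threshold > 0:
        below = np.flatnonzero((mag[1:] < threshold) & (mag[:-1] >= threshold)) + 1
        if below.size:
            i = int(below[0])
            # interpolate the crossing in (frequency, log10 magnitude)
            lm0, lm1 = np.log10(mag[i - 1]), np.log10(max(mag[i], 1e-300))
            t = (np.log10(threshold) - lm0) / (lm1 - lm0)
            omega_f = float(freqs[i - 1] + t * (freqs[i] - freqs[i - 1]))
            floor_gain = float(threshold)
            pf_ratio = float(np.log10(peak_gain / floor_gain))
            defined = True

    return TFFeatures(
        peak_gain=peak_gain,
        peak_gain_db=float(20 * np.log10(peak_gain)) if peak_gain > 0 else -np.inf,
        omega_p=omega_p,
        dc_gain=dc_gain,
        omega_f=omega_f,
        floor_gain=floor_gain,
        pf_ratio=pf_ratio,
        rolloff_defined=defined,
    )


class TransferFunctionEstimator(BaseEstimator):
    """Estimator wrapper around the Welch transfer-function pipeline.

    ``fit(x, y)`` estimates H from the input signal ``x`` to the output
    ``y`` and exposes ``freqs_``, ``H_``, ``psd_x_``, ``cpsd_xy_`` and
    ``epsilon_``; ``features()`` extracts the scalar transmission summary.
    """

    def __init__(
        self,
        fs: float = 3000.0,
        epsilon: float | str = "auto",
        window_len: int | None = None,
        overlap: float = 0.5,
        window: str = "hann",
        min_freq: float | None = None,
    ):
        self.fs = fs
        self.epsilon = epsilon
        self.window_len = window_len
        self.overlap = overlap
        self.window = window
        self.min_freq = min_freq

    def fit(self, x: np.ndarray, y: np.ndarray):
        tfe = estimate_transfer_function(
            x, y, fs=self.fs, epsilon=self.epsilon,
            window_len=self.window_len, overlap=self.overlap, window=self.window,
        )
        self.estimate_ = tfe
        self.freqs_ = tfe.freqs
        self.H_ = tfe.H
        self.psd_x_ = tfe.psd_x
        self.cpsd_xy_ = tfe.cpsd_xy
        self.epsilon_ = tfe.epsilon
        return self

    def features(self) -> TFFeatures:
        return extract_features(self.estimate_, self.min_freq)


def pathway_features(
    session: BipolarSession,
    region_a: str,
    region_b: str,
    hemisphere: str | None = None,
    reducer: str = "mean",
    epsilon: float | str = "auto",
    window_len: int | None = None,
    overlap: float = 0.5,
    min_freq: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directed pathway features a → b aggregated over all SISO channel pairs.

    Computes :func:`extract_features` for every ordered pair (channel in
    ``region_a`` → channel in ``region_b``) sharing a hemisphere, then
    aggregates to one record per hemisphere with the configured reducer
    (mean by default; undefined roll-offs are excluded from the PF
    aggregate).  Returns ``(aggregated, per_pair)`` data frames; per-pair
    records are retained for audit.
    """
    reducers = {"mean": np.nanmean, "median": np.nanmedian, "max": np.nanmax}
    if reducer not in reducers:
        raise ConfigurationError(f"unknown reducer {reducer!r}; use one of {sorted(reducers)}")
    reduce = reducers[reducer]

    if hemisphere is None:
        hemis = sorted({p.hemisphere for p in session.pairs})
    else:
        hemis = [hemisphere]

    pair_rows = []
    for hemi in hemis:
        ia = session.channel_indices(region_a, hemi)
        ib = session.channel_indices(region_b, hemi)
        if not ia or not ib:
            raise EmptyPathwayError(
                f"no bipolar channels for pathway {region_a}->{region_b} in hemisphere {hemi}"
            )
        for i in ia:
            for j in ib:
                tfe = estimate_transfer_function(
                    session.samples[i], session.samples[j], fs=session.fs,
                    epsilon=epsilon, window_len=window_len, overlap=overlap,
                    input_channel=session.pairs[i], output_channel=session.pairs[j],
                )
                feats = extract_features(tfe, min_freq)
                row = {
                    "subject": session.pairs[i].subject,
                    "hemisphere": hemi,
                    "pathway": f"{region_a}->{region_b}",
                    "input": f"{session.pairs[i].lead}:{session.pairs[i].contact_a}-{session.pairs[i].contact_b}",
                    "output": f"{session.pairs[j].lead}:{session.pairs[j].contact_a}-{session.pairs[j].contact_b}",
                }
                row.update(feats.as_dict())
                pair_rows.append(row)

    per_pair = pd.DataFrame(pair_rows)
    agg_rows = []
    for (subj, hemi), grp in per_pair.groupby(["subject", "hemisphere"], sort=True):
        rec = {"subject": subj, "hemisphere": hemi, "pathway": f"{region_a}->{region_b}",
               "n_pairs": len(grp)}
        for col in ["peak_gain", "peak_gain_db", "omega_p", "dc_gain"]:
            rec[col] = float(reduce(grp[col].to_numpy()))
        defined = grp[grp["rolloff_defined"]]
        if len(defined):
            for col in ["omega_f", "floor_gain", "pf_ratio"]:
                rec[col] = float(reduce(defined[col].to_numpy()))
        else:
            rec.update({"omega_f": np.nan, "floor_gain": np.nan, "pf_ratio": np.nan})
        agg_rows.append(rec)
    return pd.DataFrame(agg_rows), per_pair
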