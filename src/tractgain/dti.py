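"""Diffusion-tensor scalar metrics and per-pathway tract summaries.

The four structural measures used by the coupling analysis:

* FA — fractional anisotropy, the normalized dispersion of the tensor
  eigenvalues (0 = isotropic diffusion, 1 = maximally anisotropic):

  ``FA = sqrt(1/2) * sqrt((λ1-λ2)² + (λ2-λ3)² + (λ3-λ1)²) / sqrt(λ1²+λ2²+λ3²)``

* Ad — axial diffusivity, the first (largest) eigenvalue λ1, diffusion along
  the principal fibre axis.
* N — streamline count between two regions normalized by the effective seed
  area of a micro-contact (a 3 mm diameter disc by default).
* L — arc length of a streamline polyline.

Tensors enter pre-fitted (full 3x3 symmetric matrices or eigenvalue
triples); no tensor fitting from raw diffusion signals happens here.
"""

from __future__ import annotations

import numpy as np

from .containers import TractMetrics, TractSet
from .errors import ConfigurationError, DataError

__all__ = [
    "tensor_eigenvalues",
    "fractional_anisotropy",
    "axial_diffusivity",
    "mean_diffusivity",
    "streamline_length",
    "fibres_per_area",
    "pathway_dti_summary",
]


def tensor_eigenvalues(tensor: np.ndarray, atol: float = 1e-8) -> tuple[float, float, float]:
    """Descending real eigenvalues (λ1, λ2, λ3) of a symmetric 3x3 tensor.

    Raises
    ------
    DataError
        If the tensor is not symmetric within ``atol``.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape != (3, 3):
        raise DataError(f"expected a 3x3 tensor, got shape {t.shape}")
    if not np.allclose(t, t.T, atol=atol):
        raise DataError("tensor is asymmetric beyond tolerance")
    vals = np.linalg.eigvalsh(0.5 * (t + t.T))
    l3, l2, l1 = vals
    return float(l1), float(l2), float(l3)


def fractional_anisotropy(l1, l2, l3):
    """Fractional anisotropy of one or many eigenvalue triples.

    Accepts scalars or broadcastable arrays of non-negative eigenvalues;
    an all-zero triple has no defined anisotropy and raises ``DataError``.
    """
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    l3 = np.asarray(l3, dtype=float)
    if np.any(l1 < 0) or np.any(l2 < 0) or np.any(l3 < 0):
        raise DataError("eigenvalues must be non-negative")
    norm_sq = l1**2 + l2**2 + l3**2
    if np.any(norm_sq == 0):
        raise DataError("FA is undefined for an all-zero eigenvalue triple")
    num = (l1 - l2) ** 2 + (l2 - l3) ** 2 + (l3 - l1) ** 2
    fa = np.sqrt(0.5 * num / norm_sq)
    # clip the sqrt round-off so the invariant FA in [0, 1] holds exactly
    fa = np.clip(fa, 0.0, 1.0)
    return float(fa) if fa.ndim == 0 else fa


def axial_diffusivity(l1, l2, l3):
    """Axial diffusivity Ad = λ1 (largest eigenvalue) of sorted triples."""
    l1 = np.asarray(l1, dtype=float)
    return float(l1) if l1.ndim == 0 else l1


def mean_diffusivity(l1, l2, l3):
    """Mean diffusivity (λ1 + λ2 + λ3) / 3."""
    md = (np.asarray(l1, float) + np.asarray(l2, float) + np.asarray(l3, float)) / 3.0
    return float(md) if md.ndim == 0 else md


def streamline_length(polyline: np.ndarray) -> float:
    """Arc length of a 3-D polyline in mm (sum of Euclidean segment lengths)."""
    p = np.asarray(polyline, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise DataError("a streamline needs at least two points")
    return float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))


def fibres_per_area(tracts: TractSet) -> float:
    """Streamline count normalized by the effective contact area (count / mm²)."""
    if tracts.contact_area <= 0:
        raise ConfigurationError("contact area must be positive")
    return tracts.n_streamlines / tracts.contact_area


def pathway_dti_summary(tracts: TractSet) -> TractMetrics:
    """Per-pathway structural summary.

    FA and Ad are unweighted means over per-streamline tensor samples;
    length is the mean streamline arc length; N is the count per unit area.
    An empty tract set (no reconstructed connection) returns a flagged
    record with NaN metrics rather than raising.
    """
    if tracts.is_empty:
        return TractMetrics(fa=np.nan, ad=np.nan, n_per_area=0.0, length=np.nan,
                            n_streamlines=0, empty=True)
    ev = tracts.eigenvalues
    fa = float(np.mean(fractional_anisotropy(ev[:, 0], ev[:, 1], ev[:, 2])))
    ad = float(np.mean(ev[:, 0]))
    length = float(np.mean([streamline_length(s) for s in tracts.streamlines]))
    return TractMetrics(
        fa=fa,
        ad=ad,
        n_per_area=fibres_per_area(tracts),
        length=length,
        n_streamlines=tracts.n_streamlines,
        empty=False,
    )
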