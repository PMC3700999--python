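"""Detectable-signal counting: data covariance, normalized eigenspectra, and
field-vs-potential signal-count ratio curves.

The number of uncorrelated detectable signals in a sensor array is estimated
by principal component analysis of the simulated data: eigenvalues of the
channel covariance are normalized by the largest one so they can be read as
noise-to-signal power levels, and the count of eigenvalues above a given
level is the number of uncorrelated signals detectable at that noise floor.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .experiment_data import DataMatrix

__all__ = [
    "EigenSpectrum",
    "covariance",
    "eigenspectrum",
    "count_detectable",
    "signal_ratio_curve",
    "DEFAULT_THRESHOLD_BAND",
]

# "realistic range" of noise-to-signal powers over which counts are compared
DEFAULT_THRESHOLD_BAND = (1e-4, 1e-3)


@dataclasses.dataclass(frozen=True)
class EigenSpectrum:
    """Covariance eigenvalues sorted descending and normalized by the
    largest; all in [0, 1] (a tiny negative numerical floor is clamped)."""

    values: np.ndarray
    label: str = ""
    standoff: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


def covariance(data: DataMatrix | np.ndarray, center: bool = True) -> np.ndarray:
    """Channel covariance of a channels x observations matrix.

    ``C[i, j]`` is the mean over observations of the (optionally mean-
    centered) products of channels i and j.  Centering across observations is
    the PCA convention and the default; the no-centering variant is kept as a
    sensitivity toggle.
    """
    x = data.data if isinstance(data, DataMatrix) else np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("covariance needs a 2-D matrix with >= 2 observations")
    if center:
        x = x - x.mean(axis=1, keepdims=True)
    return (x @ x.T) / x.shape[1]


def eigenspectrum(C: np.ndarray, label: str = "", standoff: float = 0.0) -> EigenSpectrum:
    """Descending eigenvalues of a symmetric PSD matrix, normalized by the
    largest."""
    C = np.asarray(C, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("covariance must be square")
    if np.max(np.abs(C - C.T)) > 1e-9 * max(np.max(np.abs(C)), 1.0):
        raise ValueError("covariance must be symmetric")
    vals = np.linalg.eigvalsh(C)[::-1]
    vals = np.clip(vals, 0.0, None)
    top = vals[0]
    if top <= 0.0:
        return EigenSpectrum(np.zeros_like(vals), label, standoff)
    return EigenSpectrum(vals / top, label, standoff)


def count_detectable(spectrum: EigenSpectrum, noise_to_signal: float) -> int:
    """Number of normalized eigenvalues strictly above the noise-to-signal
    power threshold (non-increasing in the threshold)."""
    if not 0.0 < noise_to_signal <= 1.0:
        raise ValueError("noise_to_signal must be in (0, 1]")
    return int(np.sum(spectrum.values > noise_to_signal))


def signal_ratio_curve(
    field_spectrum: EigenSpectrum,
    potential_spectrum: EigenSpectrum,
    thresholds: np.ndarray,
) -> pd.DataFrame:
    """Field/potential detectable-signal count ratio over a threshold grid.

    Returns a tidy frame with columns ``threshold``, ``count_field``,
    ``count_potential``, ``ratio``; the ratio is NaN where the potential
    count is zero (undefined, flagged rather than dropped).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    n_field = np.array([count_detectable(field_spectrum, t) for t in thresholds])
    n_pot = np.array([count_detectable(potential_spectrum, t) for t in thresholds])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(n_pot > 0, n_field / np.where(n_pot > 0, n_pot, 1), np.nan)
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "count_field": n_field,
            "count_potential": n_pot,
            "ratio": ratio,
        }
    )


def threshold_grid(
    band: tuple[float, float] = DEFAULT_THRESHOLD_BAND, n: int = 25
) -> np.ndarray:
    """Log-spaced noise-to-signal thresholds spanning the evaluation band."""
    return np.logspace(np.log10(band[0]), np.log10(band[1]), n)
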