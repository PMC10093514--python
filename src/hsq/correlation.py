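"""Band-wise Pearson correlation between spectra and concentrations."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .datasets import SpectraSet

__all__ = ["CorrelationProfile", "correlate", "max_abs_correlation"]


@dataclass
class CorrelationProfile:
    """Per-band Pearson r between one transform's spectra and one analyte."""

    wavelengths: np.ndarray
    r: np.ndarray  # NaN at invalid bands
    analyte: str
    transform_tag: str
    valid_mask: np.ndarray


def correlate(spectra: SpectraSet, y: np.ndarray, analyte: str = "") -> CorrelationProfile:
    """Pearson r per valid band, across all samples.

    Zero-variance bands are masked with a warning rather than producing
    NaN/inf correlations.
    """
    y = np.asarray(y, dtype=float)
    n = spectra.n_samples
    if n < 3:
        raise ValueError("correlation needs at least 3 samples")
    if y.shape != (n,):
        raise ValueError("y must align with spectra rows")
    yc = y - y.mean()
    sy = np.sqrt(yc @ yc)
    if sy == 0.0:
        raise ValueError("y has zero variance")

    X = spectra.reflectance
    mask = spectra.valid_mask.copy()
    r = np.full(spectra.n_bands, np.nan)
    Xv = X[:, mask]
    Xc = Xv - Xv.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    col_scale = np.maximum(np.abs(Xv).max(axis=0), 1e-300)
    zero_var = sx <= 1e-12 * np.sqrt(n) * col_scale
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance bands masked in correlation",
            stacklevel=2,
        )
    rv = np.full(Xv.shape[1], np.nan)
    ok = ~zero_var
    rv[ok] = (Xc[:, ok].T @ yc) / (sx[ok] * sy)
    r[mask] = rv
    new_mask = mask.copy()
    new_mask[mask] = ok
    return CorrelationProfile(
        wavelengths=spectra.wavelengths.copy(),
        r=r,
        analyte=analyte,
        transform_tag=spectra.transform_tag,
        valid_mask=new_mask,
    )


def max_abs_correlation(profile: CorrelationProfile) -> tuple[float, float]:
    """(wavelength, r) of the band with maximal |r|; ties -> lowest wavelength."""
    if not profile.valid_mask.any():
        raise ValueError("profile has no valid bands")
    absr = np.where(profile.valid_mask, np.abs(profile.r), -np.inf)
    k = int(np.argmax(absr))  # first occurrence = lowest wavelength
    return float(profile.wavelengths[k]), float(profile.r[k])
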