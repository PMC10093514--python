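"""Spectral preprocessing transforms.

Six pure transforms SpectraSet -> SpectraSet:

* MSC  - multiplicative scatter correction: per-sample OLS against the
  mean spectrum, corrected spectrum = (x - intercept) / slope.
* SNV  - standard normal variate: per-spectrum standardization to mean 0,
  SD 1 (population convention); a ``global`` mode pools mean/SD over all
  samples.
* Lg   - absorbance transform log10(1/R).
* FD/SD - first/second derivative on the uniform band grid (central
  3-point stencil by default, literal forward differences optionally).
* FOD  - Gruenwald-Letnikov fractional-order derivative of any real
  order alpha, a weighted sum of the current and previous ``t`` bands
  with weights w_m = (-1)^m * binom(alpha, m).

The step size is one band (1 nm grids give units "per band^alpha").
Bands a stencil or burn-in cannot reach are masked, never extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .datasets import SpectraSet

__all__ = [
    "MSCModel",
    "GLWeights",
    "msc",
    "snv",
    "lg",
    "derivative_int",
    "gl_weights",
    "fod",
]


@dataclass
class MSCModel:
    """Reference spectrum and per-sample regression coefficients."""

    reference_spectrum: np.ndarray  # over valid bands
    slope: np.ndarray  # b_i per sample
    offset: np.ndarray  # c_i per sample


@dataclass
class GLWeights:
    """Gruenwald-Letnikov weights w_0..w_t for a given fractional order."""

    order: float
    window: int
    weights: np.ndarray

    @property
    def support(self) -> int:
        """Index of the last nonzero weight (== order for integer orders)."""
        nz = np.nonzero(self.weights)[0]
        return int(nz[-1]) if nz.size else 0


def _masked_output(
    spectra: SpectraSet, values: np.ndarray, tag: str, mask: np.ndarray
) -> SpectraSet:
    out = values.copy()
    out[:, ~mask] = np.nan
    return spectra.with_values(out, tag, valid_mask=mask)


def msc(spectra: SpectraSet) -> tuple[SpectraSet, MSCModel]:
    """Multiplicative scatter correction against the mean spectrum.

    The mean spectrum over samples is the reference; each sample is
    regressed on it (OLS over valid bands) to estimate a multiplicative
    slope b_i and additive offset c_i, and corrected as (x_i - c_i)/b_i.
    """
    if spectra.n_samples < 2:
        raise ValueError("MSC needs at least 2 samples")
    X = spectra.valid_reflectance
    if X.shape[1] < 2:
        raise ValueError("MSC needs at least 2 valid bands")
    ref = X.mean(axis=0)
    ref_c = ref - ref.mean()
    denom = float(ref_c @ ref_c)
    if denom <= 1e-24 * max(float(np.abs(ref).max()) ** 2, 1e-300):
        raise ValueError("reference spectrum has zero variance; MSC undefined")
    slope = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    # a flat sample has no variance against the reference: slope undefined
    row_sd = X.std(axis=1, ddof=0)
    row_scale = np.maximum(np.abs(X).max(axis=1), 1e-300)
    bad = ~np.isfinite(slope) | (slope == 0.0) | (row_sd <= 1e-12 * row_scale)
    if bad.any():
        ids = [spectra.sample_ids[i] for i in np.nonzero(bad)[0]]
        raise ValueError(f"MSC slope undefined or zero for samples {ids}")
    offset = X.mean(axis=1) - slope * ref.mean()

    corrected = np.full_like(spectra.reflectance, np.nan)
    corrected[:, spectra.valid_mask] = (X - offset[:, None]) / slope[:, None]
    out = spectra.with_values(corrected, "MSC")
    return out, MSCModel(reference_spectrum=ref, slope=slope, offset=offset)


def snv(spectra: SpectraSet, mode: str = "per_spectrum") -> SpectraSet:
    """Standard normal variate.

    ``per_spectrum`` (default): each row standardized by its own mean and
    population SD.  ``global``: one mean and SD pooled over every valid
    value standardize the whole matrix (a single affine map, kept for
    literal comparisons).
    """
    X = spectra.valid_reflectance
    out = np.full_like(spectra.reflectance, np.nan)
    if mode == "per_spectrum":
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, ddof=0, keepdims=True)
        scale = np.maximum(np.abs(X).max(axis=1), 1e-300)
        bad = np.nonzero(sd.ravel() <= 1e-12 * scale)[0]
        if bad.size:
            ids = [spectra.sample_ids[i] for i in bad]
            raise ValueError(f"zero-variance spectra, SNV undefined: {ids}")
        out[:, spectra.valid_mask] = (X - mu) / sd
    elif mode == "global":
        mu = X.mean()
        sd = X.std(ddof=0)
        if sd <= 1e-12 * max(float(np.abs(X).max()), 1e-300):
            raise ValueError("pooled SD is zero; global SNV undefined")
        out[:, spectra.valid_mask] = (X - mu) / sd
    else:
        raise ValueError(f"unknown SNV mode {mode!r}")
    return spectra.with_values(out, "SNV")


def lg(spectra: SpectraSet) -> SpectraSet:
    """Reciprocal-logarithm (absorbance) transform log10(1/R)."""
    X = spectra.valid_reflectance
    if np.any(X <= 0):
        rows, cols = np.nonzero(X <= 0)
        wl = spectra.valid_wavelengths
        offenders = [
            f"{spectra.sample_ids[r]}@{wl[c]:g}nm" for r, c in zip(rows[:5], cols[:5])
        ]
        raise ValueError(f"non-positive reflectance, Lg undefined: {offenders}")
    out = np.full_like(spectra.reflectance, np.nan)
    out[:, spectra.valid_mask] = -np.log10(X)
    return spectra.with_values(out, "Lg")


def _erode_mask(mask: np.ndarray, offsets: tuple[int, ...]) -> np.ndarray:
    """Band j stays valid iff every band j+o (o in offsets) exists and is valid."""
    n = mask.size
    out = np.ones(n, dtype=bool)
    idx = np.arange(n)
    for o in offsets:
        shifted = idx + o
        ok = (shifted >= 0) & (shifted < n)
        contrib = np.zeros(n, dtype=bool)
        contrib[ok] = mask[shifted[ok]]
        out &= contrib
    return out


def derivative_int(spectra: SpectraSet, order: int, scheme: str = "central_3pt") -> SpectraSet:
    """First or second spectral derivative with unit band step.

    ``central_3pt`` (default): FD_j = (f_{j+1} - f_{j-1}) / 2,
    SD_j = f_{j+1} - 2 f_j + f_{j-1}.  ``forward``: literal forward
    differences f_{j+1} - f_j and f_{j+2} - 2 f_{j+1} + f_j.  Bands whose
    stencil leaves the grid (or touches an invalid band) are masked.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if spectra.valid_mask.sum() < 3:
        raise ValueError("derivative needs at least 3 valid bands")
    X = spectra.reflectance
    out = np.full_like(X, np.nan)
    if scheme == "central_3pt":
        if order == 1:
            out[:, 1:-1] = (X[:, 2:] - X[:, :-2]) / 2.0
        else:
            out[:, 1:-1] = X[:, 2:] - 2.0 * X[:, 1:-1] + X[:, :-2]
        offsets = (-1, 0, 1)
    elif scheme == "forward":
        if order == 1:
            out[:, :-1] = X[:, 1:] - X[:, :-1]
            offsets = (0, 1)
        else:
            out[:, :-2] = X[:, 2:] - 2.0 * X[:, 1:-1] + X[:, :-2]
            offsets = (0, 1, 2)
    else:
        raise ValueError(f"unknown derivative scheme {scheme!r}")
    mask = _erode_mask(spectra.valid_mask, offsets)
    tag = "FD" if order == 1 else "SD"
    return _masked_output(spectra, out, tag, mask)


def gl_weights(alpha: float, t: int) -> GLWeights:
    """Gruenwald-Letnikov weights by the pole-free recurrence.

    w_0 = 1 and w_m = w_{m-1} * (m - 1 - alpha) / m, equivalently
    w_m = (-1)^m * binom(alpha, m).  For integer alpha = k the weights
    vanish exactly beyond m = k, recovering the classical finite
    differences.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if t < 1:
        raise ValueError("window t must be >= 1")
    w = np.empty(t + 1)
    w[0] = 1.0
    for m in range(1, t + 1):
        w[m] = w[m - 1] * (m - 1 - alpha) / m
    return GLWeights(order=float(alpha), window=int(t), weights=w)


def fod(spectra: SpectraSet, alpha: float, t: int = 40) -> SpectraSet:
    """Fractional-order derivative along the band axis (G-L scheme).

    output_j = sum_{m=0..min(s, j)} w_m * f_{j-m} where s is the weight
    support (s = alpha for integer alpha, s = t otherwise).  The first s
    bands lack history and are masked; alpha = 0 returns the input
    unchanged apart from the transform tag.
    """
    if not 0.0 <= alpha <= 2.0:
        raise ValueError("alpha must lie in [0, 2]")
    tag = f"FOD:{alpha:g}"
    if alpha == 0.0:
        return spectra.with_values(spectra.reflectance.copy(), tag)
    glw = gl_weights(alpha, t)
    support = glw.support
    w = glw.weights[: support + 1]
    X = spectra.reflectance
    n_bands = X.shape[1]
    out = np.zeros_like(X)
    for m, wm in enumerate(w):
        if wm == 0.0:
            continue
        out[:, m:] += wm * X[:, : n_bands - m]
    burn = np.zeros(n_bands, dtype=bool)
    burn[support:] = True
    mask = _erode_mask(spectra.valid_mask, tuple(range(-support, 1))) & burn
    return _masked_output(spectra, out, tag, mask)
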