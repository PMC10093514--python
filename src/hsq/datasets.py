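"""Core in-memory containers for spectra and analyte concentrations.

A :class:`SpectraSet` is a wide matrix of reflectance values (samples x
wavelengths) on a uniform, strictly increasing wavelength grid, together
with a per-band validity mask.  Bands become invalid when a derivative
stencil or fractional-derivative burn-in cannot be evaluated; invalid
bands carry NaN and are excluded from every downstream distance,
correlation and model fit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpectraSet", "AnalyteTable", "trim_bands"]


@dataclass
class SpectraSet:
    """Samples x wavelengths reflectance matrix with a band validity mask.

    Parameters
    ----------
    sample_ids
        One label per row.
    wavelengths
        Strictly increasing, uniformly spaced grid in nm.
    reflectance
        Matrix of shape ``(len(sample_ids), len(wavelengths))``.  For raw
        reflectance (``transform_tag == "R"``) values lie in (0, 1];
        transformed spectra may take any real value.
    transform_tag
        Label recording the applied preprocessing, e.g. ``"R"``, ``"MSC"``,
        ``"FOD:1.6"``.
    valid_mask
        Boolean per-band flags; ``None`` means all bands valid.
    """

    sample_ids: list[str]
    wavelengths: np.ndarray
    reflectance: np.ndarray
    transform_tag: str = "R"
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.sample_ids = list(self.sample_ids)
        if self.wavelengths.ndim != 1 or self.wavelengths.size < 2:
            raise ValueError("wavelength grid needs at least 2 points")
        steps = np.diff(self.wavelengths)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-9):
            raise ValueError("wavelength grid must be uniformly spaced")
        if self.reflectance.shape != (len(self.sample_ids), self.wavelengths.size):
            raise ValueError(
                f"reflectance shape {self.reflectance.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.wavelengths.size} bands"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.wavelengths.size, dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.wavelengths.shape:
                raise ValueError("valid_mask length must equal band count")
        if np.isnan(self.reflectance[:, self.valid_mask]).any():
            raise ValueError("NaN inside the declared valid band range")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    @property
    def valid_reflectance(self) -> np.ndarray:
        """Matrix restricted to valid bands."""
        return self.reflectance[:, self.valid_mask]

    @property
    def valid_wavelengths(self) -> np.ndarray:
        return self.wavelengths[self.valid_mask]

    def with_values(
        self,
        reflectance: np.ndarray,
        transform_tag: str,
        valid_mask: np.ndarray | None = None,
    ) -> "SpectraSet":
        """New SpectraSet on the same samples/grid with replaced values."""
        return SpectraSet(
            sample_ids=list(self.sample_ids),
            wavelengths=self.wavelengths.copy(),
            reflectance=np.asarray(reflectance, dtype=float),
            transform_tag=transform_tag,
            valid_mask=self.valid_mask.copy() if valid_mask is None else valid_mask,
        )

    def copy(self) -> "SpectraSet":
        return dataclasses.replace(
            self,
            sample_ids=list(self.sample_ids),
            wavelengths=self.wavelengths.copy(),
            reflectance=self.reflectance.copy(),
            valid_mask=self.valid_mask.copy(),
        )


@dataclass
class AnalyteTable:
    """Per-sample analyte concentrations in % of dry powder mass."""

    sample_ids: list[str]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        clean: dict[str, np.ndarray] = {}
        for name, v in self.values.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (len(self.sample_ids),):
                raise ValueError(f"analyte {name!r} length mismatch")
            if np.any(v <= 0):
                raise ValueError(f"analyte {name!r} has non-positive values")
            clean[name] = v
        self.values = clean

    @property
    def analytes(self) -> list[str]:
        return list(self.values)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]


def trim_bands(spectra: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Drop bands outside [lo, hi] nm (e.g. noisy instrument edges)."""
    if lo >= hi:
        raise ValueError("band range lower bound must be below upper bound")
    keep = (spectra.wavelengths >= lo) & (spectra.wavelengths <= hi)
    if keep.sum() < 2:
        raise ValueError("band range keeps fewer than 2 bands")
    return SpectraSet(
        sample_ids=list(spectra.sample_ids),
        wavelengths=spectra.wavelengths[keep],
        reflectance=spectra.reflectance[:, keep],
        transform_tag=spectra.transform_tag,
        valid_mask=spectra.valid_mask[keep],
    )
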