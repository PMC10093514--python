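"""Calibration/validation partitioning by SPXY.

SPXY (sample-set partitioning based on joint X-Y distances) is a
Kennard-Stone-style greedy maximin selection on the normalized sum of a
spectral distance and a response distance, so the calibration set spans
both spectral space and the concentration range.  Everything is
deterministic: ties are broken toward the lowest original sample index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .datasets import SpectraSet

__all__ = ["SplitAssignment", "spxy_split", "n_cal_for_ratio"]


@dataclass
class SplitAssignment:
    """Disjoint calibration/validation partition of the sample set."""

    calibration_ids: list[str]
    validation_ids: list[str]
    ratio: tuple[int, int]
    target_analyte: str

    @property
    def n_cal(self) -> int:
        return len(self.calibration_ids)

    @property
    def n_val(self) -> int:
        return len(self.validation_ids)


def n_cal_for_ratio(n: int, ratio: tuple[int, int] = (2, 1)) -> int:
    """Calibration size for an n-sample set at cal:val = ratio (96 @ 2:1 -> 64)."""
    c, v = ratio
    return int(round(n * c / (c + v)))


def joint_distances(X: np.ndarray, y: np.ndarray, y_weight: float = 1.0) -> np.ndarray:
    """d(i,j) = d_x/max(d_x) + y_weight * d_y/max(d_y).

    ``y_weight = 0`` degenerates to Kennard-Stone on X alone (kept for
    testing).
    """
    dx = cdist(X, X, metric="euclidean")
    dx_max = dx.max()
    if dx_max == 0.0:
        raise ValueError("all samples identical in X; SPXY distances degenerate")
    d = dx / dx_max
    if y_weight != 0.0:
        dy = np.abs(y[:, None] - y[None, :])
        dy_max = dy.max()
        if dy_max == 0.0:
            raise ValueError("all samples identical in y; SPXY distances degenerate")
        d = d + y_weight * dy / dy_max
    return d


def spxy_split(
    spectra: SpectraSet,
    y: np.ndarray,
    n_cal: int,
    target_analyte: str = "",
    y_weight: float = 1.0,
) -> SplitAssignment:
    """Greedy maximin selection of ``n_cal`` calibration samples.

    Seeds with the pair at maximal joint distance, then repeatedly adds
    the sample whose minimum joint distance to the selected set is
    largest.  The selection at k is by construction a subset of the
    selection at k+1.
    """
    y = np.asarray(y, dtype=float)
    n = spectra.n_samples
    if y.shape != (n,):
        raise ValueError("y must align with spectra rows")
    if not 2 <= n_cal <= n - 1:
        raise ValueError(f"n_cal must lie in [2, {n - 1}]")
    d = joint_distances(spectra.valid_reflectance, y, y_weight=y_weight)

    # argmax in row-major order = lowest (i, j) on ties
    i, j = np.unravel_index(int(np.argmax(d)), d.shape)
    selected = [min(i, j), max(i, j)]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    min_to_set = np.minimum(d[selected[0]], d[selected[1]])
    while len(selected) < n_cal:
        cand = np.where(in_set, -np.inf, min_to_set)
        nxt = int(np.argmax(cand))  # first occurrence = lowest index
        selected.append(nxt)
        in_set[nxt] = True
        min_to_set = np.minimum(min_to_set, d[nxt])

    cal_ids = [spectra.sample_ids[k] for k in selected]
    val_ids = [spectra.sample_ids[k] for k in range(n) if not in_set[k]]
    g = int(np.gcd(n_cal, n - n_cal))
    return SplitAssignment(
        calibration_ids=cal_ids,
        validation_ids=val_ids,
        ratio=(n_cal // g, (n - n_cal) // g),
        target_analyte=target_analyte,
    )
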