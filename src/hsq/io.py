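"""CSV/JSON readers and writers for the pipeline's artifacts.

Spectra CSV: an optional ``# transform_tag: <tag>`` comment line, then a
``sample_id`` column followed by one column per wavelength named by its
value in nm; masked bands are written as empty fields.  Analyte CSV:
``sample_id`` plus one column per analyte (%).  Values round-trip
losslessly (shortest-repr floats).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chemometrics import CVCurve, ModelReport
from .correlation import CorrelationProfile
from .datasets import AnalyteTable, SpectraSet
from .sampling import SplitAssignment

__all__ = [
    "write_spectra_csv",
    "read_spectra_csv",
    "write_analytes_csv",
    "read_analytes_csv",
    "write_split_json",
    "read_split_json",
    "report_to_dict",
    "write_reports_json",
    "write_correlation_csv",
]


def _fmt_wavelength(w: float) -> str:
    return f"{w:g}"


def write_spectra_csv(spectra: SpectraSet, path: str | Path) -> None:
    df = pd.DataFrame(
        spectra.reflectance,
        columns=[_fmt_wavelength(w) for w in spectra.wavelengths],
    )
    df.insert(0, "sample_id", spectra.sample_ids)
    invalid = [_fmt_wavelength(w) for w in spectra.wavelengths[~spectra.valid_mask]]
    df[invalid] = np.nan
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# transform_tag: {spectra.transform_tag}\n")
        # %.17g round-trips float64 exactly
        df.to_csv(fh, index=False, na_rep="", float_format="%.17g")


def read_spectra_csv(path: str | Path) -> SpectraSet:
    path = Path(path)
    tag = "R"
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("#"):
        _, _, value = first.partition(":")
        tag = value.strip() or "R"
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    ids = df["sample_id"].astype(str).tolist()
    wl = np.array([float(c) for c in df.columns[1:]])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    mask = ~np.isnan(values).any(axis=0)
    return SpectraSet(
        sample_ids=ids,
        wavelengths=wl,
        reflectance=values,
        transform_tag=tag,
        valid_mask=mask,
    )


def write_analytes_csv(table: AnalyteTable, path: str | Path) -> None:
    df = pd.DataFrame({"sample_id": table.sample_ids})
    for name in table.analytes:
        df[name] = table[name]
    df.to_csv(path, index=False, float_format="%.17g")


def read_analytes_csv(path: str | Path) -> AnalyteTable:
    df = pd.read_csv(path, float_precision="round_trip")
    ids = df["sample_id"].astype(str).tolist()
    values = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "sample_id"}
    return AnalyteTable(sample_ids=ids, values=values)


def write_split_json(split: SplitAssignment, path: str | Path) -> None:
    payload = {
        "target_analyte": split.target_analyte,
        "ratio": list(split.ratio),
        "calibration_ids": split.calibration_ids,
        "validation_ids": split.validation_ids,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_split_json(path: str | Path) -> SplitAssignment:
    payload = json.loads(Path(path).read_text())
    return SplitAssignment(
        calibration_ids=list(payload["calibration_ids"]),
        validation_ids=list(payload["validation_ids"]),
        ratio=tuple(payload["ratio"]),
        target_analyte=payload["target_analyte"],
    )


def report_to_dict(report: ModelReport) -> dict:
    d = dataclasses.asdict(report)
    curve = d.pop("cv_curve")
    if curve is not None:
        d["rmse_cv"] = [float(v) for v in curve["rmse_cv"]]
        d["chosen_lv"] = int(curve["chosen_lv"])
    for key in ("r2_c", "rmse_c", "r2_v", "rmse_v", "rpd"):
        d[key] = None if np.isnan(d[key]) else float(d[key])
    return d


def write_reports_json(reports: list[ModelReport], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([report_to_dict(r) for r in reports], indent=1, sort_keys=True) + "\n"
    )


def write_correlation_csv(profile: CorrelationProfile, path: str | Path) -> None:
    df = pd.DataFrame({"wavelength": profile.wavelengths, "r": profile.r})
    df.loc[~profile.valid_mask, "r"] = np.nan
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# transform_tag: {profile.transform_tag}, analyte: {profile.analyte}\n"
        )
        df.to_csv(fh, index=False, na_rep="")
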