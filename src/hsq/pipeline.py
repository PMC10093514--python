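"""End-to-end study orchestration.

One run: simulate (or load) spectra + analytes, trim the noisy edge
bands, compute one SPXY calibration/validation split per analyte on the
raw spectra, then for every preprocessing variant (raw R, MSC, SNV, Lg,
FD, SD, and the fractional-derivative sweep) select the latent-variable
count by leave-one-out CV on the calibration set, fit PLSR, evaluate on
the validation set, compute the band-wise correlation profile, and rank
all models per analyte by validation RPD.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from .chemometrics import ModelReport, evaluate, fit_plsr, loocv_curve
from .correlation import CorrelationProfile, correlate
from .datasets import AnalyteTable, SpectraSet, trim_bands
from .preprocess import derivative_int, fod, lg, msc, snv
from .sampling import SplitAssignment, n_cal_for_ratio, spxy_split
from .simulate import SimConfig, make_dataset

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "DEFAULT_FOD_ORDERS",
    "expand_roster",
    "apply_transform",
    "rank_models",
    "run_pipeline",
]

logger = logging.getLogger("hsq")

#: fractional-derivative sweep: 0.1..2.0 in steps of 0.1 (order 0
#: duplicates the raw spectrum and is deduplicated out of the roster).
DEFAULT_FOD_ORDERS: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 21))

NAMED_TRANSFORMS = ("R", "MSC", "SNV", "Lg", "FD", "SD")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full study run."""

    sim: SimConfig | None = None
    spectra_path: str | None = None
    analytes_path: str | None = None
    band_range: tuple[float, float] = (401.0, 2450.0)
    roster: tuple[str, ...] = NAMED_TRANSFORMS
    fod_orders: tuple[float, ...] = DEFAULT_FOD_ORDERS
    fod_window: int = 40
    fd_scheme: str = "central_3pt"
    snv_mode: str = "per_spectrum"
    split_ratio: tuple[int, int] = (2, 1)
    max_lv: int = 20
    targets: tuple[str, ...] = ("total_flavonoids", "total_phenols")
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.sim is None and (self.spectra_path is None or self.analytes_path is None):
            object.__setattr__(self, "sim", SimConfig())
        for a in self.fod_orders:
            if not 0.0 <= a <= 2.0:
                raise ValueError("fod orders must lie in [0, 2]")
        for tag in self.roster:
            if tag not in NAMED_TRANSFORMS:
                raise ValueError(f"unrecognized roster tag {tag!r}")


@dataclass
class PipelineResult:
    reports: list[ModelReport]
    profiles: list[CorrelationProfile]
    splits: dict[str, SplitAssignment]
    ranking: pd.DataFrame
    manifest: dict


def expand_roster(config: PipelineConfig) -> list[str]:
    """Named transforms plus the FOD sweep; order 0 deduplicates to R."""
    tags = list(config.roster)
    for a in config.fod_orders:
        if a == 0.0:
            continue  # FOD:0 is the raw spectrum, already in the roster as R
        tags.append(f"FOD:{a:g}")
    return tags


def apply_transform(spectra: SpectraSet, tag: str, config: PipelineConfig) -> SpectraSet:
    if tag == "R":
        return spectra
    if tag == "MSC":
        return msc(spectra)[0]
    if tag == "SNV":
        return snv(spectra, mode=config.snv_mode)
    if tag == "Lg":
        return lg(spectra)
    if tag == "FD":
        return derivative_int(spectra, 1, scheme=config.fd_scheme)
    if tag == "SD":
        return derivative_int(spectra, 2, scheme=config.fd_scheme)
    if tag.startswith("FOD:"):
        return fod(spectra, float(tag[4:]), t=config.fod_window)
    raise ValueError(f"unknown transform tag {tag!r}")


def rank_models(reports: list[ModelReport]) -> pd.DataFrame:
    """Per-analyte ranking by validation RPD (desc); ties -> higher R^2_v,
    then fewer latent variables.  Missing RPDs sink to the bottom with a
    warning; exactly one best flag per analyte."""
    if not reports:
        raise ValueError("no reports to rank")
    rows = []
    for r in reports:
        rows.append(
            {
                "analyte": r.analyte,
                "transform_tag": r.transform_tag,
                "rpd": r.rpd,
                "r2_v": r.r2_v,
                "rmse_v": r.rmse_v,
                "r2_c": r.r2_c,
                "rmse_c": r.rmse_c,
                "n_lv": r.n_lv,
            }
        )
    df = pd.DataFrame(rows)
    if df["rpd"].isna().any():
        warnings.warn("reports with missing RPD ranked last", stacklevel=2)
    df["_rpd_sort"] = df["rpd"].fillna(-np.inf)
    df = df.sort_values(
        by=["analyte", "_rpd_sort", "r2_v", "n_lv"],
        ascending=[True, False, False, True],
        kind="mergesort",
    ).drop(columns="_rpd_sort")
    df["best"] = False
    df.loc[df.groupby("analyte").head(1).index, "best"] = True
    return df.reset_index(drop=True)


def _config_hash(config: PipelineConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("outdir", None)  # the same study written elsewhere is the same study
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _load_inputs(config: PipelineConfig) -> tuple[SpectraSet, AnalyteTable]:
    if config.spectra_path is not None and config.analytes_path is not None:
        return (
            hio.read_spectra_csv(config.spectra_path),
            hio.read_analytes_csv(config.analytes_path),
        )
    return make_dataset(config.sim)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Deterministic end-to-end run; artifacts written when outdir is set."""
    t0 = time.perf_counter()
    stage = "load"
    tag = ""
    try:
        spectra, analytes = _load_inputs(config)
        stage = "trim"
        spectra = trim_bands(spectra, *config.band_range)

        stage = "split"
        splits: dict[str, SplitAssignment] = {}
        idx = {sid: i for i, sid in enumerate(spectra.sample_ids)}
        n_cal = n_cal_for_ratio(spectra.n_samples, config.split_ratio)
        for target in config.targets:
            splits[target] = spxy_split(
                spectra, analytes[target], n_cal, target_analyte=target
            )
        logger.info("split: %d cal / %d val (%.2fs)", n_cal,
                    spectra.n_samples - n_cal, time.perf_counter() - t0)

        reports: list[ModelReport] = []
        profiles: list[CorrelationProfile] = []
        for tag in expand_roster(config):
            t_tag = time.perf_counter()
            stage = "transform"
            ts = apply_transform(spectra, tag, config)
            X = ts.valid_reflectance
            for target in config.targets:
                y = analytes[target]
                stage = "correlate"
                profiles.append(correlate(ts, y, analyte=target))
                split = splits[target]
                cal = [idx[s] for s in split.calibration_ids]
                val = [idx[s] for s in split.validation_ids]
                Xc, yc = X[cal], y[cal]
                Xv, yv = X[val], y[val]
                stage = "loocv"
                curve = loocv_curve(Xc, yc, max_lv=config.max_lv)
                stage = "fit"
                model = fit_plsr(Xc, yc, curve.chosen_lv)
                stage = "evaluate"
                reports.append(
                    evaluate(model, Xc, yc, Xv, yv, transform_tag=tag,
                             analyte=target, cv_curve=curve)
                )
            logger.info("transform %s done (%.2fs)", tag, time.perf_counter() - t_tag)

        stage = "rank"
        tag = ""
        ranking = rank_models(reports)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}"
            + (f" (transform {tag!r})" if tag else "")
            + f": {exc}"
        ) from exc

    manifest = {
        "config_hash": _config_hash(config),
        "seed": None if config.sim is None else config.sim.seed,
        "n_samples": spectra.n_samples,
        "n_models": len(reports),
        "package_version": _package_version(),
    }
    result = PipelineResult(
        reports=reports, profiles=profiles, splits=splits,
        ranking=ranking, manifest=manifest,
    )
    if config.outdir is not None:
        _write_artifacts(result, Path(config.outdir))
    logger.info("pipeline: %d models in %.1fs", len(reports), time.perf_counter() - t0)
    return result


def _package_version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("hsq")
    except PackageNotFoundError:
        return "unknown"


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    hio.write_reports_json(result.reports, outdir / "model_reports.json")
    result.ranking.to_csv(outdir / "ranking.csv", index=False)
    for target, split in result.splits.items():
        hio.write_split_json(split, outdir / f"split_{target}.json")
    corr_dir = outdir / "correlations"
    corr_dir.mkdir(exist_ok=True)
    for profile in result.profiles:
        fname = f"corr_{profile.analyte}_{profile.transform_tag.replace(':', '')}.csv"
        hio.write_correlation_csv(profile, corr_dir / fname)
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True) + "\n"
    )
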