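"""Synthetic grain-powder reflectance generator.

Emulates a 96-sample Tartary-buckwheat grain-powder dataset: per-sample
total-flavonoids and total-phenols concentrations drawn from
moment-matched truncated normals (so the generated population reproduces
the reported mean / SD / min / max of the field study), and 350-2500 nm
reflectance built from a Beer-Lambert absorbance model,

    A_i(lambda) = baseline(lambda)
                  + sum_analytes sum_bands gain * c_i * G(lambda; center, width),
    R_i = 10^(-A_i),

followed by per-sample multiplicative/additive scatter (a_i * R_i + b_i)
and band-dependent Gaussian noise (inflated outside 401-2450 nm, the
noisy edges of a field spectroradiometer).  Every artifact downstream
preprocessing is meant to remove is therefore planted with known ground
truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.stats import norm, truncnorm

from .datasets import AnalyteTable, SpectraSet

__all__ = [
    "AnalyteSpec",
    "SimConfig",
    "FLAVONOIDS",
    "PHENOLS",
    "generate_concentrations",
    "generate_spectra",
    "make_dataset",
    "analyte_summary",
]

#: wavelength range inside which instrument noise is at its core level;
#: outside it the generator inflates noise (motivates edge trimming).
CORE_BAND_RANGE = (401.0, 2450.0)

# absorbance cap: 10^-6 reflectance is far below any real measurement
_ABSORBANCE_CAP = 6.0
_REFLECTANCE_FLOOR = 1e-4


@dataclass(frozen=True)
class AnalyteSpec:
    """Target concentration distribution and planted absorption bands.

    ``mean``/``sd``/``min``/``max`` are in % of dry mass and define a
    truncated-normal concentration distribution.  ``band_centers`` (nm),
    ``band_widths`` (nm, Gaussian sigma) and ``band_gains`` (absorbance
    units per % concentration) define where and how strongly the analyte
    absorbs.
    """

    name: str
    mean: float
    sd: float
    min: float
    max: float
    band_centers: tuple[float, ...] = ()
    band_widths: tuple[float, ...] = ()
    band_gains: tuple[float, ...] = ()

    def validate(self, wavelengths: np.ndarray | None = None) -> None:
        if not self.min < self.mean < self.max:
            raise ValueError(
                f"analyte {self.name!r}: need min < mean < max "
                f"(got {self.min}, {self.mean}, {self.max})"
            )
        if self.sd < 0:
            raise ValueError(f"analyte {self.name!r}: sd must be >= 0")
        if not (
            len(self.band_centers) == len(self.band_widths) == len(self.band_gains)
        ):
            raise ValueError(f"analyte {self.name!r}: band lists must align")
        if any(w <= 0 for w in self.band_widths):
            raise ValueError(f"analyte {self.name!r}: band widths must be > 0")
        if wavelengths is not None:
            lo, hi = wavelengths[0], wavelengths[-1]
            for c in self.band_centers:
                if not lo <= c <= hi:
                    raise ValueError(
                        f"analyte {self.name!r}: band center {c} nm outside grid"
                    )


#: Total flavonoids: population statistics of the 96-sample field study
#: (mean 0.9733 %, SD 0.3653, range 0.4275-1.9275).  Absorption planted on
#: three NIR overtone/combination regions.
FLAVONOIDS = AnalyteSpec(
    name="total_flavonoids",
    mean=0.9733,
    sd=0.3653,
    min=0.4275,
    max=1.9275,
    band_centers=(1415.0, 1660.0, 2050.0),
    band_widths=(35.0, 40.0, 50.0),
    band_gains=(0.12, 0.10, 0.08),
)

#: Total phenols: mean 2.7298 %, SD 0.4352, range 1.9115-4.0968; bands
#: placed on distinct regions so the two signals are separable.
PHENOLS = AnalyteSpec(
    name="total_phenols",
    mean=2.7298,
    sd=0.4352,
    min=1.9115,
    max=4.0968,
    band_centers=(1130.0, 1780.0, 2240.0),
    band_widths=(40.0, 45.0, 55.0),
    band_gains=(0.05, 0.06, 0.045),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic acquisition."""

    n_samples: int = 96
    wavelength_start: float = 350.0
    wavelength_stop: float = 2500.0
    wavelength_step: float = 1.0
    analytes: tuple[AnalyteSpec, ...] = (FLAVONOIDS, PHENOLS)
    analyte_correlation: float = 0.6
    scatter_slope_sd: float = 0.05
    scatter_offset_sd: float = 0.01
    noise_sd_core: float = 0.0015
    noise_sd_edges: float = 0.006
    seed: int = 42

    def wavelengths(self) -> np.ndarray:
        n = int(round((self.wavelength_stop - self.wavelength_start) / self.wavelength_step)) + 1
        return self.wavelength_start + self.wavelength_step * np.arange(n)

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        wl = self.wavelengths()
        if wl.size < 2:
            raise ValueError("wavelength grid needs >= 2 points")
        for sd_name in ("scatter_slope_sd", "scatter_offset_sd", "noise_sd_core", "noise_sd_edges"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        if self.noise_sd_edges < self.noise_sd_core:
            raise ValueError("noise_sd_edges must be >= noise_sd_core")
        if not -1.0 <= self.analyte_correlation <= 1.0:
            raise ValueError("analyte_correlation must lie in [-1, 1]")
        for spec in self.analytes:
            spec.validate(wl)


@lru_cache(maxsize=32)
def _matched_parent_params(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Parent normal (mu, sigma) whose [lo, hi]-truncation has the target moments.

    Truncation shifts the mean and shrinks the SD, so drawing from
    N(mean, sd) truncated to the reported range would not reproduce the
    reported mean/SD.  Solve the two-moment matching problem instead.
    """

    def resid(p: np.ndarray) -> list[float]:
        mu, log_s = p
        s = float(np.exp(log_s))
        a, b = (lo - mu) / s, (hi - mu) / s
        m, v = truncnorm.stats(a, b, loc=mu, scale=s, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    sol = optimize.root(resid, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success or max(abs(r) for r in sol.fun) > 1e-8:
        raise RuntimeError(
            f"could not moment-match truncated normal for mean={mean}, sd={sd}, "
            f"range=[{lo}, {hi}]"
        )
    mu, log_s = sol.x
    return float(mu), float(np.exp(log_s))


def _truncnorm_ppf(u: np.ndarray, spec: AnalyteSpec) -> np.ndarray:
    mu, s = _matched_parent_params(spec.mean, spec.sd, spec.min, spec.max)
    a, b = (spec.min - mu) / s, (spec.max - mu) / s
    return truncnorm.ppf(u, a, b, loc=mu, scale=s)


def generate_concentrations(spec: AnalyteSpec, n: int, seed: int) -> np.ndarray:
    """Draw n concentrations (%) from the analyte's truncated normal.

    Deterministic for a fixed seed.  With ``sd == 0`` every draw equals
    the mean (degenerate distribution).
    """
    if spec.min >= spec.max:
        raise ValueError(f"analyte {spec.name!r}: min must be below max")
    spec.validate()
    if n < 1:
        raise ValueError("n must be >= 1")
    if spec.sd == 0:
        return np.full(n, spec.mean)
    rng = np.random.default_rng(seed)
    return _truncnorm_ppf(rng.random(n), spec)


def _correlated_concentrations(
    specs: tuple[AnalyteSpec, ...], n: int, rho: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Gaussian-copula draws: latent MVN with pairwise correlation rho,
    mapped through each analyte's truncated-normal quantile function."""
    k = len(specs)
    if rho >= 0.0:
        # equicorrelation factor model; exact (and singular-safe) at rho = 1
        g = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, k))
        z = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e
    else:
        cov = np.full((k, k), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(k), cov, size=n, method="cholesky")
    u = norm.cdf(z)
    out = {}
    for j, spec in enumerate(specs):
        if spec.min >= spec.max:
            raise ValueError(f"analyte {spec.name!r}: min must be below max")
        if spec.sd == 0:
            out[spec.name] = np.full(n, spec.mean)
        else:
            out[spec.name] = _truncnorm_ppf(u[:, j], spec)
    return out


def _baseline_absorbance(wl: np.ndarray) -> np.ndarray:
    """Matrix absorbance of analyte-free grain powder.

    A visible pigment edge, weak 970/1450 nm and strong 1940 nm water
    features, a slow NIR rise and a long-wavelength edge: the resulting
    reflectance rises from 350 nm, peaks near 800-1300 nm and then falls,
    with reflection peaks and absorption valleys along the way.
    """
    a = 0.32 * np.ones_like(wl)
    a += 0.55 * np.exp(-0.5 * ((wl - 420.0) / 130.0) ** 2)
    a += 0.06 * np.exp(-0.5 * ((wl - 970.0) / 40.0) ** 2)
    a += 0.16 * np.exp(-0.5 * ((wl - 1450.0) / 45.0) ** 2)
    a += 0.34 * np.exp(-0.5 * ((wl - 1940.0) / 65.0) ** 2)
    a += 0.25 * np.exp(-0.5 * ((wl - 2500.0) / 220.0) ** 2)
    a += 0.00022 * np.clip(wl - 1300.0, 0.0, None)
    return a


def clean_absorbance(concentrations: AnalyteTable, config: SimConfig) -> np.ndarray:
    """Noise-free absorbance matrix: baseline plus analyte Gaussian bands."""
    wl = config.wavelengths()
    a = np.tile(_baseline_absorbance(wl), (len(concentrations.sample_ids), 1))
    for spec in config.analytes:
        if spec.name not in concentrations.values:
            continue
        c = concentrations[spec.name]
        shape = np.zeros_like(wl)
        for center, width, gain in zip(spec.band_centers, spec.band_widths, spec.band_gains):
            shape += gain * np.exp(-0.5 * ((wl - center) / width) ** 2)
        a += np.outer(c, shape)
    return a


def generate_spectra(
    concentrations: AnalyteTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> SpectraSet:
    """Observed reflectance: Beer-Lambert signal + scatter + band noise.

    Per sample i: ``obs_i = a_i * 10^(-A_i) + b_i + eps`` with
    ``a_i ~ lognormal(0, scatter_slope_sd)``,
    ``b_i ~ N(0, scatter_offset_sd)`` and eps Gaussian with SD
    ``noise_sd_core`` inside 401-2450 nm, ``noise_sd_edges`` outside.
    Output clipped into (0, 1].
    """
    config.validate()
    if not concentrations.sample_ids:
        raise ValueError("concentrations table is empty")
    if rng is None:
        # child stream 1 of the master seed (stream 0 draws concentrations)
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    wl = config.wavelengths()
    a_mat = clean_absorbance(concentrations, config)
    if np.any(a_mat > _ABSORBANCE_CAP):
        warnings.warn(
            "absorbance exceeds cap; clipping to keep reflectance positive",
            stacklevel=2,
        )
        a_mat = np.minimum(a_mat, _ABSORBANCE_CAP)
    r = 10.0 ** (-a_mat)

    n = r.shape[0]
    slope = rng.lognormal(mean=0.0, sigma=config.scatter_slope_sd, size=n) \
        if config.scatter_slope_sd > 0 else np.ones(n)
    offset = rng.normal(0.0, config.scatter_offset_sd, size=n) \
        if config.scatter_offset_sd > 0 else np.zeros(n)
    core = (wl >= CORE_BAND_RANGE[0]) & (wl <= CORE_BAND_RANGE[1])
    noise_sd = np.where(core, config.noise_sd_core, config.noise_sd_edges)
    eps = rng.standard_normal((n, wl.size)) * noise_sd \
        if (config.noise_sd_core > 0 or config.noise_sd_edges > 0) else 0.0

    obs = slope[:, None] * r + offset[:, None] + eps
    obs = np.clip(obs, _REFLECTANCE_FLOOR, 1.0)
    return SpectraSet(
        sample_ids=list(concentrations.sample_ids),
        wavelengths=wl,
        reflectance=obs,
        transform_tag="R",
    )


def make_dataset(config: SimConfig) -> tuple[SpectraSet, AnalyteTable]:
    """Full synthetic acquisition: correlated concentrations, then spectra."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(2)
    conc_rng = np.random.default_rng(streams[0])
    values = _correlated_concentrations(
        config.analytes, config.n_samples, config.analyte_correlation, conc_rng
    )
    ids = [f"S{i + 1:03d}" for i in range(config.n_samples)]
    analytes = AnalyteTable(sample_ids=ids, values=values)
    spectra = generate_spectra(
        analytes, config, rng=np.random.default_rng(streams[1])
    )
    return spectra, analytes


def analyte_summary(values: np.ndarray) -> dict[str, float]:
    """Num / Min / Max / Ave / SD / CV summary (population SD)."""
    v = np.asarray(values, dtype=float)
    sd = float(v.std(ddof=0))
    mean = float(v.mean())
    return {
        "num": int(v.size),
        "min": float(v.min()),
        "max": float(v.max()),
        "ave": mean,
        "sd": sd,
        "cv": sd / mean,
    }
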