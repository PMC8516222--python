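"""Synthetic genotypes, weather, geography, exposures and phenotypes.

Everything downstream of raw data is exercised against this generator: the
phenotype model is y = Xb + Zg + W g_hs + e with polygenic effects drawn
multivariate-normal with covariance G*sigma2_g (and G_hs*sigma2_ghs on the
exposed subset), plus optional explicit causal-marker effects. Identical
configurations (including the seed) produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import climate
from .errors import ConfigurationError, SimulationError
from .geno_qc import GenotypeMatrix, Grm, mean_impute, subset_grm, vanraden_grm

# sub-seed keys so each operation has an independent, order-free stream
_KEY_MARKERS = 1
_KEY_GENOTYPES = 2
_KEY_WEATHER = 3
_KEY_POPULATION = 4
_KEY_PHENOTYPES = 5


@dataclass(frozen=True)
class FactorSpec:
    """A categorical fixed effect: number of levels and the range its level
    effects are drawn from (uniform)."""

    n_levels: int
    effect_range: tuple[float, float] = (-1.0, 1.0)


@dataclass(frozen=True)
class CausalMarker:
    """Explicit allele-substitution effect at one marker.

    ``main`` acts on all animals, ``interaction`` only on HS-exposed ones.
    """

    marker_index: int
    main: float = 0.0
    interaction: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    n_animals: int = 500
    n_snps: int = 1000
    n_chromosomes: int = 29
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    n_herds: int = 10
    n_stations: int = 5
    bounding_box: tuple[float, float, float, float] = (51.0, 54.5, 6.0, 14.5)  # lat0,lat1,lon0,lon1
    date_range: tuple[str, str] = ("2012-01-01", "2014-12-31")
    variance_components: tuple[float, float, float] = (0.3, 0.1, 0.6)  # (g, ghs, e)
    causal_spec: tuple[CausalMarker, ...] = ()
    fixed_effect_spec: tuple[FactorSpec, ...] = (FactorSpec(4, (-1.0, 1.0)),)
    hs_target_prevalence: float = 0.25
    confound_herd_exposure: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_animals < 2:
            raise ConfigurationError("n_animals must be >= 2")
        if self.n_snps < 1:
            raise ConfigurationError("n_snps must be >= 1")
        if self.n_chromosomes < 1:
            raise ConfigurationError("n_chromosomes must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be a probability < 1")
        if self.n_herds < 1 or self.n_stations < 1:
            raise ConfigurationError("n_herds and n_stations must be positive")
        s2g, s2ghs, s2e = self.variance_components
        if s2g < 0 or s2ghs < 0 or s2e <= 0:
            raise ConfigurationError(
                "variances must satisfy sigma2_g, sigma2_ghs >= 0 and sigma2_e > 0"
            )
        if pd.Timestamp(self.date_range[0]) > pd.Timestamp(self.date_range[1]):
            raise ConfigurationError("empty date_range")
        if not 0.0 <= self.hs_target_prevalence <= 1.0:
            raise ConfigurationError("hs_target_prevalence must be a probability")
        for c in self.causal_spec:
            if not 0 <= c.marker_index < self.n_snps:
                raise ConfigurationError(f"causal marker index {c.marker_index} out of range")

    def rng(self, key: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, key])


def simulate_markers(config: SimulationConfig) -> pd.DataFrame:
    """Marker map: autosomes 1..n_chromosomes, strictly increasing positions
    within each chromosome, true allele frequency uniform in ``maf_range``."""
    config.validate()
    rng = config.rng(_KEY_MARKERS)
    chrom = np.sort(rng.integers(1, config.n_chromosomes + 1, size=config.n_snps))
    pos = np.empty(config.n_snps, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        # distinct sorted positions on a 100 Mb chromosome
        pos[idx] = np.sort(rng.choice(100_000_000, size=idx.size, replace=False)) + 1
    lo, hi = config.maf_range
    freq = rng.uniform(lo, hi, size=config.n_snps)
    return pd.DataFrame({
        "snp_id": [f"snp{i:06d}" for i in range(config.n_snps)],
        "chrom": chrom, "pos": pos, "a1": "A", "a2": "B",
        "true_freq": freq,
    })


def simulate_genotypes(config: SimulationConfig, markers: pd.DataFrame) -> GenotypeMatrix:
    """Hardy-Weinberg doses Binomial(2, p) with independent missingness."""
    config.validate()
    rng = config.rng(_KEY_GENOTYPES)
    p = markers["true_freq"].to_numpy()
    doses = rng.binomial(2, p[None, :], size=(config.n_animals, len(markers))).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(doses.shape) < config.missing_rate
        doses[mask] = np.nan
    animal_ids = np.array([f"an{i:05d}" for i in range(config.n_animals)])
    return GenotypeMatrix(animal_ids, markers.drop(columns=["true_freq"]), doses)


# --- weather -------------------------------------------------------------

_ANNUAL_AMPLITUDE = 9.0   # deg C, seasonal swing
_DIURNAL_AMPLITUDE = 4.0  # deg C, day/night swing
_NOISE_SD = 2.0
_RH_BASE = 75.0
_RH_TEMP_SLOPE = -1.2     # RH drops as temperature rises
_RH_NOISE_SD = 5.0


def _temperature_model(day_of_year, hour, base_temp,
                       annual=_ANNUAL_AMPLITUDE, diurnal=_DIURNAL_AMPLITUDE):
    seasonal = annual * np.cos(2 * np.pi * (np.asarray(day_of_year) - 197) / 365.25)
    daily = diurnal * np.cos(2 * np.pi * (np.asarray(hour) - 15) / 24.0)
    return base_temp + seasonal + daily


def _weekly_thi_sample(base_temp: float, n_weeks: int, rng: np.random.Generator) -> np.ndarray:
    """Weekly-mean THI for random week starts spread over the year."""
    doy0 = rng.uniform(0, 365.25, size=n_weeks)
    hours = np.arange(7 * 24)
    doy = doy0[:, None] + hours[None, :] / 24.0
    temp = _temperature_model(doy % 365.25, hours[None, :] % 24, base_temp)
    temp = temp + rng.normal(0.0, _NOISE_SD, size=temp.shape)
    rh = np.clip(_RH_BASE + _RH_TEMP_SLOPE * (temp - base_temp)
                 + rng.normal(0.0, _RH_NOISE_SD, size=temp.shape), 0.0, 100.0)
    thi = climate.thi_hourly(temp, rh)
    return thi.reshape(n_weeks, 7, 24).mean(axis=(1, 2))


def tune_base_temperature(target_prevalence: float, rng: np.random.Generator,
                          n_weeks: int = 10_000, tol: float = 0.005) -> float:
    """Bisect the annual-mean temperature so that the fraction of weekly THI
    values >= 60 matches ``target_prevalence``."""
    target = min(max(target_prevalence, 0.0), 1.0)
    # monotone in base temperature; use one frozen noise realization
    state = rng.bit_generator.state
    def frac(base):
        r = np.random.Generator(np.random.PCG64())
        r.bit_generator.state = state
        return float(np.mean(_weekly_thi_sample(base, n_weeks, r) >= climate.HS_THI_THRESHOLD))
    lo, hi = -15.0, 45.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        f = frac(mid)
        if abs(f - target) < tol:
            return mid
        if f < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_weather(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Hourly per-station weather: annual + diurnal sinusoids plus noise,
    relative humidity clamped to [0, 100].

    The series starts 70 days before ``date_range`` so that every gestation
    week of an animal born on the first day is covered. The annual mean is
    tuned by bisection so weekly THI exceeds 60 with probability close to
    ``hs_target_prevalence``.
    """
    config.validate()
    rng = config.rng(_KEY_WEATHER)
    base = tune_base_temperature(config.hs_target_prevalence, rng)
    start = pd.Timestamp(config.date_range[0]) - pd.Timedelta(days=70)
    end = pd.Timestamp(config.date_range[1])
    times = pd.date_range(start, end + pd.Timedelta(hours=23), freq="h")
    doy = times.dayofyear.to_numpy() + times.hour.to_numpy() / 24.0
    hour = times.hour.to_numpy()
    out = {}
    for s in range(config.n_stations):
        offset = rng.normal(0.0, 0.5)
        temp = _temperature_model(doy, hour, base + offset)
        temp = temp + rng.normal(0.0, _NOISE_SD, size=temp.shape)
        rh = np.clip(_RH_BASE + _RH_TEMP_SLOPE * (temp - base)
                     + rng.normal(0.0, _RH_NOISE_SD, size=temp.shape), 0.0, 100.0)
        out[f"st{s:03d}"] = pd.DataFrame(
            {"timestamp": times, "temp_c": temp, "rh_pct": rh})
    return out


def simulate_population(config: SimulationConfig):
    """Animal records (herd, birth date, fixed-effect levels) plus herd and
    station coordinates drawn uniformly in the bounding box.

    Returns ``(animals, herd_coords, station_coords)``. With
    ``confound_herd_exposure`` each herd calves within its own 120-day window,
    inducing herd-by-season (and hence herd-by-exposure) confounding.
    """
    config.validate()
    rng = config.rng(_KEY_POPULATION)
    n = config.n_animals
    herd_ids = np.array([f"h{h:03d}" for h in range(config.n_herds)])
    herd = rng.integers(0, config.n_herds, size=n)
    t0 = pd.Timestamp(config.date_range[0])
    t1 = pd.Timestamp(config.date_range[1])
    span = (t1 - t0).days
    if config.confound_herd_exposure:
        herd_anchor = rng.integers(0, max(span - 119, 1), size=config.n_herds)
        day = herd_anchor[herd] + rng.integers(0, min(120, span + 1), size=n)
        day = np.minimum(day, span)
    else:
        day = rng.integers(0, span + 1, size=n)
    birth = t0 + pd.to_timedelta(day, unit="D")

    animals = pd.DataFrame({
        "animal_id": [f"an{i:05d}" for i in range(n)],
        "herd_id": herd_ids[herd],
        "birth_date": birth,
    })
    for k, spec in enumerate(config.fixed_effect_spec):
        animals[f"factor{k + 1}"] = rng.integers(1, spec.n_levels + 1, size=n)

    lat0, lat1, lon0, lon1 = config.bounding_box
    herd_coords = pd.DataFrame({
        "herd_id": herd_ids,
        "lat": rng.uniform(lat0, lat1, size=config.n_herds),
        "lon": rng.uniform(lon0, lon1, size=config.n_herds),
    })
    station_coords = pd.DataFrame({
        "station_id": [f"st{s:03d}" for s in range(config.n_stations)],
        "lat": rng.uniform(lat0, lat1, size=config.n_stations),
        "lon": rng.uniform(lon0, lon1, size=config.n_stations),
    })
    return animals, herd_coords, station_coords


def direct_exposure(config: SimulationConfig,
                    weeks: Sequence[int] = climate.DEFAULT_WEEKS) -> climate.ExposureTable:
    """Shortcut exposure: HS flags Bernoulli(hs_target_prevalence) per
    (animal, week), bypassing the weather path. For fast unit tests."""
    config.validate()
    rng = config.rng(_KEY_WEATHER)
    n = config.n_animals
    rows = []
    for wk in weeks:
        flags = rng.random(n) < config.hs_target_prevalence
        # weekly THI consistent with the flag: 55 below threshold, 65 above
        thi = np.where(flags, 65.0, 55.0)
        for i in range(n):
            rows.append((f"an{i:05d}", wk, thi[i], int(flags[i])))
    return climate.ExposureTable(
        pd.DataFrame(rows, columns=["animal_id", "week", "weekly_thi", "hs_flag"]))


@dataclass
class PhenotypeTruth:
    """Ground-truth effects behind a simulated phenotype vector."""

    b: dict
    g: np.ndarray
    g_hs: np.ndarray  # full-length, zero for unexposed animals
    causal: tuple[CausalMarker, ...]

    def to_dict(self) -> dict:
        return {
            "b": {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in self.b.items()},
            "g": self.g.tolist(),
            "g_hs": self.g_hs.tolist(),
            "causal": [c.__dict__ for c in self.causal],
        }


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    grm: Grm,
    exposure: climate.ExposureTable,
    week: int,
    config: SimulationConfig,
    animals: Optional[pd.DataFrame] = None,
):
    """Draw y = Xb + Zg + W g_hs + e for one gestation week's exposure.

    Returns ``(phenotypes, truth)`` where ``phenotypes`` has columns
    animal_id, y, hs_flag plus any fixed-effect level columns from
    ``animals``. Polygenic effects use the (cached) square root of G; the
    interaction effects use the exposed-subset principal submatrix of G.
    """
    config.validate()
    rng = config.rng(_KEY_PHENOTYPES + 100 * week)
    s2g, s2ghs, s2e = config.variance_components
    ids = genotypes.animal_ids
    n = len(ids)
    exposed = exposure.exposed_mask(ids, week)

    y = np.zeros(n)
    b: dict = {}
    if animals is not None:
        aligned = animals.set_index("animal_id").loc[ids]
        for k, spec in enumerate(config.fixed_effect_spec):
            col = f"factor{k + 1}"
            if col not in aligned.columns:
                continue
            lo, hi = spec.effect_range
            effects = rng.uniform(lo, hi, size=spec.n_levels)
            b[col] = effects
            y += effects[aligned[col].to_numpy() - 1]

    g = np.zeros(n)
    if s2g > 0:
        g = np.sqrt(s2g) * (grm.sqrt_factor() @ rng.standard_normal(n))
        y += g

    g_hs = np.zeros(n)
    n_exp = int(exposed.sum())
    if s2ghs > 0 and n_exp > 0:
        ghs_grm = subset_grm(grm, ids[exposed])
        g_hs[exposed] = np.sqrt(s2ghs) * (
            ghs_grm.sqrt_factor() @ rng.standard_normal(n_exp))
        y += g_hs

    if config.causal_spec:
        doses = mean_impute(genotypes).doses
        p = doses.sum(axis=0) / (2.0 * n)
        for c in config.causal_spec:
            x = doses[:, c.marker_index] - 2.0 * p[c.marker_index]
            y += c.main * x
            y += c.interaction * x * exposed

    if s2e > 0:
        y += np.sqrt(s2e) * rng.standard_normal(n)

    pheno = pd.DataFrame({"animal_id": ids, "y": y, "hs_flag": exposed.astype(int)})
    if animals is not None:
        extra = [c for c in animals.columns if c.startswith("factor")]
        pheno = pheno.merge(animals[["animal_id"] + extra], on="animal_id", how="left")
    truth = PhenotypeTruth(b=b, g=g, g_hs=g_hs, causal=tuple(config.causal_spec))
    return pheno, truth


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    markers: pd.DataFrame
    genotypes: GenotypeMatrix
    animals: pd.DataFrame
    herd_coords: pd.DataFrame
    station_coords: pd.DataFrame
    weather: Optional[dict]
    exposure: climate.ExposureTable
    grm: Grm
    phenotypes: pd.DataFrame
    truth: PhenotypeTruth
    week: int


def simulate_dataset(config: SimulationConfig, week: int = 1,
                     exposure_mode: str = "weather") -> SimulatedDataset:
    """Run the whole generative chain for one phenotype week.

    ``exposure_mode='weather'`` pushes simulated station weather through the
    climate module (station assignment, daily/weekly THI); ``'direct'``
    assigns Bernoulli HS flags, skipping the weather path.
    """
    config.validate()
    markers = simulate_markers(config)
    genotypes = simulate_genotypes(config, markers)
    animals, herd_coords, station_coords = simulate_population(config)
    weather = None
    if exposure_mode == "weather":
        weather = simulate_weather(config)
        daily = {sid: climate.daily_thi_series(frame) for sid, frame in weather.items()}
        assignment = climate.assign_stations(herd_coords, station_coords)
        exposure = climate.build_exposure(animals, daily, assignment)
    elif exposure_mode == "direct":
        exposure = direct_exposure(config)
    else:
        raise ConfigurationError(f"unknown exposure_mode {exposure_mode!r}")
    complete = mean_impute(genotypes)
    grm = vanraden_grm(complete)
    phenotypes, truth = simulate_phenotypes(
        genotypes, grm, exposure, week, config, animals=animals)
    return SimulatedDataset(config, markers, genotypes, animals, herd_coords,
                            station_coords, weather, exposure, grm,
                            phenotypes, truth, week)
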