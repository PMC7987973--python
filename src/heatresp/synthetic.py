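"""Synthetic weather / soil-moisture / respiration generator.

Produces multi-year hourly series with known statistical structure so every
pipeline stage — climatology fitting, heat and moisture labelling,
conditional exceedance probabilities — can be tested end-to-end, including
recovery of generator ground truth:

* air temperature: seasonal + diurnal harmonics, AR(1) noise, and
  Poisson-arriving multi-hour heat episodes of geometric duration with an
  additive intensity boost;
* soil moisture: Poisson precipitation pulses with exponential drydown
  toward a floor, a saturation ceiling, and an optional nocturnal dew bump;
* respiration: a Q10 temperature response on lagged (soil-buffered) air
  temperature, multiplied by a piecewise-linear moisture scaling that
  saturates at field capacity, plus Gaussian observation noise and random
  missingness (~7% by default, matching typical instrument outage rates).

One master seed spawns named substreams (temperature noise, heat episodes,
precipitation, flux noise, missingness), so each component is independently
reproducible.

Default parameters sketch a semi-arid Mediterranean site: annual mean near
17 °C, soil moisture confined to 0.18–0.37 m3/m3 with saturation at
0.33 m3/m3, and a mean respiration rate near 1.1 μmol CO2 m-2 s-1.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .climatology import HOURS_PER_YEAR
from .ingest import FluxSeries, MoistureSeries, TemperatureSeries

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_temperature",
    "generate_moisture",
    "generate_flux",
    "generate_site",
    "moisture_scaling",
    "temperature_mean",
    "ground_truth_exceedance",
    "ground_truth_all_conditions",
]

_STREAMS = {"temp_noise": 0, "episodes": 1, "precip": 2, "flux_noise": 3, "missing": 4}


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterisation of the generator. All rates are per hour unless
    noted; temperatures in °C, moisture in m3/m3, fluxes in μmol CO2 m-2 s-1."""

    seed: int = 0
    climatology_years: int = 30  # length of the station record before the study period
    study_hours: int = 8760  # study period appended after the climatology record

    # temperature
    t_mean: float = 17.0
    t_seasonal_amp: float = 6.0  # annual harmonic, peak ~20 July
    t_diurnal_amp: float = 5.0  # daily harmonic, peak 15:00 local
    t_ar1_coef: float = 0.8
    t_ar1_sd: float = 1.5  # innovation standard deviation
    heat_episode_rate: float = 12.0  # episodes per year (Poisson arrivals)
    heat_episode_mean_hours: float = 48.0  # geometric duration
    heat_episode_boost: float = 6.0  # additive °C during an episode

    # soil moisture
    precip_rate: float = 0.008  # pulse arrivals per hour
    sm_jump: float = 0.08  # m3/m3 added per pulse
    sm_tau_hours: float = 120.0  # exponential drydown e-folding time
    sm_floor: float = 0.18
    sm_ceiling: float = 0.37
    dew_amp: float = 0.005  # nocturnal dew bump amplitude (0 disables)
    sm_init: float | None = None  # starting water content; default: stationary mean

    # respiration
    rs_ref: float = 1.45  # rate at t_ref under saturated moisture
    t_ref: float = 17.0
    q10: float = 2.0
    sm_sat: float = 0.33  # scaling reaches 1 here and stays flat above
    g_min: float = 0.4  # scaling at/below the moisture floor
    t_lag_hours: int = 6  # trailing moving-average window (soil buffering)
    noise_sd: float = 0.15
    missing_frac: float = 0.07
    subhourly_per_hour: int = 1  # >1 emits that many sub-hourly records per hour

    def __post_init__(self) -> None:
        positive = ("heat_episode_mean_hours", "sm_tau_hours", "q10")
        nonneg = (
            "t_ar1_sd",
            "heat_episode_rate",
            "heat_episode_boost",
            "precip_rate",
            "sm_jump",
            "dew_amp",
            "noise_sd",
            "t_seasonal_amp",
            "t_diurnal_amp",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.t_ar1_coef < 1.0:
            raise ValueError("t_ar1_coef must be in [0, 1)")
        if not self.sm_floor < self.sm_ceiling:
            raise ValueError("sm_floor must be below sm_ceiling")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must be in [0, 1)")
        if self.subhourly_per_hour < 1:
            raise ValueError("subhourly_per_hour must be >= 1")

    @property
    def total_hours(self) -> int:
        return self.climatology_years * HOURS_PER_YEAR + self.study_hours

    def rng(self, stream: str) -> np.random.Generator:
        """Named, independently reproducible substream of the master seed."""
        key = _STREAMS[stream]
        return np.random.default_rng(np.random.SeedSequence(entropy=self.seed, spawn_key=(key,)))


def temperature_mean(cfg: SynthConfig, index: pd.DatetimeIndex) -> np.ndarray:
    """Deterministic (seasonal + diurnal) part of the temperature model;
    the analytic expectation of the series outside heat episodes."""
    doy = index.dayofyear.to_numpy() + index.hour.to_numpy() / 24.0
    seasonal = cfg.t_seasonal_amp * np.cos(2 * np.pi * (doy - 201.0) / 365.25)
    diurnal = cfg.t_diurnal_amp * np.cos(2 * np.pi * (index.hour.to_numpy() - 15.0) / 24.0)
    return cfg.t_mean + seasonal + diurnal


def generate_temperature(
    cfg: SynthConfig, n_hours: int | None = None, start: str = "1980-01-01"
) -> TemperatureSeries:
    """Hourly air temperature: harmonic mean function + stationary AR(1)
    noise + additive boosts over Poisson-arriving heat episodes."""
    n = cfg.total_hours if n_hours is None else int(n_hours)
    index = pd.date_range(start, periods=n, freq="h")
    tair = temperature_mean(cfg, index).astype(float)

    rng = cfg.rng("temp_noise")
    innov = rng.normal(0.0, cfg.t_ar1_sd, n)
    rho = cfg.t_ar1_coef
    stat_sd = cfg.t_ar1_sd / np.sqrt(1.0 - rho**2)
    x0 = rng.normal(0.0, stat_sd)
    noise, _ = lfilter([1.0], [1.0, -rho], innov, zi=np.array([rho * x0]))
    tair += noise

    rng_ep = cfg.rng("episodes")
    n_episodes = rng_ep.poisson(cfg.heat_episode_rate * n / HOURS_PER_YEAR)
    if n_episodes and cfg.heat_episode_boost > 0:
        starts = rng_ep.integers(0, n, n_episodes)
        durations = rng_ep.geometric(1.0 / cfg.heat_episode_mean_hours, n_episodes)
        for s, d in zip(starts, durations):
            tair[s : s + d] += cfg.heat_episode_boost

    return TemperatureSeries(data=pd.DataFrame({"tair": tair}, index=index.rename("timestamp")))


def generate_moisture(cfg: SynthConfig, temp: TemperatureSeries) -> MoistureSeries:
    """Hourly volumetric water content on the same timestamps as ``temp``:
    exponential drydown toward the floor, instantaneous pulses at Poisson
    precipitation arrivals clipped at the ceiling, plus an optional
    pre-dawn dew bump."""
    index = temp.data.index
    n = len(index)
    rng = cfg.rng("precip")
    counts = rng.poisson(cfg.precip_rate, n)
    xmax = cfg.sm_ceiling - cfg.sm_floor
    decay1 = np.exp(-1.0 / cfg.sm_tau_hours)

    x = np.empty(n)
    if cfg.sm_init is not None:
        x_prev = float(np.clip(cfg.sm_init - cfg.sm_floor, 0.0, xmax))
    else:
        # start at the unclipped stationary mean of the pulse-decay process
        x_prev = min(xmax, cfg.precip_rate * cfg.sm_jump * cfg.sm_tau_hours)
    t_prev = -1
    for t in np.flatnonzero(counts):
        gap = t - t_prev - 1
        if gap > 0:
            x[t_prev + 1 : t] = x_prev * np.exp(-np.arange(1, gap + 1) / cfg.sm_tau_hours)
            x_at_decay = x[t - 1] * decay1
        else:
            x_at_decay = x_prev * decay1
        x[t] = min(xmax, x_at_decay + counts[t] * cfg.sm_jump)
        x_prev = x[t]
        t_prev = t
    if t_prev < n - 1:
        gap = n - 1 - t_prev
        x[t_prev + 1 :] = x_prev * np.exp(-np.arange(1, gap + 1) / cfg.sm_tau_hours)

    sm = cfg.sm_floor + x
    if cfg.dew_amp > 0:
        hour = index.hour.to_numpy()
        dew_shape = np.maximum(0.0, np.cos(2 * np.pi * (hour - 4.0) / 24.0))
        sm = sm + cfg.dew_amp * dew_shape
    sm = np.clip(sm, cfg.sm_floor, cfg.sm_ceiling)
    return MoistureSeries(data=pd.DataFrame({"sm": sm}, index=index))


def moisture_scaling(cfg: SynthConfig, sm: np.ndarray) -> np.ndarray:
    """Piecewise-linear moisture limitation g(SM) in [g_min, 1]: rises from
    g_min at the moisture floor to 1 at saturation, flat above (respiration
    unresponsive to further wetting)."""
    sm = np.asarray(sm, dtype=float)
    if cfg.sm_sat <= cfg.sm_floor:
        return np.ones_like(sm)
    frac = (sm - cfg.sm_floor) / (cfg.sm_sat - cfg.sm_floor)
    return np.clip(cfg.g_min + (1.0 - cfg.g_min) * frac, cfg.g_min, 1.0)


def lagged_temperature(cfg: SynthConfig, temp: TemperatureSeries) -> np.ndarray:
    """Trailing moving average of air temperature over ``t_lag_hours`` —
    a simple stand-in for the thermal buffering of the soil column."""
    if cfg.t_lag_hours <= 1:
        return temp.data["tair"].to_numpy()
    return (
        temp.data["tair"].rolling(cfg.t_lag_hours, min_periods=1).mean().to_numpy()
    )


def generate_flux(
    cfg: SynthConfig, temp: TemperatureSeries, sm: MoistureSeries | None = None
) -> FluxSeries:
    """Respiration record driven by lagged temperature and moisture:

        Rs(t) = rs_ref * q10**((T_lag(t) - t_ref)/10) * g(SM(t)) + noise

    With ``subhourly_per_hour`` > 1, that many sub-hourly records are emitted
    per hour (shared hourly drivers, independent noise). A ``missing_frac``
    share of records is removed uniformly at random.
    """
    index = temp.data.index
    if sm is not None and not index.equals(sm.data.index):
        raise ValueError("temperature and moisture series are not aligned")
    tl = lagged_temperature(cfg, temp)
    g = moisture_scaling(cfg, sm.data["sm"].to_numpy()) if sm is not None else 1.0
    mu = cfg.rs_ref * cfg.q10 ** ((tl - cfg.t_ref) / 10.0) * g

    k = cfg.subhourly_per_hour
    if k > 1:
        minutes = np.arange(k) * (60 // k)
        stamps = (
            index.to_numpy()[:, None] + minutes[None, :].astype("timedelta64[m]")
        ).ravel()
        full_index = pd.DatetimeIndex(stamps, name="timestamp")
        mu = np.repeat(mu, k)
    else:
        full_index = index

    rng = cfg.rng("flux_noise")
    rs = mu + rng.normal(0.0, cfg.noise_sd, len(mu))

    if cfg.missing_frac > 0:
        keep = cfg.rng("missing").random(len(rs)) >= cfg.missing_frac
        rs = rs[keep]
        full_index = full_index[keep]
    return FluxSeries(data=pd.DataFrame({"rs": rs}, index=full_index))


def generate_site(
    cfg: SynthConfig, start: str = "1980-01-01"
) -> tuple[TemperatureSeries, TemperatureSeries, MoistureSeries, FluxSeries]:
    """One synthetic site: the full station temperature record (climatology
    years + study period) and study-period temperature, moisture and flux.

    Returns ``(temp_record, temp_study, sm_study, flux_study)``; the study
    period is the final ``study_hours`` of the station record, so a
    climatology fitted on the full record covers it.
    """
    temp_record = generate_temperature(cfg, start=start)
    study = temp_record.data.iloc[-cfg.study_hours :]
    temp_study = TemperatureSeries(data=study)
    sm_study = generate_moisture(cfg, temp_study)
    flux_study = generate_flux(cfg, temp_study, sm_study)
    return temp_record, temp_study, sm_study, flux_study


@dataclass
class GroundTruth:
    """Monte-Carlo estimate of a generator exceedance probability."""

    condition: str
    p: float
    se: float  # binomial standard error of the estimate
    n: int  # conditioning subsample size


def _oracle_frame(cfg: SynthConfig, n_hours: int, seed: int) -> pd.DataFrame:
    """Long clean realisation of the generator (no missingness, hourly) with
    heat / moisture condition labels computed directly with numpy — kept
    independent of the analysis modules so it can serve as their oracle."""
    cfg_o = dataclasses.replace(
        cfg,
        seed=seed,
        climatology_years=0,
        study_hours=int(n_hours),
        missing_frac=0.0,
        subhourly_per_hour=1,
    )
    temp = generate_temperature(cfg_o)
    sm = generate_moisture(cfg_o, temp)
    flux = generate_flux(cfg_o, temp, sm)
    df = pd.DataFrame(
        {
            "rs": flux.data["rs"].to_numpy(),
            "tair": temp.data["tair"].to_numpy(),
            "sm": sm.data["sm"].to_numpy(),
        },
        index=temp.data.index,
    )
    month = df.index.month.to_numpy()
    hour = df.index.hour.to_numpy()
    thr = np.full((13, 24), np.nan)
    for m in range(1, 13):
        in_m = month == m
        for h in range(24):
            cell = df["tair"].to_numpy()[in_m & (hour == h)]
            if len(cell):
                thr[m, h] = np.quantile(cell, 0.85, method="linear")
    df["hot"] = df["tair"].to_numpy() > thr[month, hour]
    dry_thr, wet_thr = np.quantile(df["sm"].to_numpy(), [0.30, 0.70], method="linear")
    df["dry"] = df["sm"].to_numpy() < dry_thr
    df["wet"] = df["sm"].to_numpy() > wet_thr
    return df


def ground_truth_all_conditions(
    cfg: SynthConfig, n_hours: int = 1_000_000, seed: int | None = None
) -> dict[str, GroundTruth]:
    """Monte-Carlo P(Rs > mean Rs | condition) for all six heat x moisture
    conditions from one long generator run (default 10^6 hours)."""
    seed = cfg.seed + 1_000_003 if seed is None else seed
    df = _oracle_frame(cfg, n_hours, seed)
    r_star = df["rs"].mean()
    hot = df["hot"].to_numpy()
    masks = {
        "HW": hot,
        "NHW": ~hot,
        "dHW": hot & df["dry"].to_numpy(),
        "dNHW": ~hot & df["dry"].to_numpy(),
        "wHW": hot & df["wet"].to_numpy(),
        "wNHW": ~hot & df["wet"].to_numpy(),
    }
    out = {}
    rs = df["rs"].to_numpy()
    for cond, mask in masks.items():
        m = int(mask.sum())
        p = float(np.mean(rs[mask] > r_star)) if m else float("nan")
        se = float(np.sqrt(p * (1 - p) / m)) if m else float("nan")
        out[cond] = GroundTruth(condition=cond, p=p, se=se, n=m)
    return out


def ground_truth_exceedance(
    cfg: SynthConfig,
    condition: str,
    n_hours: int = 1_000_000,
    seed: int | None = None,
) -> GroundTruth:
    """Monte-Carlo estimate of one conditional exceedance probability under
    the generator, with its binomial standard error."""
    return ground_truth_all_conditions(cfg, n_hours=n_hours, seed=seed)[condition]
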