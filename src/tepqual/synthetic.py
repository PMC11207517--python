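"""Synthetic greenhouse climate and fruit-quality generators.

The generators emulate the statistical structure the analysis assumes —
solar-greenhouse diurnal/seasonal temperature and radiation envelopes, and
stage-wise quality trajectories driven by the TEP-response models plus
replicate-scale Gaussian noise — so the full pipeline can be exercised and
parameter recovery quantified without any external data.

All generators are pure functions of (scenario, seed).  A single scenario
seed fans out to per-component streams through ``numpy``'s
``SeedSequence.spawn``, so adding a generator never perturbs existing
streams.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .exceptions import FittingError, InputError
from .models import _logistic, fit_curve
from .quality import ColorMeasurement, QualityRecord, RipeningStage, records_to_frame

#: Replicate noise scales per index, comparable to the calibration tables'
#: standard deviations (SSC ~0.15 g/100 g, OAC ~0.03 g/100 g, ...).
DEFAULT_NOISE_SD = {
    "ssc": 0.15,
    "oac": 0.03,
    "ssc_oac": 0.25,
    "vc": 1.3,
    "lycopene": 1.0,
    "firmness": 0.9,
    "l_star": 1.9,
    "a_star": 2.2,
    "b_star": 2.1,
}


@dataclass(frozen=True)
class ClimateScenario:
    """Sinusoid-plus-noise solar-greenhouse climate scenario.

    The defaults mirror the ripening-optimum magnitudes of the study
    greenhouse: night minimum ~14.3 degC, day maximum ~26.3 degC, a few
    degrees of seasonal modulation, ~8.5 MJ m-2 d-1 of radiation over a
    ~10 h daylight window.
    """

    start: date = date(2021, 8, 13)
    end: date = date(2021, 12, 10)
    night_min: float = 14.3
    day_max: float = 26.3
    seasonal_amplitude: float = 4.0
    daily_solar_mj: float = 8.5
    sunshine_hours: float = 10.0
    temp_noise_sd: float = 0.5
    par_profile: str = "half_sine"  # or "flat"
    seed: int = 0


@dataclass(frozen=True)
class QualityScenario:
    """Ground-truth response models and noise scales for quality generation.

    Default parameters are the calibration-data fits: SSC and the
    sugar-acid ratio follow logarithmic TEP responses, organic acid a
    decreasing linear one, and comprehensive quality a rising logistic.
    """

    ssc_log: tuple = (3.010, -13.917)
    oac_linear: tuple = (-0.00547, 2.071)
    ssc_oac_log: tuple = (15.001, -78.942)
    comprehensive_logistic: tuple = (1.2, 0.09, 272.0)
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    tep_grid: tuple = tuple(np.round(np.linspace(232.0, 290.0, 21), 2))
    seed: int = 0


def generate_climate(scenario: ClimateScenario) -> pd.DataFrame:
    """Hourly climate frame (timestamp, temp_c, par) for a scenario.

    Temperature is a diurnal sinusoid (minimum ~05:00, maximum ~17:00)
    around a seasonally modulated midpoint, plus Gaussian noise.  PAR is
    positive only in a daylight window centred on noon and is scaled so the
    hourly series integrates exactly to the scenario's daily solar total.
    """
    if scenario.end < scenario.start:
        raise InputError("scenario end precedes start")
    n_days = (scenario.end - scenario.start).days + 1
    ss = np.random.SeedSequence(scenario.seed)
    temp_rng = np.random.default_rng(ss.spawn(2)[0])

    hours = np.arange(24)
    mid = 0.5 * (scenario.night_min + scenario.day_max)
    amp = 0.5 * (scenario.day_max - scenario.night_min)
    diurnal = amp * np.sin(2 * np.pi * (hours - 11.0) / 24.0)

    window = scenario.sunshine_hours
    centre = 12.0
    rel = hours + 0.5 - (centre - window / 2.0)
    inside = (rel > 0) & (rel < window)
    if scenario.par_profile == "half_sine":
        shape = np.where(inside, np.sin(np.pi * np.clip(rel, 0, window) / window), 0.0)
    elif scenario.par_profile == "flat":
        shape = inside.astype(float)
    else:
        raise InputError(f"unknown par_profile {scenario.par_profile!r}")
    # scale so sum(par) * 3600e-6 MJ == daily_solar_mj exactly
    par_day = shape * scenario.daily_solar_mj / (shape.sum() * 3600e-6)

    frames = []
    for k in range(n_days):
        day = scenario.start + timedelta(days=k)
        doy = day.timetuple().tm_yday
        seasonal = scenario.seasonal_amplitude * np.sin(2 * np.pi * (doy - 105) / 365.0)
        temp = mid + seasonal + diurnal
        if scenario.temp_noise_sd > 0:
            temp = temp + temp_rng.normal(0.0, scenario.temp_noise_sd, size=24)
        frames.append(
            pd.DataFrame(
                {
                    "timestamp": pd.date_range(pd.Timestamp(day), periods=24, freq="h"),
                    "temp_c": temp,
                    "par": par_day,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


_STAGE_CYCLE = (RipeningStage.GM, RipeningStage.V1, RipeningStage.V2,
                RipeningStage.V3, RipeningStage.RR)


def generate_quality(scenario: QualityScenario, tep_grid=None) -> list[QualityRecord]:
    """Quality records at the TEP grid from the scenario's ground-truth models.

    SSC, OAC and SSC/OAC come from their own response models plus Gaussian
    noise (so each model's parameters are recoverable); the remaining
    indices follow monotone trends whose correlation signs against TEP
    match the calibration data (CI, SSC, SSC/OAC, lycopene, Vc rising;
    OAC and firmness falling).
    """
    grid = np.asarray(scenario.tep_grid if tep_grid is None else tep_grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise InputError("tep_grid must be positive and strictly increasing")
    ss = np.random.SeedSequence(scenario.seed)
    rng = np.random.default_rng(ss.spawn(3)[1])
    sd = {**DEFAULT_NOISE_SD, **scenario.noise_sd}

    a, b = scenario.ssc_log
    ssc = a * np.log(grid) + b
    a, b = scenario.oac_linear
    oac = a * grid + b
    a, b = scenario.ssc_oac_log
    ratio = a * np.log(grid) + b
    frac = (grid - grid[0]) / (grid[-1] - grid[0])
    vc = 15.0 + 18.0 * frac
    lyc = 4.0 + 19.0 * frac
    firm = 15.5 - 9.0 * frac
    a_star = -7.0 + 25.0 * frac
    b_star = 23.5 - 9.5 * frac
    l_star = 48.5 - 9.0 * frac

    def noisy(mean, key, floor=None):
        values = mean + rng.normal(0.0, sd[key], size=len(grid)) if sd[key] > 0 else mean.copy()
        if floor is not None:
            values = np.maximum(values, floor)
        return values

    ssc, oac, ratio = noisy(ssc, "ssc", 0.01), noisy(oac, "oac", 0.01), noisy(ratio, "ssc_oac", 0.01)
    vc, lyc, firm = noisy(vc, "vc", 0.1), noisy(lyc, "lycopene", 0.1), noisy(firm, "firmness", 0.1)
    a_star, b_star = noisy(a_star, "a_star"), noisy(b_star, "b_star", 0.5)
    l_star = noisy(l_star, "l_star", 1.0)

    records = []
    n = len(grid)
    for i in range(n):
        stage = _STAGE_CYCLE[min(i * len(_STAGE_CYCLE) // n, len(_STAGE_CYCLE) - 1)]
        records.append(
            QualityRecord(
                treatment=f"S{i + 1}",
                stage=stage,
                tep=float(grid[i]),
                color=ColorMeasurement(l_star[i], a_star[i], b_star[i]),
                ssc=float(ssc[i]),
                oac=float(oac[i]),
                ssc_oac=float(ratio[i]),
                vc=float(vc[i]),
                lycopene=float(lyc[i]),
                firmness=float(firm[i]),
            )
        )
    return records


def generate_comprehensive(scenario: QualityScenario, tep_grid=None) -> np.ndarray:
    """Noisy comprehensive-quality scores from the scenario's logistic truth."""
    grid = np.asarray(scenario.tep_grid if tep_grid is None else tep_grid, dtype=float)
    ss = np.random.SeedSequence(scenario.seed)
    rng = np.random.default_rng(ss.spawn(3)[2])
    k, r, x0 = scenario.comprehensive_logistic
    mean = _logistic(grid, k, r, x0)
    sd = scenario.noise_sd.get("comprehensive", 0.05)
    return mean + rng.normal(0.0, sd, size=len(grid)) if sd > 0 else mean


_TRUTH_MODELS = (
    ("ssc", "log", "ssc_log"),
    ("oac", "linear", "oac_linear"),
    ("ssc_oac", "log", "ssc_oac_log"),
    ("comprehensive", "logistic", "comprehensive_logistic"),
)


def recovery_experiment(truth: QualityScenario, n_replicates: int = 200, seed: int = 0) -> pd.DataFrame:
    """Monte-Carlo bias/RMSE of parameter estimates under a known truth.

    Each replicate generates a quality data set from ``truth`` (with a
    replicate-specific child seed), refits the four response models, and
    records the estimates.  Returns one row per (model, parameter) with the
    truth, mean estimate, bias and RMSE; fitting failures are counted in
    ``result.attrs["n_failures"]``, not fatal.
    """
    if n_replicates < 1:
        raise InputError("n_replicates must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    estimates = {key: [] for _, _, key in _TRUTH_MODELS}
    n_failures = 0
    for rep_seed in child_seeds:
        scen = dataclasses.replace(truth, seed=int(rep_seed))
        records = generate_quality(scen)
        frame = records_to_frame(records)
        tep = frame["tep"].to_numpy()
        comp = generate_comprehensive(scen)
        targets = {
            "ssc_log": frame["ssc"], "oac_linear": frame["oac"],
            "ssc_oac_log": frame["ssc_oac"], "comprehensive_logistic": comp,
        }
        for _, form, key in _TRUTH_MODELS:
            try:
                fitted = fit_curve(form, tep, np.asarray(targets[key], dtype=float),
                                   random_state=int(rep_seed))
                estimates[key].append(fitted.params)
            except FittingError:
                n_failures += 1

    rows = []
    for index, form, key in _TRUTH_MODELS:
        true_params = np.asarray(getattr(truth, key), dtype=float)
        est = np.asarray(estimates[key], dtype=float)
        names = ("a", "b") if form in ("log", "linear") else ("K", "r", "X0")
        for j, name in enumerate(names):
            mean_est = est[:, j].mean() if len(est) else np.nan
            rows.append(
                {
                    "index": index,
                    "form": form,
                    "param": name,
                    "truth": true_params[j],
                    "mean_estimate": mean_est,
                    "bias": mean_est - true_params[j],
                    "rmse": float(np.sqrt(np.mean((est[:, j] - true_params[j]) ** 2)))
                    if len(est) else np.nan,
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_failures"] = n_failures
    out.attrs["n_replicates"] = n_replicates
    return out
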