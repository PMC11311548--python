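"""Oxidation kinetics: per-temperature rate fits, Arrhenius temperature
dependence, and shelf-life prediction.

Zero-order model:   y(t) = y0 + k * t
First-order model:  ln y(t) = ln y0 + k * t
Arrhenius law:      ln k(T) = ln k0 - Ea / (R * T)
Shelf life (first): SL = [ln(endpoint) - ln(y0)] / k(T)
Shelf life (zero):  SL = (endpoint - y0) / k(T)
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import R_GAS

ZERO = "zero"
FIRST = "first"

KELVIN_OFFSET = 273.15


def celsius_to_kelvin(temperature_C: float) -> float:
    return temperature_C + KELVIN_OFFSET


@dataclass
class OxidationSeries:
    """Replicate-resolved measurements of one response over storage time
    at a single temperature."""

    response: str
    process: str
    temperature_K: float
    times_days: np.ndarray
    values: np.ndarray
    replicate: np.ndarray

    def __post_init__(self) -> None:
        self.times_days = np.asarray(self.times_days, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.replicate = np.asarray(self.replicate, dtype=int)
        if not (self.times_days.shape == self.values.shape == self.replicate.shape):
            raise ValueError("times_days, values and replicate must have equal length")
        if self.temperature_K <= 0:
            raise ValueError("temperature_K must be positive")

    @property
    def temperature_C(self) -> float:
        return self.temperature_K - KELVIN_OFFSET

    def n_distinct_times(self) -> int:
        return np.unique(self.times_days).size

    def subset_replicate(self, replicate_id: int) -> "OxidationSeries":
        mask = self.replicate == replicate_id
        return OxidationSeries(
            response=self.response,
            process=self.process,
            temperature_K=self.temperature_K,
            times_days=self.times_days[mask],
            values=self.values[mask],
            replicate=self.replicate[mask],
        )


@dataclass
class KineticFit:
    order: str
    rate_k: float
    intercept: float  # y0 for zero order, ln(y0) for first order
    r_squared: float
    n_points: int
    temperature_K: float
    zero_variance: bool = False

    @property
    def y0(self) -> float:
        return self.intercept if self.order == ZERO else math.exp(self.intercept)


@dataclass
class ArrheniusModel:
    Ea: float
    k0_pre_exponential: float
    r_squared: float
    order: str
    per_temperature_k: dict[float, float] = field(default_factory=dict)
    R_gas: float = R_GAS

    def rate_at(self, temperature_K: float) -> float:
        return self.k0_pre_exponential * math.exp(-self.Ea / (self.R_gas * temperature_K))


@dataclass
class ShelfLifePrediction:
    temperature_K: float
    endpoint_value: float
    initial_value: float
    shelf_life_days: float
    order_used: str
    infinite: bool = False


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """Least-squares line y = slope*x + intercept.

    Returns (slope, intercept, r_squared, zero_variance).  R^2 is the
    squared Pearson correlation between fitted and observed values; a
    response with zero variance is reported as R^2 = 0 with a flag.
    """
    if np.unique(x).size < 2:
        raise ValueError("all time points identical; line fit is singular")
    slope, intercept = np.polyfit(x, y, 1)
    if np.ptp(y) == 0:
        return float(slope), float(intercept), 0.0, True
    fitted = slope * x + intercept
    if np.ptp(fitted) == 0:
        return float(slope), float(intercept), 0.0, True
    r = np.corrcoef(fitted, y)[0, 1]
    return float(slope), float(intercept), float(r * r), False


def fit_zero_order(series: OxidationSeries) -> KineticFit:
    """OLS of the raw response on time; slope is the zero-order rate."""
    if series.n_distinct_times() < 3:
        raise ValueError("zero-order fit requires >= 3 distinct timepoints")
    slope, intercept, r2, flat = _ols_line(series.times_days, series.values)
    return KineticFit(
        order=ZERO,
        rate_k=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=series.values.size,
        temperature_K=series.temperature_K,
        zero_variance=flat,
    )


def fit_first_order(series: OxidationSeries) -> KineticFit:
    """OLS of ln(response) on time; slope is the first-order rate (day^-1)."""
    if series.n_distinct_times() < 3:
        raise ValueError("first-order fit requires >= 3 distinct timepoints")
    bad = np.flatnonzero(series.values <= 0)
    if bad.size:
        i = int(bad[0])
        raise ValueError(
            f"first-order fit requires positive values; value {float(series.values[i]):g} "
            f"at day {float(series.times_days[i]):g} (replicate {series.replicate[i]}) is not"
        )
    slope, intercept, r2, flat = _ols_line(series.times_days, np.log(series.values))
    return KineticFit(
        order=FIRST,
        rate_k=slope,
        intercept=intercept,
        r_squared=r2,
        n_points=series.values.size,
        temperature_K=series.temperature_K,
        zero_variance=flat,
    )


def select_order(zero_fit: KineticFit, first_fit: KineticFit) -> str:
    """Pick the order with higher R^2; ties go to first order."""
    if zero_fit.order != ZERO or first_fit.order != FIRST:
        raise ValueError("expected a zero-order and a first-order fit, in that order")
    return ZERO if zero_fit.r_squared > first_fit.r_squared else FIRST


def fit_arrhenius(fits: Sequence[KineticFit]) -> ArrheniusModel:
    """OLS of ln(k) on 1/T: Ea = -slope * R, k0 = exp(intercept)."""
    if len(fits) < 2:
        raise ValueError("Arrhenius fit requires rate constants at >= 2 temperatures")
    orders = {f.order for f in fits}
    if len(orders) != 1:
        raise ValueError("all kinetic fits must share the same order")
    temps = np.array([f.temperature_K for f in fits], dtype=float)
    if np.unique(temps).size != temps.size:
        raise ValueError("temperatures must be distinct")
    rates = np.array([f.rate_k for f in fits], dtype=float)
    if np.any(rates <= 0):
        raise ValueError("all rate constants must be positive for the Arrhenius fit")
    x = 1.0 / temps
    y = np.log(rates)
    slope, intercept, r2, _ = _ols_line(x, y)
    return ArrheniusModel(
        Ea=-slope * R_GAS,
        k0_pre_exponential=math.exp(intercept),
        r_squared=r2,
        order=orders.pop(),
        per_temperature_k={float(t): float(k) for t, k in zip(temps, rates)},
    )


def predict_shelf_life(
    model: ArrheniusModel,
    y0: float,
    endpoint: float,
    temperature_K: float,
    order_used: str | None = None,
) -> ShelfLifePrediction:
    """Days for the response to move from ``y0`` to ``endpoint`` at the
    Arrhenius-interpolated rate k(T)."""
    if y0 <= 0 or endpoint <= 0:
        raise ValueError("y0 and endpoint must be positive")
    order = order_used or model.order
    if order not in (ZERO, FIRST):
        raise ValueError(f"unknown kinetic order {order!r}")
    k = model.rate_at(temperature_K)
    if k == 0:
        return ShelfLifePrediction(
            temperature_K=temperature_K,
            endpoint_value=endpoint,
            initial_value=y0,
            shelf_life_days=math.inf,
            order_used=order,
            infinite=True,
        )
    if order == FIRST:
        sl = (math.log(endpoint) - math.log(y0)) / k
    else:
        sl = (endpoint - y0) / k
    if endpoint < y0:
        warnings.warn(
            f"endpoint {endpoint} below initial value {y0}: negative shelf life returned",
            stacklevel=2,
        )
    return ShelfLifePrediction(
        temperature_K=temperature_K,
        endpoint_value=endpoint,
        initial_value=y0,
        shelf_life_days=sl,
        order_used=order,
    )


def _fit_both(series: OxidationSeries) -> tuple[KineticFit, KineticFit]:
    return fit_zero_order(series), fit_first_order(series)


def _group_order(series_by_temp: Mapping[float, OxidationSeries]) -> str:
    """One kinetic order per process/response group: the order with the
    higher mean R^2 across temperatures (ties to first)."""
    zero_r2, first_r2 = [], []
    for s in series_by_temp.values():
        zf, ff = _fit_both(s)
        zero_r2.append(zf.r_squared)
        first_r2.append(ff.r_squared)
    return ZERO if float(np.mean(zero_r2)) > float(np.mean(first_r2)) else FIRST


def _shelf_lives_for_group(
    series_by_temp: Mapping[float, OxidationSeries],
    order: str,
    endpoint: float,
) -> dict[float, tuple[KineticFit, float]]:
    """Per-temperature (fit, shelf life) using a shared Arrhenius model."""
    fitter = fit_zero_order if order == ZERO else fit_first_order
    fits = {T: fitter(s) for T, s in series_by_temp.items()}
    model = fit_arrhenius(list(fits.values()))
    out: dict[float, tuple[KineticFit, float]] = {}
    for T, f in fits.items():
        pred = predict_shelf_life(model, f.y0, endpoint, T, order)
        out[T] = (f, pred.shelf_life_days)
    return out


def shelf_life_table(
    series: Iterable[OxidationSeries],
    endpoints: Mapping[str, float],
) -> pd.DataFrame:
    """Shelf-life summary: one row per process x response x temperature.

    Replicates are pooled into one regression per temperature; the SD
    column comes from refitting each replicate separately through the
    whole Arrhenius pipeline.
    """
    groups: dict[tuple[str, str], dict[float, OxidationSeries]] = {}
    for s in series:
        groups.setdefault((s.process, s.response), {})[float(s.temperature_K)] = s

    rows = []
    for (process, response), by_temp in sorted(groups.items()):
        if response not in endpoints:
            raise KeyError(f"no endpoint configured for response {response!r}")
        endpoint = float(endpoints[response])
        order = _group_order(by_temp)
        pooled = _shelf_lives_for_group(by_temp, order, endpoint)

        replicate_ids = sorted(
            set(np.concatenate([s.replicate for s in by_temp.values()]).tolist())
        )
        per_rep: dict[float, list[float]] = {T: [] for T in by_temp}
        if len(replicate_ids) > 1:
            for rep in replicate_ids:
                sub = {T: s.subset_replicate(rep) for T, s in by_temp.items()}
                try:
                    rep_sl = _shelf_lives_for_group(sub, order, endpoint)
                except ValueError:
                    continue  # replicate not fittable (e.g. too few points)
                for T, (_, sl) in rep_sl.items():
                    per_rep[T].append(sl)

        for T in sorted(by_temp):
            fit, sl = pooled[T]
            sd = float(np.std(per_rep[T], ddof=1)) if len(per_rep[T]) > 1 else float("nan")
            rows.append(
                {
                    "process": process,
                    "response": response,
                    "temperature_C": round(T - KELVIN_OFFSET, 6),
                    "order": order,
                    "r_squared": fit.r_squared,
                    "shelf_life_days": sl,
                    "sd_days": sd,
                    "endpoint_used": endpoint,
                }
            )
    return pd.DataFrame(rows)
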