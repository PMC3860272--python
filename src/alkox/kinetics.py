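"""Headspace gas kinetics: inventory conversion and consumption-rate fitting.

Sealed 200 mL serum-bottle incubations (100 mL sediment slurry under 100 mL
headspace of a single C1–C4 alkane at ~69 kPa overpressure, 7 °C) are sampled
every 15 days for 80 days.  Consumption rates are estimated by ordinary least
squares on headspace gas inventory versus time over all time points, and
expressed per mL of slurry, matching how slurry incubation rates are reported
in the field (nmol mL⁻¹ day⁻¹).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VesselGeometry",
    "HeadspaceTimeSeries",
    "RateEstimate",
    "headspace_amount",
    "fit_consumption_rate",
    "summarize_replicates",
    "percent_consumption",
    "onset_day",
    "percent_inhibition",
]

R_GAS = 8.314462618  # J mol-1 K-1

TREATMENTS = ("N2", "methane", "ethane", "propane", "butane")


@dataclass(frozen=True)
class VesselGeometry:
    """Serum-bottle geometry and conditions of the incubation."""

    slurry_volume_ml: float = 100.0
    headspace_volume_ml: float = 100.0
    temperature_c: float = 7.0
    gauge_pressure_kpa: float = 69.0
    ambient_pressure_kpa: float = 101.325

    def __post_init__(self) -> None:
        if self.slurry_volume_ml <= 0 or self.headspace_volume_ml <= 0:
            raise ValueError("vessel volumes must be positive")
        if self.temperature_c <= -273.15:
            raise ValueError("temperature below absolute zero")

    @property
    def absolute_pressure_kpa(self) -> float:
        return self.ambient_pressure_kpa + self.gauge_pressure_kpa

    def initial_headspace_umol(self) -> float:
        """Ideal-gas headspace inventory at fill pressure, µmol."""
        return headspace_amount(self, self.absolute_pressure_kpa, unit="kPa_abs")


@dataclass
class HeadspaceTimeSeries:
    """Headspace measurements of one replicate bottle over the incubation.

    ``values`` are either headspace concentrations (mM) or partial pressures
    (kPa) as declared by ``unit``; conversion to µmol happens once, in
    :func:`headspace_amount`.
    """

    treatment: str
    replicate_id: str
    times_days: Sequence[float]
    values: Sequence[float]
    unit: str = "mM"
    vessel: VesselGeometry = field(default_factory=VesselGeometry)

    def __post_init__(self) -> None:
        t = np.asarray(self.times_days, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(t < 0):
            raise ValueError("times must be nonnegative")
        if np.any(v < 0):
            raise ValueError("headspace values must be nonnegative")
        if self.unit not in ("mM", "kPa"):
            raise ValueError(f"unit must be 'mM' or 'kPa', got {self.unit!r}")
        self.times_days = t
        self.values = v

    def amounts_umol(self) -> np.ndarray:
        return np.array([headspace_amount(self.vessel, v, unit=self.unit)
                         for v in self.values])


@dataclass
class RateEstimate:
    """OLS consumption-rate estimate for one replicate series.

    ``rate`` is positive for consumption (negative regression slope), in
    nmol per mL slurry per day.
    """

    rate: float
    standard_error: float
    r_squared: float
    n_points: int
    percent_consumed: float
    onset_day: float | None
    intercept_umol: float = float("nan")


def headspace_amount(geometry: VesselGeometry, value: float, unit: str = "mM") -> float:
    """Amount of gas in the headspace, µmol.

    ``unit='mM'``: value is a headspace concentration, amount = conc × V_head.
    ``unit='kPa'``: value is a partial pressure above ambient baseline 0, i.e.
    the gas's own partial pressure; ideal-gas n = P·V/(R·T).
    ``unit='kPa_abs'`` is an alias for the same ideal-gas conversion (kept
    separate so call sites are explicit about gauge-vs-absolute bookkeeping).
    """
    if value < 0:
        raise ValueError("negative pressure/concentration")
    if unit == "mM":
        # mM × mL = µmol
        return value * geometry.headspace_volume_ml
    if unit in ("kPa", "kPa_abs"):
        t_kelvin = geometry.temperature_c + 273.15
        v_m3 = geometry.headspace_volume_ml * 1e-6
        n_mol = value * 1e3 * v_m3 / (R_GAS * t_kelvin)
        return n_mol * 1e6
    raise ValueError(f"unknown unit {unit!r}")


def fit_consumption_rate(ts: HeadspaceTimeSeries) -> RateEstimate:
    """OLS of headspace inventory vs time over all points; rate per mL slurry.

    No outlier rejection and no model selection: the estimator is a straight
    line through every sampled time point, so the estimate is comparable
    across treatments regardless of curvature.
    """
    t = np.asarray(ts.times_days, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 time points to fit a rate")
    if np.ptp(t) == 0:
        raise ValueError("degenerate design: no time variance")
    y = ts.amounts_umol()

    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(t)).fit()
    slope_umol_day = model.params[1]
    se_slope = model.bse[1]
    slurry = ts.vessel.slurry_volume_ml
    # µmol/day per mL slurry -> nmol mL-1 day-1
    rate = -slope_umol_day * 1e3 / slurry
    se = se_slope * 1e3 / slurry
    r2 = 1.0 if y.size == 2 else float(model.rsquared)
    return RateEstimate(
        rate=float(rate),
        standard_error=float(se) if np.isfinite(se) else 0.0,
        r_squared=r2,
        n_points=int(t.size),
        percent_consumed=percent_consumption(ts),
        onset_day=onset_day(ts),
        intercept_umol=float(model.params[0]),
    )


def summarize_replicates(estimates: Sequence[RateEstimate]) -> dict[str, float]:
    """Mean ± sd of independently fitted replicate rates."""
    if not estimates:
        raise ValueError("no replicate estimates to summarize")
    rates = np.array([e.rate for e in estimates])
    return {
        "rate_mean": float(rates.mean()),
        "rate_sd": float(rates.std(ddof=1)) if rates.size > 1 else 0.0,
        "n_replicates": int(rates.size),
        "percent_consumed_mean": float(np.mean([e.percent_consumed for e in estimates])),
    }


def percent_consumption(ts: HeadspaceTimeSeries) -> float:
    """100 × (amount(T0) − amount(Tf)) / amount(T0)."""
    amounts = ts.amounts_umol()
    if amounts[0] <= 0:
        raise ValueError("initial amount must be positive")
    return 100.0 * (amounts[0] - amounts[-1]) / amounts[0]


def onset_day(ts: HeadspaceTimeSeries, threshold_percent: float = 10.0) -> float | None:
    """Earliest sampled day at which cumulative consumption exceeds the threshold.

    Consumption onset is conventionally scored as the first sampling at which
    more than 10% of the initial inventory has disappeared; None if never.
    """
    amounts = ts.amounts_umol()
    if amounts[0] <= 0:
        raise ValueError("initial amount must be positive")
    consumed = 100.0 * (amounts[0] - amounts) / amounts[0]
    for day, c in zip(ts.times_days, consumed):
        if c > threshold_percent:
            return float(day)
    return None


def percent_inhibition(rate_uninhibited: float, rate_inhibited: float) -> float:
    """Percent reduction of the consumption rate under molybdate inhibition."""
    if rate_uninhibited <= 0:
        raise ValueError("uninhibited rate must be positive")
    return 100.0 * (1.0 - rate_inhibited / rate_uninhibited)
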