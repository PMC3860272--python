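"""Model/Results objects tying the pipeline stages together.

`AlkaneCouplingModel` is constructed from the raw observables of an
incubation campaign — headspace time series, 35S tracer assays, optional
molybdate-inhibited series and isotope endpoints.  ``fit()`` runs the full
estimation chain (per-replicate OLS rates -> replicate summaries -> tracer
SRRs -> control correction -> coupling ledger -> DIC mass balance) and
returns an `AlkaneCouplingResults` holding every intermediate with a
``summary()`` table, in the spirit of the statsmodels model/results split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coupling as _coupling
from . import io as _io
from .isotopes import IsotopeMassBalanceInput, solve_alkane_transfer, \
    fraction_of_loss_explained
from .kinetics import (HeadspaceTimeSeries, RateEstimate, VesselGeometry,
                       fit_consumption_rate, summarize_replicates)
from .radiotracer import TracerAssay, compute_srr
from .stoichiometry import ALKANES

__all__ = ["AlkaneCouplingModel", "AlkaneCouplingResults"]


class AlkaneCouplingModel:
    """Joint model of alkane consumption and sulfate reduction in slurries.

    Parameters
    ----------
    time_series
        One `HeadspaceTimeSeries` per replicate bottle (all treatments).
    tracer_assays
        treatment -> `TracerAssay` or list of replicate assays; must include
        the N2 control, whose rate is the intrinsic-SRR correction.
    inhibited_rates
        treatment -> (rate, sd) from molybdate-amended incubations, optional.
    isotopes
        treatment -> `IsotopeMassBalanceInput`, optional; enables the DIC
        carbon-transfer estimates.
    reaction_source
        'table6' uses the published reaction set verbatim; 'derived' uses
        electron-balanced reactions ((3n+1)/4 sulfate per alkane).
    isotope_mode
        'delta' solves the DIC mass balance in delta space (the conventional
        linear form); 'ratio' uses exact 13C/12C atom-fraction bookkeeping.
    """

    def __init__(self, time_series: list[HeadspaceTimeSeries],
                 tracer_assays: dict[str, TracerAssay | list[TracerAssay]],
                 inhibited_rates: dict[str, tuple[float, float]] | None = None,
                 isotopes: dict[str, IsotopeMassBalanceInput] | None = None,
                 reaction_source: str = "table6",
                 control_treatment: str = "N2",
                 duration_days: float = 80.0,
                 isotope_mode: str = "delta"):
        if not time_series:
            raise ValueError("no time series supplied")
        if control_treatment not in tracer_assays:
            raise KeyError(
                f"tracer assays must include the {control_treatment!r} control")
        self.time_series = time_series
        self.tracer_assays = {
            t: (v if isinstance(v, list) else [v]) for t, v in tracer_assays.items()}
        self.inhibited_rates = inhibited_rates or {}
        self.isotopes = isotopes or {}
        self.reaction_source = reaction_source
        self.control_treatment = control_treatment
        self.duration_days = duration_days
        if isotope_mode not in ("delta", "ratio"):
            raise ValueError("isotope_mode must be 'delta' or 'ratio'")
        self.isotope_mode = isotope_mode

    @classmethod
    def from_dataframes(cls, timeseries_df: pd.DataFrame, assays_df: pd.DataFrame,
                        vessel: VesselGeometry | None = None, **kwargs
                        ) -> "AlkaneCouplingModel":
        """Build from the standard CSV-shaped frames (see io.SCHEMAS)."""
        import io as _stdio
        ts_buf = _stdio.StringIO(timeseries_df.to_csv(index=False))
        as_buf = _stdio.StringIO(assays_df.to_csv(index=False))
        series = _io.read_timeseries_csv(ts_buf, vessel=vessel)
        assays = _io.read_assays_csv(as_buf)
        return cls(series, assays, **kwargs)

    @classmethod
    def from_dataset(cls, dataset, **kwargs) -> "AlkaneCouplingModel":
        """Build from a simulated `SyntheticDataset`."""
        isotopes = {t: e["balance_input"] for t, e in dataset.isotopes.items()}
        duration = dataset.truth["config"]["duration_days"]
        kwargs.setdefault("duration_days", duration)
        return cls(dataset.time_series, dict(dataset.tracer_assays),
                   isotopes=isotopes, **kwargs)

    def fit(self) -> "AlkaneCouplingResults":
        replicate_fits: dict[str, list[RateEstimate]] = {}
        for ts in self.time_series:
            replicate_fits.setdefault(ts.treatment, []).append(
                fit_consumption_rate(ts))
        rate_summaries = {t: summarize_replicates(fits)
                          for t, fits in replicate_fits.items()}

        srrs: dict[str, tuple[float, float]] = {}
        for treatment, assays in self.tracer_assays.items():
            vals = np.array([compute_srr(a) for a in assays])
            srrs[treatment] = (float(vals.mean()),
                               float(vals.std(ddof=1)) if vals.size > 1 else 0.0)

        rates = {t: (s["rate_mean"], s["rate_sd"])
                 for t, s in rate_summaries.items()
                 if t != self.control_treatment and t in ALKANES}
        reports = _coupling.build_table4(
            rates, srrs, inhibited_rates=self.inhibited_rates,
            control_treatment=self.control_treatment,
            reaction_source=self.reaction_source)

        transfers: dict[str, dict] = {}
        for treatment, inp in self.isotopes.items():
            result = solve_alkane_transfer(inp, mode=self.isotope_mode,
                                           duration_days=self.duration_days)
            entry = {
                "alk_conc_transferred_mol_per_l": result.alk_conc_transferred,
                "moles_c_transferred": result.moles_transferred,
                "implied_rate_nmol_c_per_ml_day": result.implied_rate,
            }
            if treatment in rates and treatment in ALKANES:
                carbon_rate = ALKANES[treatment].n_carbons * rates[treatment][0]
                if carbon_rate > 0:
                    entry["fraction_of_loss_explained"] = fraction_of_loss_explained(
                        result.implied_rate, carbon_rate)
            transfers[treatment] = entry

        return AlkaneCouplingResults(
            model=self, replicate_fits=replicate_fits,
            rate_summaries=rate_summaries, srrs=srrs, reports=reports,
            transfers=transfers)


@dataclass
class AlkaneCouplingResults:
    """Fitted rates, SRRs, coupling ledger and isotope transfers."""

    model: AlkaneCouplingModel
    replicate_fits: dict[str, list[RateEstimate]]
    rate_summaries: dict[str, dict]
    srrs: dict[str, tuple[float, float]]
    reports: list
    transfers: dict[str, dict] = field(default_factory=dict)

    def table4(self, printed_style: bool = False) -> pd.DataFrame:
        """The coupling ledger; printed_style applies display rounding."""
        return _io.table4_frame(self.reports, printed_style=printed_style)

    def rates_frame(self) -> pd.DataFrame:
        rows = [{"treatment": t, **s} for t, s in self.rate_summaries.items()]
        return pd.DataFrame(rows)

    def srr_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"treatment": t, "srr_nmol_per_ml_day": m, "srr_sd": s}
             for t, (m, s) in self.srrs.items()])

    def transfers_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{"treatment": t, **v} for t, v in self.transfers.items()])

    def summary(self) -> str:
        """Plain-text report of rates, SRRs and the coupling ledger."""
        lines = ["Alkane oxidation / sulfate reduction coupling", "=" * 46, ""]
        lines.append(f"reaction source: {self.model.reaction_source}; "
                     f"control: {self.model.control_treatment}; "
                     f"rates per mL slurry from OLS over all time points")
        lines.append("")
        lines.append("Consumption rates (nmol alkane mL-1 day-1):")
        for t, s in self.rate_summaries.items():
            lines.append(f"  {t:<9s} {s['rate_mean']:8.1f} ± {s['rate_sd']:.1f}"
                         f"   ({s['n_replicates']} replicates, "
                         f"{s['percent_consumed_mean']:.0f}% consumed)")
        lines.append("")
        lines.append("Sulfate reduction rates (nmol S mL-1 day-1):")
        for t, (m, s) in self.srrs.items():
            lines.append(f"  {t:<9s} {m:8.1f} ± {s:.1f}")
        lines.append("")
        lines.append("Coupling ledger (mol alkane : mol SO4):")
        header = (f"  {'treatment':<9s} {'obs(tot)':>9s} {'obs(corr)':>9s} "
                  f"{'predicted':>9s} {'demand':>9s} {'explained':>9s}")
        lines.append(header)
        for r in self.reports:
            lines.append(
                f"  {r.treatment:<9s} {r.observed_ratio_total:9.2f} "
                f"{r.observed_ratio_corrected:9.2f} {r.predicted_ratio:9.2f} "
                f"{r.predicted_sulfate_demand:9.0f} {r.srr_fraction_explained:8.0%}")
        if self.transfers:
            lines.append("")
            lines.append("DIC carbon-transfer estimates:")
            for t, v in self.transfers.items():
                rate = v.get("implied_rate_nmol_c_per_ml_day")
                frac = v.get("fraction_of_loss_explained")
                extra = f", {frac:.0%} of headspace loss" if frac is not None else ""
                lines.append(f"  {t:<9s} {v['moles_c_transferred'] * 1e3:.2f} mmol C"
                             f" -> {rate:.0f} nmol C mL-1 day-1{extra}")
        return "\n".join(lines)

    def plot_timeseries(self, ax=None):
        """Diagnostic plot: headspace inventory vs time with fitted lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        seen: dict[str, int] = {}
        for ts in self.model.time_series:
            amounts = ts.amounts_umol()
            line, = ax.plot(ts.times_days, amounts, "o", alpha=0.6,
                            label=ts.replicate_id)
            idx = seen.get(ts.treatment, 0)
            seen[ts.treatment] = idx + 1
            fit = self.replicate_fits[ts.treatment][idx]
            t = np.asarray(ts.times_days)
            slope = -fit.rate * ts.vessel.slurry_volume_ml / 1e3
            ax.plot(t, fit.intercept_umol + slope * t, "-",
                    color=line.get_color(), alpha=0.5)
        ax.set_xlabel("day")
        ax.set_ylabel("headspace inventory (µmol)")
        ax.legend(fontsize="x-small")
        return ax
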