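"""CSV schemas, readers/writers and validation for the incubation pipeline.

All tabular interchange is plain RFC-4180 CSV with units declared in column
names.  Schemas:

* ``timeseries``: treatment, replicate, day, value, unit (mM|kPa)
* ``assays``:     treatment, replicate, sulfate_nmol_per_ml, a_dpm, A_dpm, t_days
* ``isotopes``:   treatment, pool (alkane|DIC), timepoint (T0|Tf),
                  delta_permil, conc_mm (conc may be empty except DIC @ T0)
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .coupling import CouplingReport, round_table4_style
from .isotopes import IsotopeMassBalanceInput
from .kinetics import HeadspaceTimeSeries, VesselGeometry, TREATMENTS
from .radiotracer import TracerAssay

__all__ = [
    "SCHEMAS",
    "validate_csv",
    "ValidationIssue",
    "read_timeseries_csv",
    "read_assays_csv",
    "read_isotopes_csv",
    "write_timeseries_csv",
    "write_assays_csv",
    "write_isotopes_csv",
    "write_rates_csv",
    "write_srr_csv",
    "write_table4_csv",
    "write_transfers_csv",
    "dataset_to_csvs",
]

SCHEMAS: dict[str, dict] = {
    "timeseries": {
        "columns": ["treatment", "replicate", "day", "value", "unit"],
        "key": ["treatment", "replicate", "day"],
    },
    "assays": {
        "columns": ["treatment", "replicate", "sulfate_nmol_per_ml",
                    "a_dpm", "A_dpm", "t_days"],
        "key": ["treatment", "replicate"],
    },
    "isotopes": {
        "columns": ["treatment", "pool", "timepoint", "delta_permil", "conc_mm"],
        "key": ["treatment", "pool", "timepoint"],
    },
}


@dataclass
class ValidationIssue:
    row: int | None  # 0-based data row; None for file-level problems
    column: str | None
    message: str

    def __str__(self) -> str:
        loc = f"row {self.row}" if self.row is not None else "file"
        if self.column:
            loc += f", column {self.column!r}"
        return f"{loc}: {self.message}"


def validate_csv(path, schema_name: str) -> list[ValidationIssue]:
    """Check a CSV against a named schema; empty list means clean."""
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; have {sorted(SCHEMAS)}")
    schema = SCHEMAS[schema_name]
    issues: list[ValidationIssue] = []
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # unreadable/not CSV
        return [ValidationIssue(None, None, f"cannot parse CSV: {exc}")]
    missing = [c for c in schema["columns"] if c not in df.columns]
    if missing:
        issues.append(ValidationIssue(None, None, f"missing columns: {missing}"))
        return issues

    dup = df.duplicated(subset=schema["key"], keep=False)
    for idx in df.index[dup]:
        issues.append(ValidationIssue(int(idx), None,
                                      f"duplicate key {tuple(df.loc[idx, schema['key']])}"))

    checkers = {
        "timeseries": _check_timeseries_row,
        "assays": _check_assay_row,
        "isotopes": _check_isotope_row,
    }
    check = checkers[schema_name]
    for idx, row in df.iterrows():
        issues.extend(check(int(idx), row))
    return issues


def _num(row, col):
    try:
        v = float(row[col])
    except (TypeError, ValueError):
        return None
    return v


def _check_timeseries_row(idx, row) -> list[ValidationIssue]:
    out = []
    if row["unit"] not in ("mM", "kPa"):
        out.append(ValidationIssue(idx, "unit", f"unit must be mM or kPa, got {row['unit']!r}"))
    for col, minimum in (("day", 0.0), ("value", 0.0)):
        v = _num(row, col)
        if v is None:
            out.append(ValidationIssue(idx, col, "not numeric"))
        elif v < minimum:
            out.append(ValidationIssue(idx, col, f"negative value {v}"))
    return out


def _check_assay_row(idx, row) -> list[ValidationIssue]:
    out = []
    for col in ("sulfate_nmol_per_ml", "a_dpm", "A_dpm", "t_days"):
        v = _num(row, col)
        if v is None:
            out.append(ValidationIssue(idx, col, "not numeric"))
        elif v < 0:
            out.append(ValidationIssue(idx, col, f"negative value {v}"))
        elif col == "t_days" and v == 0:
            out.append(ValidationIssue(idx, col, "incubation time must be positive"))
    return out


def _check_isotope_row(idx, row) -> list[ValidationIssue]:
    out = []
    if row["pool"] not in ("alkane", "DIC"):
        out.append(ValidationIssue(idx, "pool", f"pool must be alkane or DIC, got {row['pool']!r}"))
    if row["timepoint"] not in ("T0", "Tf"):
        out.append(ValidationIssue(idx, "timepoint", f"timepoint must be T0 or Tf"))
    v = _num(row, "delta_permil")
    if v is None:
        out.append(ValidationIssue(idx, "delta_permil", "not numeric"))
    elif not -120 < v < 50:
        out.append(ValidationIssue(idx, "delta_permil", f"delta {v} outside sanity window"))
    return out


# -- readers ---------------------------------------------------------------

def read_timeseries_csv(path, vessel: VesselGeometry | None = None
                        ) -> list[HeadspaceTimeSeries]:
    """Load a time-series CSV into per-replicate series objects."""
    vessel = vessel or VesselGeometry()
    df = pd.read_csv(path)
    series = []
    for (treatment, replicate), grp in df.groupby(["treatment", "replicate"],
                                                  sort=False):
        grp = grp.sort_values("day")
        units = grp["unit"].unique()
        if len(units) != 1:
            raise ValueError(
                f"{treatment}/{replicate}: mixed units {list(units)} in one series")
        series.append(HeadspaceTimeSeries(
            treatment=str(treatment), replicate_id=str(replicate),
            times_days=grp["day"].to_numpy(float),
            values=grp["value"].to_numpy(float),
            unit=str(units[0]), vessel=vessel))
    return series


def read_assays_csv(path) -> dict[str, list[TracerAssay]]:
    df = pd.read_csv(path)
    out: dict[str, list[TracerAssay]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["treatment"]), []).append(TracerAssay(
            sulfate_conc=float(row["sulfate_nmol_per_ml"]),
            a=float(row["a_dpm"]), A=float(row["A_dpm"]),
            t=float(row["t_days"])))
    return out


def read_isotopes_csv(path, volume_ml: float = 100.0
                      ) -> dict[str, IsotopeMassBalanceInput]:
    """Assemble per-treatment mass-balance inputs from the long-format CSV."""
    df = pd.read_csv(path)
    out = {}
    for treatment, grp in df.groupby("treatment", sort=False):
        rows = {(r["pool"], r["timepoint"]): r for _, r in grp.iterrows()}
        try:
            dic0 = rows[("DIC", "T0")]
            dicf = rows[("DIC", "Tf")]
            alk0 = rows[("alkane", "T0")]
        except KeyError as exc:
            raise ValueError(
                f"{treatment}: isotope CSV needs DIC@T0, DIC@Tf and alkane@T0 "
                f"rows; missing {exc}") from None
        out[str(treatment)] = IsotopeMassBalanceInput(
            dic_T0_conc=float(dic0["conc_mm"]) / 1e3,
            delta_dic_T0=float(dic0["delta_permil"]),
            delta_dic_Tf=float(dicf["delta_permil"]),
            delta_alk_T0=float(alk0["delta_permil"]),
            volume_ml=volume_ml)
    return out


# -- writers ---------------------------------------------------------------

def write_timeseries_csv(series: list[HeadspaceTimeSeries], path) -> None:
    rows = []
    for ts in series:
        for day, value in zip(ts.times_days, ts.values):
            rows.append({"treatment": ts.treatment, "replicate": ts.replicate_id,
                         "day": day, "value": value, "unit": ts.unit})
    pd.DataFrame(rows, columns=SCHEMAS["timeseries"]["columns"]).to_csv(
        path, index=False)


def write_assays_csv(assays: dict[str, TracerAssay | list[TracerAssay]], path) -> None:
    rows = []
    for treatment, entry in assays.items():
        entries = entry if isinstance(entry, list) else [entry]
        for i, a in enumerate(entries, start=1):
            rows.append({"treatment": treatment, "replicate": f"{treatment}-{i}",
                         "sulfate_nmol_per_ml": a.sulfate_conc, "a_dpm": a.a,
                         "A_dpm": a.A, "t_days": a.t})
    pd.DataFrame(rows, columns=SCHEMAS["assays"]["columns"]).to_csv(path, index=False)


def write_isotopes_csv(isotopes: dict[str, dict], path) -> None:
    """Write simulated isotope endpoints (see SyntheticDataset.isotopes)."""
    rows = []
    for treatment, entry in isotopes.items():
        inp: IsotopeMassBalanceInput = entry["balance_input"]
        rows.append({"treatment": treatment, "pool": "DIC", "timepoint": "T0",
                     "delta_permil": inp.delta_dic_T0,
                     "conc_mm": inp.dic_T0_conc * 1e3})
        rows.append({"treatment": treatment, "pool": "DIC", "timepoint": "Tf",
                     "delta_permil": inp.delta_dic_Tf, "conc_mm": ""})
        rows.append({"treatment": treatment, "pool": "alkane", "timepoint": "T0",
                     "delta_permil": inp.delta_alk_T0, "conc_mm": ""})
        rows.append({"treatment": treatment, "pool": "alkane", "timepoint": "Tf",
                     "delta_permil": entry["delta_alk_Tf"], "conc_mm": ""})
    pd.DataFrame(rows, columns=SCHEMAS["isotopes"]["columns"]).to_csv(path, index=False)


def write_rates_csv(rates: dict[str, dict], path) -> None:
    rows = [{"treatment": t, **summary} for t, summary in rates.items()]
    pd.DataFrame(rows).rename(columns={
        "rate_mean": "rate_nmol_per_ml_day",
        "rate_sd": "rate_sd_nmol_per_ml_day"}).to_csv(path, index=False)


def write_srr_csv(srrs: dict[str, tuple[float, float]], path) -> None:
    rows = [{"treatment": t, "srr_nmol_per_ml_day": m, "srr_sd_nmol_per_ml_day": s}
            for t, (m, s) in srrs.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


_TABLE4_COLUMNS = [
    "treatment",
    "alkane_rate_nmol_per_ml_day", "alkane_rate_sd",
    "inhibited_rate_nmol_per_ml_day", "percent_inhibition",
    "total_srr_nmol_per_ml_day", "total_srr_sd",
    "observed_ratio_total",
    "corrected_srr_nmol_per_ml_day", "corrected_srr_sd",
    "observed_ratio_corrected",
    "predicted_ratio",
    "predicted_sulfate_demand_nmol_per_ml_day",
    "srr_fraction_explained",
    "excess_carbon_rate_nmol_c_per_ml_day",
]


def table4_frame(reports: list[CouplingReport], printed_style: bool = False
                 ) -> pd.DataFrame:
    """Coupling ledger as a DataFrame; optionally with display rounding."""
    rows = []
    for r in reports:
        row = {
            "treatment": r.treatment,
            "alkane_rate_nmol_per_ml_day": r.alkane_rate,
            "alkane_rate_sd": r.alkane_rate_sd,
            "inhibited_rate_nmol_per_ml_day": r.inhibited_rate,
            "percent_inhibition": r.percent_inhibition,
            "total_srr_nmol_per_ml_day": r.total_srr,
            "total_srr_sd": r.total_srr_sd,
            "observed_ratio_total": r.observed_ratio_total,
            "corrected_srr_nmol_per_ml_day": r.corrected_srr,
            "corrected_srr_sd": r.corrected_srr_sd,
            "observed_ratio_corrected": r.observed_ratio_corrected,
            "predicted_ratio": r.predicted_ratio,
            "predicted_sulfate_demand_nmol_per_ml_day": r.predicted_sulfate_demand,
            "srr_fraction_explained": r.srr_fraction_explained,
            "excess_carbon_rate_nmol_c_per_ml_day": r.excess_carbon_rate,
        }
        if printed_style:
            for key in ("observed_ratio_total", "observed_ratio_corrected",
                        "predicted_ratio"):
                row[key] = round_table4_style(row[key])
            for key in ("alkane_rate_nmol_per_ml_day", "total_srr_nmol_per_ml_day",
                        "corrected_srr_nmol_per_ml_day", "percent_inhibition",
                        "predicted_sulfate_demand_nmol_per_ml_day"):
                if row[key] is not None:
                    row[key] = round(row[key])
        rows.append(row)
    return pd.DataFrame(rows, columns=_TABLE4_COLUMNS)


def write_table4_csv(reports: list[CouplingReport], path,
                     printed_style: bool = False) -> None:
    table4_frame(reports, printed_style=printed_style).to_csv(path, index=False)


def write_transfers_csv(transfers: dict[str, dict], path) -> None:
    rows = [{"treatment": t, **vals} for t, vals in transfers.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def dataset_to_csvs(dataset, outdir) -> dict[str, Path]:
    """Write a SyntheticDataset as the standard CSV bundle plus truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "timeseries": outdir / "timeseries.csv",
        "assays": outdir / "assays.csv",
        "isotopes": outdir / "isotopes.csv",
        "endpoints": outdir / "endpoints.csv",
        "truth": outdir / "truth.json",
    }
    write_timeseries_csv(dataset.time_series, paths["timeseries"])
    write_assays_csv(dataset.tracer_assays, paths["assays"])
    write_isotopes_csv(dataset.isotopes, paths["isotopes"])
    rows = [{"treatment": t, "sulfate_mM": v["sulfate_mM"],
             "sulfide_mM": v["sulfide_mM"]} for t, v in dataset.endpoints.items()]
    pd.DataFrame(rows).to_csv(paths["endpoints"], index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=2, default=float)
    return paths
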