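"""The alkane-oxidation / sulfate-reduction coupling ledger.

Assembles, per treatment, the observed mol-alkane : mol-sulfate ratio (with
total and control-corrected SRR), the stoichiometric prediction from the
reaction set, the sulfate demand the measured alkane rate would impose, the
fraction of measured sulfate reduction that demand explains, and the carbon
flux left unexplained by sulfate-coupled oxidation.  The ratio basis is
mol alkane per mol sulfate throughout; the per-carbon rate is carried
alongside (carbon_rate = n_carbons × alkane_rate) and never mixed in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

from .radiotracer import SrrResult, correct_srr
from .kinetics import percent_inhibition
from .stoichiometry import (
    ALKANES,
    Reaction,
    derive_alkane_sulfate_reaction,
    predicted_ratios,
    table6_reaction,
)

__all__ = [
    "CouplingReport",
    "observed_ratio",
    "predicted_sulfate_demand",
    "srr_fraction_explained",
    "excess_carbon_rate",
    "nitrate_oxidation_bound",
    "ratio_uncertainty",
    "reaction_for",
    "build_table4",
    "round_table4_style",
]

#: Literature reaction id per alkane treatment.
_TABLE6_IDS = {"methane": 2, "ethane": 3, "propane": 4, "butane": 5}


@dataclass
class CouplingReport:
    """One treatment row of the coupling ledger."""

    treatment: str
    alkane_rate: float                 # nmol alkane mL-1 day-1
    alkane_rate_sd: float
    carbon_rate: float                 # nmol C mL-1 day-1
    inhibited_rate: float | None
    percent_inhibition: float | None
    total_srr: float                   # nmol S mL-1 day-1
    total_srr_sd: float
    corrected_srr: float
    corrected_srr_sd: float
    observed_ratio_total: float        # mol alkane per mol SO4
    observed_ratio_total_sd: float
    observed_ratio_corrected: float
    observed_ratio_corrected_sd: float
    predicted_ratio: float
    predicted_sulfate_demand: float    # nmol S mL-1 day-1
    srr_fraction_explained: float
    excess_carbon_rate: float          # nmol C mL-1 day-1


def observed_ratio(alkane_rate: float, srr: float) -> float:
    """Mol alkane consumed per mol sulfate reduced."""
    if srr <= 0:
        raise ValueError("SRR must be positive to form a ratio")
    return alkane_rate / srr


def predicted_sulfate_demand(alkane_rate: float, reaction: Reaction) -> float:
    """Sulfate the measured alkane rate would reduce at reaction stoichiometry."""
    ratios = predicted_ratios(reaction)  # validates sulfate + single donor
    sulfate_per_alkane = 1 / ratios["alkane_to_sulfate"]
    return alkane_rate * float(sulfate_per_alkane)


def srr_fraction_explained(demand: float, measured_srr: float) -> float:
    """Stoichiometric demand over measured SRR; >1 reads as fold-excess."""
    if measured_srr <= 0:
        raise ValueError("measured SRR must be positive")
    return demand / measured_srr


def excess_carbon_rate(carbon_rate: float, srr: float, reaction: Reaction) -> float:
    """Carbon flux beyond what the measured SRR can oxidize, nmol C mL-1 day-1.

    Negative values indicate sulfate reduction in excess of the carbon supply.
    """
    c_per_s = float(predicted_ratios(reaction)["carbon_to_sulfate"])
    return carbon_rate - srr * c_per_s


def nitrate_oxidation_bound(no3_conc_um: float, electrons_per_n: float = 5.0,
                            electrons_per_c: float = 4.0,
                            volume_ml: float = 100.0) -> tuple[float, float]:
    """Upper bound on DIC from nitrate-coupled oxidation: (µM DIC, µmol C).

    Complete denitrification to N2 accepts 5 electrons per N; oxidizing
    organic carbon of mean oxidation state 0 to CO2 donates 4 per C, so the
    DIC ceiling is [NO3] × 5/4 (per-carbon electron count configurable, e.g.
    8 for methane-derived carbon).
    """
    if no3_conc_um < 0:
        raise ValueError("nitrate concentration must be nonnegative")
    if electrons_per_c <= 0:
        raise ValueError("electrons per carbon must be positive")
    dic_um = no3_conc_um * electrons_per_n / electrons_per_c
    umol_c = dic_um * volume_ml / 1000.0
    return dic_um, umol_c


def ratio_uncertainty(num: float, num_sd: float, den: float, den_sd: float) -> float:
    """First-order (delta-method) sd of a ratio of independent estimates."""
    if den == 0:
        return float("nan")
    r = num / den
    if num == 0:
        return abs(num_sd / den)
    return abs(r) * math.hypot(num_sd / num if num else 0.0, den_sd / den)


def reaction_for(treatment: str, source: str = "table6") -> Reaction:
    """The coupling reaction used for a treatment, printed or re-derived."""
    if source == "table6":
        return table6_reaction(_TABLE6_IDS[treatment])
    if source == "derived":
        return derive_alkane_sulfate_reaction(ALKANES[treatment])
    raise ValueError(f"reaction source must be 'table6' or 'derived', got {source!r}")


def build_table4(
    rates: Mapping[str, tuple[float, float]],
    srrs: Mapping[str, tuple[float, float]],
    reactions: Mapping[str, Reaction] | None = None,
    inhibited_rates: Mapping[str, tuple[float, float]] | None = None,
    control_treatment: str = "N2",
    reaction_source: str = "table6",
) -> list[CouplingReport]:
    """Assemble the full coupling ledger, one report per alkane treatment.

    ``rates`` / ``srrs`` map treatment -> (mean, sd) in nmol mL-1 day-1;
    ``srrs`` must include the N2 control, whose rate corrects the others.
    """
    if control_treatment not in srrs:
        raise KeyError(
            f"missing {control_treatment!r} control SRR: the ledger requires the "
            "intrinsic (N2-headspace) sulfate reduction rate for correction")
    control, control_sd = srrs[control_treatment]
    reports: list[CouplingReport] = []
    for treatment, (rate, rate_sd) in rates.items():
        if treatment == control_treatment:
            continue
        total, total_sd = srrs[treatment]
        corr: SrrResult = correct_srr(total, control, total_sd, control_sd)
        rxn = (reactions or {}).get(treatment) or reaction_for(treatment, reaction_source)
        pred = float(predicted_ratios(rxn)["alkane_to_sulfate"])
        n_c = ALKANES[treatment].n_carbons
        demand = predicted_sulfate_demand(rate, rxn)
        inhib = (inhibited_rates or {}).get(treatment)
        corrected = corr.corrected_srr
        reports.append(CouplingReport(
            treatment=treatment,
            alkane_rate=rate,
            alkane_rate_sd=rate_sd,
            carbon_rate=n_c * rate,
            inhibited_rate=inhib[0] if inhib else None,
            percent_inhibition=(percent_inhibition(rate, inhib[0]) if inhib else None),
            total_srr=total,
            total_srr_sd=total_sd,
            corrected_srr=corrected,
            corrected_srr_sd=corr.corrected_sd,
            observed_ratio_total=observed_ratio(rate, total),
            observed_ratio_total_sd=ratio_uncertainty(rate, rate_sd, total, total_sd),
            observed_ratio_corrected=(rate / corrected if corrected > 0 else float("nan")),
            observed_ratio_corrected_sd=ratio_uncertainty(
                rate, rate_sd, corrected, corr.corrected_sd or 0.0)
            if corrected > 0 else float("nan"),
            predicted_ratio=pred,
            predicted_sulfate_demand=demand,
            srr_fraction_explained=srr_fraction_explained(demand, total),
            excess_carbon_rate=excess_carbon_rate(n_c * rate, total, rxn),
        ))
    return reports


def round_table4_style(value: float) -> float:
    """Display rounding used by the ledger: 1 decimal at >=1, 2 below 1."""
    if not math.isfinite(value):
        return value
    return round(value, 1) if abs(value) >= 1 else round(value, 2)
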