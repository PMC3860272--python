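"""Synthetic incubation generator: determinism, conservation, recovery."""

import numpy as np
import pytest

from alkox.isotopes import delta_to_ratio, solve_alkane_transfer
from alkox.kinetics import fit_consumption_rate
from alkox.simulate import (
    SimulationConfig,
    scenario_paper_defaults,
    simulate_incubation,
)


def test_scenario_defaults_carry_the_study_conditions():
    cfg = scenario_paper_defaults()
    assert cfg.true_rates == {"N2": 0.0, "methane": 263.0, "ethane": 168.0,
                              "propane": 354.0, "butane": 125.0}
    assert cfg.initial_sulfate_mm == 31.6
    assert cfg.initial_sulfide_mm == 2.3
    assert cfg.intrinsic_srr == 94.0
    assert cfg.duration_days == 80.0
    assert cfg.sampling_interval_days == 15.0
    assert cfg.vessel.slurry_volume_ml == 100.0
    assert cfg.vessel.temperature_c == 7.0
    assert len(cfg.sampling_times()) == 6


def test_identical_seed_gives_bit_identical_dataset():
    a = simulate_incubation(scenario_paper_defaults(seed=11))
    b = simulate_incubation(scenario_paper_defaults(seed=11))
    for ts_a, ts_b in zip(a.time_series, b.time_series):
        assert np.array_equal(ts_a.values, ts_b.values)
    assert a.tracer_assays["propane"].a == b.tracer_assays["propane"].a
    c = simulate_incubation(scenario_paper_defaults(seed=12))
    assert not np.array_equal(a.time_series[2].values, c.time_series[2].values)


def test_noiseless_methane_series_loses_published_inventory():
    """263 nmol mL-1 day-1 over 100 mL slurry and 80 days is 2.104 mmol."""
    ds = simulate_incubation(scenario_paper_defaults(seed=0, noise_cv=0.0))
    ts = ds.series_for("methane")[0]
    amounts = ts.amounts_umol()
    slope_per_day = (amounts[-1] - amounts[0]) / (ts.times_days[-1] - ts.times_days[0])
    assert slope_per_day == pytest.approx(-26.3, rel=1e-9)
    truth = ds.truth["per_treatment"]["methane"]
    assert truth["consumed_c_umol"] == pytest.approx(2104.0, rel=1e-12)


def test_sulfur_conservation_and_butane_envelope(noiseless_dataset):
    """Sulfate decline equals sulfide rise; the butane endpoint stays inside
    the observed final-concentration envelope (13.3–31.6 mM)."""
    cfg = noiseless_dataset.truth["config"]
    for treatment, ep in noiseless_dataset.endpoints.items():
        decline = cfg["initial_sulfate_mm"] - ep["sulfate_mM"]
        rise = ep["sulfide_mM"] - cfg["initial_sulfide_mm"]
        assert decline == pytest.approx(rise, rel=1e-12)
    assert 13.3 <= noiseless_dataset.endpoints["butane"]["sulfate_mM"] <= 31.6


def test_carbon_conservation_in_noiseless_mode(noiseless_dataset):
    for treatment in ("methane", "ethane", "propane", "butane"):
        truth = noiseless_dataset.truth["per_treatment"][treatment]
        frac = noiseless_dataset.truth["config"]["fraction_to_dic"][treatment]
        assert truth["c_to_dic_umol"] == pytest.approx(
            frac * truth["consumed_c_umol"], rel=1e-12)


def test_isotope_mass_conservation_in_ratio_space(noiseless_dataset):
    """Total 13C across residual alkane + DIC + unmodelled sink is constant."""
    cfg = noiseless_dataset.truth["config"]
    for treatment in ("methane", "propane", "butane"):
        truth = noiseless_dataset.truth["per_treatment"][treatment]
        iso = noiseless_dataset.isotopes[treatment]
        n_c = {"methane": 1, "ethane": 2, "propane": 3, "butane": 4}[treatment]
        c0 = truth["initial_amount_umol"] * n_c
        cf = c0 - truth["consumed_c_umol"]

        def heavy(total_c, delta):
            r = delta_to_ratio(delta)
            return total_c * r / (1 + r)

        dic0_umol = cfg["dic_T0_mm"] / 1e3 * 100.0 * 1e3
        initial_13c = heavy(c0, cfg["delta_alk_T0"][treatment]) + \
            heavy(dic0_umol, cfg["delta_dic_T0"])
        consumed_13c = heavy(c0, cfg["delta_alk_T0"][treatment]) - \
            heavy(cf, iso["delta_alk_Tf"])
        frac = cfg["fraction_to_dic"][treatment]
        final_13c = (heavy(cf, iso["delta_alk_Tf"])
                     + heavy(dic0_umol + truth["c_to_dic_umol"], iso["delta_dic_Tf"])
                     + (1 - frac) * consumed_13c)
        assert final_13c == pytest.approx(initial_13c, rel=1e-12)


def test_rayleigh_enrichment_follows_closed_form():
    """Residual-pool shift matches delta = delta0 + eps*ln f for the Rayleigh
    approximation (checked at the per-mil accuracy of the linearisation)."""
    cfg = scenario_paper_defaults(seed=0, noise_cv=0.0)
    ds = simulate_incubation(cfg)
    for treatment in ("propane", "butane"):
        truth = ds.truth["per_treatment"][treatment]
        eps = cfg.epsilon_permil[treatment]
        expected_shift = eps * np.log(truth["fraction_remaining"])
        shift = ds.isotopes[treatment]["delta_alk_Tf"] - cfg.delta_alk_T0[treatment]
        assert shift == pytest.approx(expected_shift, abs=0.05)


def test_mass_balance_recovers_routed_carbon_when_all_goes_to_dic():
    """fraction_to_dic = 1 with no fractionation: the ratio-space balance
    recovers the consumed carbon exactly; the delta-space approximation is
    within 1% when the DIC shift is kept under ~10 per mil."""
    cfg = SimulationConfig(
        seed=5, noise_cv=0.0, treatments=("N2", "methane"),
        fraction_to_dic={"methane": 1.0}, epsilon_permil={"methane": 0.0},
        dic_T0_mm=300.0,  # large DIC pool keeps the shift small
    )
    ds = simulate_incubation(cfg)
    truth = ds.truth["per_treatment"]["methane"]
    inp = ds.isotopes["methane"]["balance_input"]
    shift = abs(inp.delta_dic_Tf - inp.delta_dic_T0)
    assert shift <= 10.0
    consumed_mol = truth["consumed_c_umol"] * 1e-6

    exact = solve_alkane_transfer(inp, mode="ratio").moles_transferred
    assert exact == pytest.approx(consumed_mol, rel=1e-9)
    approx = solve_alkane_transfer(inp, mode="delta").moles_transferred
    assert approx == pytest.approx(consumed_mol, rel=0.01)
    # conservation: the balance never implies more carbon than was lost
    assert exact <= consumed_mol * (1 + 1e-9)


def test_first_order_mode_decays_exponentially():
    cfg = SimulationConfig(seed=0, noise_cv=0.0, kinetic_order="first",
                           treatments=("methane",))
    ds = simulate_incubation(cfg)
    amounts = ds.time_series[0].amounts_umol()
    ratios = amounts[1:] / amounts[:-1]
    assert np.allclose(ratios, ratios[0])


def test_consumption_beyond_inventory_truncates_with_warning():
    cfg = SimulationConfig(seed=0, noise_cv=0.0, treatments=("methane",),
                           true_rates={"methane": 2000.0},
                           srr_excess={"methane": 0.0})
    with pytest.warns(UserWarning, match="truncating"):
        ds = simulate_incubation(cfg)
    assert ds.time_series[0].amounts_umol()[-1] == 0.0


def test_noise_magnitude_matches_configured_cv():
    rng_rel = []
    cfg = scenario_paper_defaults(seed=21)
    ds = simulate_incubation(cfg)
    for ts in ds.series_for("N2"):
        n0 = ds.truth["per_treatment"]["N2"]["initial_amount_umol"]
        rng_rel.extend(ts.amounts_umol() / n0 - 1.0)
    assert np.std(rng_rel) == pytest.approx(0.04, abs=0.02)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(noise_cv=-0.1)
    with pytest.raises(ValueError):
        SimulationConfig(fraction_to_dic={"methane": 1.5})
    with pytest.raises(ValueError):
        SimulationConfig(kinetic_order="second")


def test_rate_estimator_recovers_all_published_truth_rates():
    """Across the four treatments, mean recovered rates over 30 seeds stay
    within Monte-Carlo error of the injected truth (unbiasedness)."""
    recovered: dict[str, list[float]] = {t: [] for t in
                                         ("methane", "ethane", "propane", "butane")}
    for seed in range(30):
        ds = simulate_incubation(scenario_paper_defaults(seed=100 + seed))
        for treatment, store in recovered.items():
            for ts in ds.series_for(treatment):
                store.append(fit_consumption_rate(ts).rate)
    truths = {"methane": 263.0, "ethane": 168.0, "propane": 354.0, "butane": 125.0}
    for treatment, values in recovered.items():
        arr = np.asarray(values)
        sem = arr.std(ddof=1) / np.sqrt(arr.size)
        assert abs(arr.mean() - truths[treatment]) < 3.5 * sem
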