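# Methods

This note records the models, parameter choices and numerical decisions
behind `alkox`, in the package's own words.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Redox stoichiometry

Complete oxidation of an n-alkane to bicarbonate coupled to sulfate
reduction is derived from electron balance.  Each carbon moves from its
mean alkane oxidation state −(2n+2)/n to +4 in HCO3⁻, donating 6n+2
electrons per molecule; sulfate→sulfide accepts 8.  The reaction

CnH2n+2 + (3n+1)/4 SO4²⁻ → n HCO3⁻ + (3n+1)/4 HS⁻ + H2O + (n−1)/4 H⁺

closes hydrogen, oxygen and charge exactly; coefficients are stored as
`fractions.Fraction` so balance checks are identities, not float
comparisons.  The balance report gives residuals as reactant-side minus
product-side totals per element plus charge, and an electron residual
(donated − accepted) from per-element formal oxidation-state accounting.
The literature reaction set is shipped verbatim under `source="table6"`;
its butane entry (26 SO4²⁻ + 9 C4H10 + 4 H2O → 36 HCO3⁻ + 36 H⁺ + 26 HS⁻)
is element-balanced but carries a −26 charge residual and implies 26/9 ≈
2.89 sulfate per butane, whereas electron balance requires 13/4 = 3.25.
Both versions are exposed, flagged by `source`, so users can reproduce
published numbers *and* see the inconsistency; the package never guesses
which the original authors intended.

### Gibbs energies

ΔG⁰ per mol sulfate is Σ(signed coefficient × ΔGf°)/|sulfate coefficient|
at 1 M / 1 atm / 298.15 K.  The shipped ΔGf° table
(`alkox/data/gibbs_formation.csv`) uses CRC-style values with
aqueous-phase energies for dissolved species (including the alkanes) and
the gas-phase reference for H2.  Thermodynamic compilations disagree by a
few kJ/mol — and published per-sulfate energies for these reactions mix
aqueous and gas-phase alkane conventions — so comparisons against
published values use a ±5 kJ/(mol SO4²⁻) tolerance, and the propane/butane
entries computed from the all-aqueous table are a few kJ more exergonic
than some published figures.  Proton activity: the default is the strict
1 M standard state, which is what the published per-sulfate values are
numerically consistent with; `ph7=True` applies an explicit
RT·ln(10⁻⁷) ≈ −39.96 kJ per mol H⁺ produced.  Temperature and
ionic-strength corrections to in-situ conditions (7–8 °C seawater) are out
of scope.

## Headspace kinetics

Gas inventory: a concentration measurement c (mM) over headspace volume V
gives n = c·V µmol; a partial pressure gives ideal-gas n = P·V/(R·T).  The
~69 kPa fill pressure is interpreted as *gauge* (over 101.325 kPa
ambient): only then does the implied headspace concentration (~73 mM at
7 °C) fall inside the 40–80 mM range the incubation design targets.  The
convention is configurable in `VesselGeometry`.

Rates are ordinary least squares of inventory against time using **all**
time points — no outlier rejection, no kinetic model selection — so
estimates are comparable across treatments; a first-order generator mode
exists to probe misspecification.  The rate is −slope scaled per mL of
slurry (nmol mL⁻¹ day⁻¹).  Replicates are fitted independently and
summarized as mean ± sd.  Dissolved-phase gas is ignored in the inventory:
alkane solubilities at these conditions (0.8–1.3 mM against a ≥40 mM
headspace pool, of which the slurry aqueous phase holds ≲2%) put
partitioning well below the 4% measurement noise.  Leak correction by
subtracting the sediment-free control slope is available but off by
default — the ~4% control variation is treated as the noise floor, not a
bias.

## Radiotracer sulfate reduction

SRR = [SO4²⁻]·α·a/(t·(A+a)) with α = 1.06, the conventional
sulfide/sulfate fractionation factor, applied multiplicatively in the
numerator.  dpm inputs are assumed background-corrected; an optional blank
subtraction is provided.  Control correction subtracts the N₂-treatment
(intrinsic) rate; negative corrected rates are *flagged, not clipped*, so
downstream ratios stay transparent, and uncertainties combine in
quadrature.  Tracer back-reaction and chromium-reduction chemistry are not
modelled.

## δ¹³C mass balance

The DIC pool is treated as closed except for alkane-derived carbon.  The
delta-space balance [Alk] = [DIC_T0](δf − δ0)/(δalk − δf) is the
conventional linear approximation; the exact mode converts deltas to
¹³C/¹²C ratios (VPDB R = 0.0112372), does atom-fraction bookkeeping and
solves the same two-endmember balance exactly.  The two agree within 1%
relative for DIC shifts up to ~10‰ (verified against the exact oracle in
the test suite).  Beyond that regime — large transfers into a small pool,
especially when kinetic fractionation makes the transferred carbon lighter
than the source alkane — the linear form can return negative transfers;
these are direction-flagged and the ratio mode should be used.  Carbonate
precipitation is not modelled (a closed-pool assumption); transfers
convert to rates with the 100 mL / 80 day incubation defaults.

## Coupling ledger

The ratio basis is **mol alkane per mol sulfate** everywhere; per-carbon
rates (carbon_rate = n·alkane_rate) are carried alongside and never mixed
into ratios.  The ledger reports observed ratios against total and
corrected SRR, the stoichiometric prediction, sulfate demand
(rate × sulfate-per-alkane), the fraction of measured SRR that demand
explains (>1 reported as fold-excess), the unexplained carbon flux, and
the nitrate electron-budget bound (5 e⁻ per NO3⁻→N₂ against 4 e⁻ per
mean-zero-valence carbon→CO2, configurable to 8 for methane-derived
carbon).  Ratio uncertainties use first-order delta-method propagation of
replicate standard deviations; they are reported, not validated against
external values.  Display rounding is one decimal at ≥1 and two below 1;
full precision is retained internally.

## Synthetic incubation generator

The generator's defaults are the study conditions: 100 mL slurry / 100 mL
headspace at 69 kPa gauge and 7 °C; sampling at days 0–75 in 15-day steps
with endpoint chemistry at day 80; true consumption rates 263/168/354/125
nmol mL⁻¹ day⁻¹ for C1–C4 and 0 for the N₂ control; initial sulfate
31.6 mM and sulfide 2.3 mM; intrinsic SRR 94 nmol mL⁻¹ day⁻¹ with
alkane-attributable excesses 203/236/152/125 (total SRRs 297/330/246/219 —
the set consistent with corrected-rate algebra).  Measurement noise is
multiplicative lognormal with cv 0.04 (the sediment-free-control
variability), independent across time points and replicates; replicate
bottles are independent, as no within-bottle correlation structure is
constrained by the study design.

The sulfur budget is SRR-driven: sulfate declines by SRR × t and sulfide
rises equally.  Draining sulfate at the alkane's stoichiometric demand
instead would overrun the 31.6 mM pool for butane (3.25 × 10 mM consumed
plus the intrinsic rate ≈ 40 mM), contradicting the observed final
concentrations (13.3–31.6 mM); the SRR-driven budget keeps the butane
endpoint (~14.1 mM) inside that envelope and embodies the study's central
observation that C3–C4 oxidation outruns sulfate-coupled capacity.

Isotopes: the residual alkane follows Rayleigh fractionation,
R(f) = R0·f^(α−1) with α = 1 + ε/1000, i.e. δ ≈ δ0 + ε·ln f.  Default ε
values (0, −1, −3.4, −7.5‰ for C1–C4) were chosen once so that
propane/butane residual-pool enrichments of a few per mil emerge at
realistic consumed fractions (e.g. ε = −3.4‰ yields +4.4‰ at 73%
consumption); they are generator anchors, not measured fractionation
factors.  Source-alkane δ¹³C defaults (−60/−35/−30/−28‰) are typical
seep-gas values.  A per-treatment fraction of consumed carbon
(1/1/0.46/0.85 for C1–C4) is routed to DIC carrying the cumulative
consumed-pool composition via exact atom-fraction bookkeeping; the
remainder goes to an unmodelled sink with identical composition, so total
¹³C is conserved exactly in noiseless mode.  The initial DIC pool
(3.48 mM at −19.14‰) is the 1:1 media/porewater mixture computed by
`mix_initial_dic` from a 2 mM / −20‰ media endmember and the mean
porewater profile (4.96 mM / −18.8‰).  Tracer assays are fabricated by
inverting the turnover formula (exact round-trip when noiseless) with
optional Poisson counting noise at a 10⁵ dpm spike.

What the generator does *not* emulate: microbial growth dynamics (rates
are constant, not Monod), sulfide inhibition, carbonate precipitation,
gas-phase/dissolved partitioning kinetics, pressure drift, or within-bottle
correlation.  Passing recovery tests therefore demonstrate estimator
correctness under the stated design, not robustness to those real-data
features.

## Numerical and testing choices

Recovery tests use 25–100 seeds (hundreds of OLS fits run in seconds);
unbiasedness is asserted within 3–3.5 Monte-Carlo standard errors plus a
5% relative-bias cap.  Noiseless datasets must reproduce ground-truth
coupling algebra to at least 6 significant figures end to end.
Comparisons against published scalar values use the precision of the
printed figure (half a unit of the last digit, widened to a whole unit
where the source's own rounding is internally inconsistent — its butane
corrected SRR differs by 1 nmol mL⁻¹ day⁻¹ from its own
total-minus-control arithmetic, and its predicted butane ratio 9/26 was
printed truncated).  Degenerate inputs (zero time variance, zero initial
amounts, exhausted pools, singular isotope balances) raise typed errors or
warn-and-truncate as documented per function.
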