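# fecolumn

Natural-attenuation audit for toluene in iron-rich aquifer columns.

In anoxic aquifers, indigenous iron-reducing microbes couple the oxidation of
aromatic hydrocarbons such as toluene to the reduction of Fe(III) oxide
minerals. Monitoring practice usually tracks only the dissolved product,
Fe²⁺ — yet most of the reduced iron stays in the sediment as solid-phase
Fe(II). An attenuation assessment based on dissolved Fe²⁺ alone therefore
underestimates iron-coupled biodegradation by up to two orders of magnitude,
while the small mobile Fe²⁺ fraction can itself breach drinking-water limits
far downgradient. `fecolumn` packages the full accounting for a bench-scale
column system: design hydraulics, a 1D reactive-transport generator of
synthetic monitoring data, electron-balance conversion of Fe(II) pools to
degraded toluene, mass balance, and groundwater-threshold exceedance mapping.

It is written for hydrogeologists and environmental microbiologists who run
(or audit) column experiments on iron-reducing biodegradation and want every
step of the mass accounting reproducible and testable without raw lab data.

## The model in brief

**Hydraulics.** For a column of length $L$, effective porosity $n_e$,
conductivity $K$ and gradient $i$: Darcy flux $q = Ki$, seepage velocity
$v = q/n_e$, hydraulic retention time $\mathrm{HRT} = L n_e / (Ki)$, pumping
rate $Q = qA$. The default column (L = 1.0 m, d = 0.07 m, $n_e$ = 0.25,
K = 10 m/d, i = 0.002) gives HRT = 12.5 d and Q ≈ 0.05 mL/min.

**Transport and reaction.** Aqueous toluene obeys
$R\,\partial_t C = -v\,\partial_x C + D\,\partial_x^2 C - r$
with retardation $R = 1 + \rho_b K_d/n_e$, dispersion $D = \alpha_L v$, a
constant-feed inlet and free outflow. Biodegradation is dual-Monod in
toluene and solid Fe(III) with biomass growth:
$r = \mu_{max} B \frac{C}{K_C + C}\frac{\mathrm{Fe^{III}}}{K_{Fe}+\mathrm{Fe^{III}}}$,
$\dot B = Y r - k_d B$.

**Electron balance.** Complete mineralization
$\mathrm{C_7H_8} + 36\,\mathrm{Fe^{3+}} + 21\,\mathrm{H_2O} \rightarrow
7\,\mathrm{HCO_3^-} + 36\,\mathrm{Fe^{2+}} + 43\,\mathrm{H^+}$
transfers 36 electrons, so measured Fe(II) mass converts to toluene degraded
as $m_{tol} = \frac{m_{Fe}}{M_{Fe}}\cdot\frac{M_{tol}}{36}$. Produced Fe(II)
partitions into an immobile solid pool (fraction $1-f_d$, default
$f_d = 0.017$) and mobile dissolved Fe²⁺ that is transported unretarded and
never re-oxidised (the column stays anoxic).

**Exceedance.** Every (column, day, port, analyte) observation is classified
against GB14848 groundwater limits (toluene 700 µg/L, iron 0.3 mg/L);
censored observations (below detection) never count as exceeding.

## Worked example

```python
from fecolumn import (ColumnSpec, column_hydraulics, make_scenario,
                      simulate_column, integrate_solid_fe, toluene_equivalent,
                      partition_fractions, mass_balance, round_sig)

spec = ColumnSpec()
print(column_hydraulics(spec).retention_time)   # 12.5  (days)

# audit of measured end-of-run pools: 42 mg solid Fe(II), 0.72 mg dissolved
print(round_sig(toluene_equivalent(42.0), 2))   # 1.9  (mg toluene degraded)
print(partition_fractions(42.0, 0.72))          # (98.3..., 1.69...)  (%)
print(mass_balance(12.0, 0.03, 1.9).discrepancy)  # 10.07  (mg, non-iron removal)

# synthetic column: simulate, then recover the degradation from its own profile
run = simulate_column(make_scenario("treatment"))
solid = integrate_solid_fe(run.solid_fe_profile, spec)
print(round_sig(toluene_equivalent(solid.mass_mg), 2))   # 17.0 (mg)
print(round_sig(36 * run.ledger.toluene_degraded /
                run.ledger.fe2_total, 2))                # 1.0 (electron balance)
```

The first block reproduces the audit arithmetic: 42 mg of solid-phase Fe(II)
is worth 1.9 mg of fully mineralized toluene; 98 % of the reduced iron is
immobile; removing ~12 mg of toluene while explaining only 1.9 mg by iron
leaves a >10 mg discrepancy (sorption / non-iron pathways). The second block
shows the closed loop on synthetic data: integrating the simulated solid
profile returns the simulator's own degraded mass, and the Fe(II):toluene
mole ratio is exactly 36.

Command line:

```
fecolumn hydraulics
fecolumn report --config examples/column.yaml --seed 1 --out-dir out/
```

writes monitoring and solid-profile CSVs per column plus `mass_balance.csv`,
`exceedance.csv` and a plain-text summary, all headed by the config hash and
seed (identical seeds give byte-identical outputs).

## Layout

- `fecolumn.column` — column specification and design hydraulics
- `fecolumn.stoichiometry` — 36-electron Fe(II)↔toluene conversions
- `fecolumn.simulate` — reactive-transport generator, scenarios, measurement model
- `fecolumn.quantify` — profile/flux integration, partitioning, mass balance
- `fecolumn.exceedance` — threshold classification and plume metrics
- `fecolumn.tables`, `fecolumn.pipeline`, `fecolumn.cli` — CSV contracts,
  orchestration, command line

See `docs/methods.md` for model assumptions, parameter choices, numerics and
limitations.
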