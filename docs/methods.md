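# Methods

## System and scope

`fecolumn` models a bench-scale aquifer column: quartz sand amended with
2.5 % ferric hydroxide (ferrihydrite-type, the most bioavailable common iron
oxide), fed from the bottom with 0.1 mmol/L toluene (≈ 9.2 mg/L) at a
constant pump rate, with nine side ports at 10 cm spacing sampled on days
1–8, 13, 18, 23, 28, 33, 38 and 43. Treatment columns carry an
iron-reducing, toluene-degrading consortium; control columns are sterilised
(HgCl₂) so only advection, dispersion and sorption act. The package
implements the audit layer — hydraulics, Fe(II) mass accounting,
electron-balance conversion, mass balance, threshold exceedance — plus a
synthetic-data generator so every stage can be verified end-to-end without
laboratory data.

## Hydraulics

Darcy flux `q = K·i`; seepage velocity `v = q/nₑ`; retention time
`HRT = L·nₑ/(K·i)`. The HRT deliberately uses the *effective* porosity
(0.25) and the full column length (1.0 m): this is the travel time of the
mobile pore water and, with the default K = 10 m/d and i = 0.002, equals
12.5 days. Bulk density `ρ_b = ρ_grain(1 − n)` uses total porosity and the
quartz grain density 2.65 g/cm³ (→ 1.855 g/cm³, ≈ 7.14 kg of dry packing);
it anchors all mg/kg ↔ column-mass conversions.

## Transport model

Vertex-centred finite volumes on a uniform grid (default dx = 1 cm; ports
coincide with nodes). Aqueous storage lives in the mobile porosity nₑ;
linear equilibrium sorption gives a storage coefficient `nₑ + ρ_b·K_d`,
i.e. retardation `R = 1 + ρ_b·K_d/nₑ`. We use nₑ (not total porosity) in R
for consistency with the mobile-water formulation — one porosity governs
both velocity and storage, so tracer transport reproduces the HRT exactly.
Dispersion `D = α_L·v` with α_L = 0.02 m, a typical desk-scale longitudinal
dispersivity (Péclet ≈ 50 over the column).

Boundary conditions: the inlet is the flux (Danckwerts) form of the
constant-feed condition — the pump delivers `q·C_in` regardless of what the
first cell does — which is exactly mass-conservative in the finite-volume
bookkeeping; the outlet is free outflow (zero dispersive flux, advective
export `q·C_N`).

Time stepping is operator-split per macro step (auto-chosen, day-aligned,
default 0.025 d): explicit upwind advection sub-stepped to Courant ≤ 0.45,
implicit centred dispersion (tridiagonal solve; unconditionally stable and
conservative), then a pointwise reaction update. Every boundary flux and
reaction removal is accumulated as it is applied, so the toluene and iron
mole ledgers close to machine precision — the ≤ 0.5 % closure requirement
is a safety margin, not the observed error. Upwinding adds numerical
dispersion of order `v·dx/2` (equivalent α ≈ 0.005 m), small against the
physical α_L.

## Reaction model

The rate law is a generator design choice (no kinetic law is identifiable
from end-of-run pools alone): dual-Monod in toluene and solid Fe(III) with
biomass growth,

    r = μ_max · B · C/(K_C + C) · Fe³⁺/(K_Fe + Fe³⁺),   dB/dt = Y·r − k_d·B.

The reaction update is clipped: a sub-step may consume at most the toluene
present in a cell and at most the Fe(III) remaining, so concentrations and
the Fe(III) pool can never go negative; Fe(III) exhaustion simply drives the
rate to zero. Consumed toluene produces Fe(II) at the fixed stoichiometric
ratio (36 mol Fe per mol toluene, ≈ 21.8 mg Fe/mg toluene), split `f_d` to
a mobile dissolved species (transported with R = 1, no re-oxidation sink —
the column's sustained anoxia shuts that pathway) and `1 − f_d` to an
immobile solid pool.

Defaults (calibration constants of the generator, with units):

| parameter | default | meaning |
|---|---|---|
| μ_max | 5.0 mg tol (mg biomass)⁻¹ d⁻¹ | maximum specific utilisation rate |
| K_C | 2.0 mg/L | toluene half-saturation |
| K_Fe | 500 mg/kg | Fe(III) half-saturation (non-limiting at the 13 g/kg initial pool) |
| Y | 0.125 mg/mg | growth yield |
| B₀ | 3·10⁻⁶ mg/L | initial active biomass |
| k_d | 0 d⁻¹ | biomass decay |
| f_d | 0.017 | dissolved share of produced Fe(II) (the 0.72/42 outcome ratio) |
| K_d | 0.05 L/kg | toluene sorption on the sand (R ≈ 1.37) |
| side sink | 0 d⁻¹ | optional first-order non-iron (e.g. aerobic) toluene loss |

The kinetic constants were chosen once so the defaults reproduce the
qualitative dynamics the audit assumes: rise-then-fall toluene at the ports,
dissolved Fe²⁺ below its detection limit for the first ~10 days, then
>99 % toluene removal confined to the first ~10 cm while the Fe²⁺ plume
spans the whole column. K_d was chosen so the sterile control's outlet first
crosses the 700 µg/L limit between days 10 and 20. The initial Fe(III) pool
derives from the 2.5 % Fe(OH)₃ amendment (× 55.845/106.867 → ≈ 13.1 g Fe/kg),
so iron is never rate-limiting at the simulated degradation totals.

## Measurement model

Sampled port concentrations are multiplied by a mean-one lognormal factor
(CV default 0.05, seeded); values below the detection limit are flagged
censored and reported *as* the limit. Detection limits: toluene 0.1 µg/L
(GC); dissolved Fe²⁺ 0.05 mg/L, a typical spectrophotometric limit adopted
as the package default. Solid-profile output is noise-free at full grid
resolution.

## Quantification choices

* Solid-profile integration: trapezoid over the sampled points with constant
  extrapolation of the end samples to the column ends (default), or a
  single-exponential least-squares fit integrated analytically. Both are
  reported with the method name, because the two can differ substantially
  when the profile is strongly inlet-peaked — users should see that
  sensitivity rather than a single number.
* Dissolved "classical method": trapezoid of `C(t)·Q` over the sampling
  days at one port; `peak` mode scans all ports and keeps the maximum.
  Censored samples contribute zero by default (conservative); `half`
  substitutes DL/2.
* Mass balance: inflow from the feed concentration (or, in conservative
  mode, the sterile control's late-window equilibrium effluent, which
  already discounts preparation and volatilisation losses); outflow from the
  farthest-port flux integral. The discrepancy `(in − out) − degraded` is
  the removal the iron pathway cannot explain (sorption, storage, side
  reactions).
* Display rounding: two significant figures; internal values full precision.

## What the generator emulates — and what it does not

Passing round-trip tests shows the *accounting* is correct: the solid-phase
method recovers the simulated iron-coupled degradation to within the
integration error, the dissolved-only method recovers ≈ f_d of it (the
quantitative basis of the ~1–2 % underestimate), and exceedance maps show
toluene containment against Fe²⁺ plume expansion. It does not show that the
kinetic constants describe any real column; they are identifiable only as a
family reproducing the qualitative dynamics.

Known deviations from real column behaviour, accepted by design:

* The Fe²⁺ lag is represented purely by biomass growth from a small
  inoculum. Real columns are inoculated heavily and their lag is driven by
  degradation intermediates reacting onward to Fe(III); intermediates are
  not modelled. Consequently synthetic treatment ports transiently carry
  near-influent toluene before the biomass catches up, whereas real
  treatment ports stayed below the 700 µg/L limit throughout.
* A corollary: when the growing biofilm finally consumes the toluene stored
  along the column during the lag, Fe(II) production briefly exceeds its
  supply-limited steady rate, so downstream dissolved Fe²⁺ rises to a
  transient maximum and settles from above onto the steady value
  `f_d · 21.8 · C_in` (≈ 3.4 mg/L). Port series are therefore monotone up
  to that maximum and bounded below by the steady floor afterwards — not
  strictly non-decreasing forever.
* Wall effects, packing heterogeneity, sampling withdrawal volumes, Fe²⁺
  re-oxidation, and early-experiment contamination artefacts are not
  simulated.

## Numerical and degenerate-input conventions

Ports must coincide with grid nodes (dx must divide the port spacing).
Sterile configurations force the biological rate to zero regardless of
μ_max. An all-censored flux series integrates to zero. A zero-length or
single-point solid profile is rejected; a failed exponential fit falls back
to trapezoid with a warning. Equality with a threshold counts as exceeding.
All randomness flows from a single integer seed (scenario seeds are spawned
from it), and identical seeds give byte-identical pipeline output files.

## Problem sizes

Default runs use 101 grid nodes (dx = 1 cm), 40 macro steps per day over
43 days, and four columns per pipeline run; a full pipeline completes in
about a second on one CPU, and the verification hooks in the acceptance
script run three additional single-column simulations.
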