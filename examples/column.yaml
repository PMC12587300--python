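# Reference configuration: two inoculated columns (T1, T2) and two
# HgCl2-sterilised controls (C1, C2) on the 100 cm x 7 cm i.d. design.
column:
  length: 1.0            # m
  inner_diameter: 0.07   # m
  porosity: 0.30
  effective_porosity: 0.25
  hydraulic_conductivity: 10.0   # m/day
  hydraulic_gradient: 0.002
  fe_hydroxide_mass_fraction: 0.025
  grain_density: 2.65    # g/cm3 (quartz)
  n_ports: 9
  port_spacing: 0.1      # m

# shared SimulationConfig overrides for every column
scenario:
  duration: 43.0
  noise_cv: 0.05

columns:
  - {scenario: treatment, column_id: T1}
  - {scenario: treatment, column_id: T2}
  - {scenario: control, column_id: C1}
  - {scenario: control, column_id: C2}

quantify:
  method: trapezoid      # or fit_then_integrate
  censored_as: zero      # censored flux samples count as 0 (conservative)
  flux_mode: peak        # dissolved flux at the port maximising the integral
  inflow_mode: constant  # or conservative (control equilibrium effluent)
  late_window: [33.0, 43.0]

thresholds:              # GB14848 groundwater limits, monitoring units
  toluene: 700.0         # ug/L
  fe2_dissolved: 0.3     # mg/L

seed: 1
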