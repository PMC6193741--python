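# Versioned physiological parameter file (SI units throughout).
# Values are literature-anchored defaults for a desmoplastic murine tumour;
# the few starred entries were fixed once by the shipped calibration
# (`oncoflow calibrate`) against the package's growth/flow anchors.

fluid:
  mu_blood: 3.5e-3          # Pa s, whole-blood dynamic viscosity
  mu_plasma: 1.2e-3         # Pa s
  mu_interstitial: 1.0e-3   # Pa s, interstitial fluid
  K_int_tumour: 5.0e-15     # m^2/(Pa s), interstitial hydraulic conductivity
  K_int_host: 6.4e-15       # m^2/(Pa s)
  sigma_osmotic: 0.82       # plasma-protein reflection coefficient (tumour)
  pi_vascular: 2666.0       # Pa (20 mmHg), plasma colloid osmotic pressure
  pi_interstitial: 1995.0   # Pa (15 mmHg), interstitial osmotic pressure
  p_inlet: 3333.0           # Pa (25 mmHg), vascular inlet pressure
  p_outlet: 1333.0          # Pa (10 mmHg), vascular outlet pressure

lymph:
  K_lmp: 1.0e-11            # m/(Pa s), lymphatic wall hydraulic permeability
  S_lmp_host: 7000.0        # 1/m, lymphatic density in host tissue
  S_lmp_tumour: 0.0         # dysfunctional tumour lymphatics
  p_lmp: 0.0                # Pa, constant lymphatic pressure

wall:
  gamma_p: 0.06             # pore surface fraction of the vessel wall
  thickness: 5.0e-6         # m, endothelial wall thickness
  pore_radius: 1.5e-7       # m, default r_p (hyperpermeable)

drug:
  molecule_size: 1.0e-9     # m, hydrodynamic diameter s_c (cytotoxic scale)
  temperature: 310.0        # K
  k_on: 5.0                 # 1/s, binding (association) rate in the tumour
  k_off: 5.0e-2             # 1/s, unbinding rate
  k_int: 1.0e-4             # 1/s, internalisation rate
  delta_i: 3.0e-6           # 1/s, internalised-drug decay rate
  c_v_max: 1.0              # dimensionless bolus peak
  tau_c: 21600.0            # s, bolus e-folding time (6 h)

oxygen:
  diffusivity: 2.0e-9       # m^2/s
  uptake_tumour: 2.0e-3     # 1/s, first-order consumption in the tumour
  decay_host: 1.0e-3        # 1/s, background clearance

mde:
  diffusivity: 2.0e-10      # m^2/s, matrix-degrading-enzyme surrogate
  decay: 5.0e-4             # 1/s

tissue:
  lambda_ecm: 0.15          # 1/day, ECM remodelling rate (*calibrated)
  delta_ecm: 0.025          # 1/day, MDE-driven ECM degradation rate
  ecm_scale: 4.0            # ϵ̄, remodelling saturation scale
  delta_d: 1.0              # 1/day, drug-driven matrix decay rate
  ecm_threshold: 0.05       # ϵ̄_d, depletion threshold on ϵ
  ci_threshold: 0.05        # c̄_i, internalised-drug threshold
  a_d: 1.0                  # depletion exponent
  alpha_g: 80.0             # growth amplitude (*calibrated)
  beta_g: 1.0               # Gompertz shape
  gamma_g: 3.0              # oxygen sensitivity of growth
  delta_g: 3.0              # ECM exponent in G(ϵ)
  tau_growth: 1.0           # days, relaxation time of ϑ_g toward its target
  ecm_tumour_init: 0.2      # initial ϵ in the tumour
  ecm_host_init: 1.0        # initial ϵ in the host
  a_w: 1.0                  # stiffness exponent in m(ϵ) = μ ϵ^a_w
  mu_shear: 1000.0          # Pa, ECM shear-stiffness constant
  kappa_bulk: 20000.0       # Pa, bulk modulus

vessels:
  compress_threshold: 200.0   # Pa, net compressive load for compression
  collapse_threshold: 900.0   # Pa, net compressive load for collapse
  compressed_factor: 0.6      # radius multiplier when compressed
  wss_setpoint: 0.5           # Pa, wall-shear-stress homeostatic set-point
  remodel_gain: 0.05          # 1/day, radius remodelling gain
  radius_min: 2.0e-6          # m
  radius_max: 1.2e-5          # m
  sprout_rate: 0.5            # 1/day, per-candidate sprouting probability rate
  sprout_length: 3.0e-4       # m, new tip segment length
  sprout_radius: 3.0e-6       # m, lumen radius of new sprouts
  hypoxia_threshold: 0.35     # ξ below which sprouting is triggered
  anastomosis_radius: 1.5e-4  # m, tip-to-node fusion distance
  max_segment_factor: 2.5     # cap on segment count growth

metrics:
  perfusion_velocity: 1.0e-4  # m/s (0.1 mm/s) perfusion threshold
  supply_velocity_factor: 0.01  # oxygen/drug exchange gate, fraction of above
  sample_resolution: 16       # δ_max sample grid points per edge
  analysis_halfwidth_frac: 0.42  # analysis subdomain half-width / edge length
  shell_width: 1.0e-3         # m, peri-tumoural averaging shell
  lambda_offset: 1.4          # convexity index offset (*calibrated)
  lambda_slope: 4.0           # convexity index slope on distance skewness
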