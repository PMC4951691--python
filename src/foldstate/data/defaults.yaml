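# Default configuration for foldstate.
# Every empirical constant the pipeline uses lives here so it can be
# overridden without touching code (foldstate.config.load_config).

charge_hydropathy:
  # Boundary of the charge-hydropathy (Uversky) plot:  <R>_b = c1*<H> - c0.
  # Points with mean net charge below the boundary fall on the native side.
  c1: 2.785
  c0: 1.151
  hydropathy_window: 5
  # Side-chain and terminal pKa values used for the Henderson-Hasselbalch
  # charge model at pH != 7 (EMBOSS-style table).
  pka:
    D: 3.9
    E: 4.1
    C: 8.5
    Y: 10.1
    H: 6.5
    K: 10.8
    R: 12.5
    n_term: 8.6
    c_term: 3.6

solvent:
  viscosity_pa_s: 0.001        # water at ~293 K
  buoyancy_product: 0.73       # nu2*rho with nu2 = 0.73 cm^3/g, rho = 1 g/cm^3

# Empirical log-log Rh-vs-mass scaling laws per conformational state:
#   log10(Rh [Angstrom]) = a * log10(M [Da]) + b
scaling_laws:
  native:              {a: 0.369, b: -0.254}
  molten_globule:      {a: 0.334, b: -0.053}
  pre_molten_globule:  {a: 0.403, b: -0.239}
  urea_unfolded:       {a: 0.521, b: -0.649}
  gdmcl_unfolded:      {a: 0.543, b: -0.709}

# Q-factor (Rg/Rh) compatibility bands.  Overlaps are intentional; the
# state classifier disambiguates.  null upper bound means unbounded.
q_bands:
  sphere:              [0.765, 0.785]   # point value 0.775 +/- 0.01
  globular:            [0.76, 0.86]
  molten_globule:      [0.70, 0.93]
  pre_molten_globule:  [0.93, 1.15]
  random_coil:         [1.35, null]
q_adjacency_margin: 0.10

guinier:
  qrg_window: [0.759, 1.294]
  qrg_ceiling: 1.3       # conventional upper bound used for the config ceiling
  max_iterations: 50
  min_points: 5

kratky:
  smooth_window: 11      # Savitzky-Golay window (points)
  smooth_order: 3
  prominence_floor_fraction: 0.05   # of max(y)
  tail_band: [2.5, 4.0]  # in qRg
  # A curve with an interior peak is called compact-plus-flexible when the
  # high-qRg tail level reaches this fraction of the peak height.
  peak_fraction: 0.5

titration:
  stern_volmer_r2_threshold: 0.99
  runs_test_alpha: 0.05
  delta_aicc_threshold: 4.0
  temperature_k: 298.15

classifier:
  # Per-channel weights for the additive evidence vote.
  weights:
    charge_hydropathy: 1.0
    q_band: 1.0
    rh_deviation: 1.0
    kratky: 1.0
    unfolding: 1.0
    ans: 1.0
    lambda_max: 1.0
  lambda_max_buried_range: [330.0, 350.0]
  confidence:
    strong_top: 0.5
    strong_margin: 0.15
    weak_margin: 0.10
  # Tie-break priority (first wins) when two states share the top score.
  priority: [kratky, rh_deviation, q_band, unfolding, charge_hydropathy, ans, lambda_max]

synthetic:
  q_grid: {start: 0.05, stop: 4.0, points: 400}   # nm^-1, beamline-style range
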