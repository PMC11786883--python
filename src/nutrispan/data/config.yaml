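# Versioned model configuration.
#
# Energy densities are per-group approximations (kJ per gram on the
# canonical fresh/prepared-weight convention) intended for the energy
# accounting that derives the uncategorized-energy fraction; replace with
# survey-specific values when available.
config_version: 1

energy_density_kj_per_g:
  whole_grains: 4.5      # fresh (cooked-equivalent) basis
  vegetables: 1.5
  fruits: 2.2
  nuts: 25.0
  legumes: 4.0           # prepared basis
  fish: 6.0
  eggs: 6.5
  milk_dairy: 2.7        # milk-equivalent basis (cheese converted)
  refined_grains: 15.0   # dry basis, as reported
  red_meat: 8.0
  processed_meat: 11.0
  white_meat: 7.0
  ssb: 1.8
  added_sugars: 17.0

unit_conversion:
  whole_grain_dry_to_fresh: 3.33
  legume_dry_to_prepared: 2.5
  cheese_to_milk: 7.5

# Linear energy-expenditure projection used when no measured requirement is
# supplied.  These coefficients are a documented placeholder calibrated to
# adult averages (~7.9 MJ/d female, ~9.7 MJ/d male at age 40, 70 kg);
# substitute published equation coefficients for serious use.
energy_requirement:
  intercept_kj: 4500.0
  sex_offset_male_kj: 1800.0
  age_coef_kj_per_year: -10.0
  weight_coef_kj_per_kg: 55.0
  height_coef_kj_per_cm: 0.0
  default_anthropometry:
    weight_kg: 70.0
    height_cm: 170.0

# Projection defaults surfaced here so appendix-derived values can be
# dropped in without code changes.
projection:
  lag_full_effect_years: 10.0
  initial_effect_fraction: 0.0
  overlap_w: 1.0

uncertainty:
  n_draws: 1000
  interval_percent: 95.0
  uncategorized_kappa: 0.1   # log-HR half-width per unit uncategorized fraction
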