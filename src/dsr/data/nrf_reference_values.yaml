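# Default daily values (DV, qualifying nutrients) and maximum reference
# values (MRV, nutrients to limit) for the NRF8.3 index, per day.
# The qualifying set and every value are configuration, not code: edit or
# replace this table to follow a different reference standard.  Defaults
# follow widely used nutrient-profiling daily values; magnesium is listed
# for convenience but not part of the default 8-nutrient set.
qualifying:
  protein_g: 50.0        # g
  fibre_g: 28.0          # g
  vitamin_a_ug: 900.0    # ug RAE
  vitamin_c_mg: 90.0     # mg
  vitamin_e_mg: 15.0     # mg
  calcium_mg: 1300.0     # mg
  iron_mg: 18.0          # mg
  potassium_mg: 4700.0   # mg
limiting:
  saturated_fat_g: 20.0  # g
  free_sugars_g: 50.0    # g
  sodium_mg: 2300.0      # mg
optional_qualifying:
  magnesium_mg: 420.0    # mg; swap into `qualifying` to use
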