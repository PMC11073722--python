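{
  "version": "1.0",
  "species": "Spodoptera frugiperda",
  "notes": "Published constant-temperature life-table fits for the fall armyworm reared at 20-32 C. Temperatures in deg C, rates per day. temp_domain reflects the ~12-14 C lower developmental threshold commonly reported for the species and the upper lethal range of the fitted curves.",
  "temp_domain": [12.0, 35.0],
  "sex_ratio": 0.5,
  "stages": {
    "egg": {
      "development_rate": {"name": "logan_5", "params": {"alph": 9.72767, "k": 939.4538, "b": 0.18416, "Tmax": 37.56302, "Dt": 2.9495}},
      "mortality": {"name": "wang_2", "params": {"Tl": 21.64409, "Th": 21.64362, "B": 3.43643, "H": 0.02341}},
      "time_slope": 139.46
    },
    "larva": {
      "development_rate": {"name": "hilbert_logan_2", "params": {"trid": 22598.24822, "D": 157157056.08524, "Tmax": 67.76324, "Dt": 2.71287}},
      "mortality": {"name": "wang_1", "params": {"Topt": 24.7892, "B": 1.75891, "H": 0.01712}},
      "time_slope": 169.36
    },
    "pupa": {
      "development_rate": {"name": "logan_1", "params": {"Y": 0.00976, "Tmax": 33.23127, "p": 0.09202, "v": 0.58139}},
      "mortality": {"name": "gaussian_log", "params": {"y0": 0.8559, "a": -0.8503, "x0": 18.0909, "b": 0.8041}},
      "time_slope": 21.70
    }
  },
  "adult": {
    "female_senescence": {"name": "hilbert_logan_3", "params": {"trid": 992834.7, "Tmax": 38.567, "Tmin": 21.6748, "D": 827000000.0, "Dt": 0.0172, "Smin": 0.0949}},
    "male_senescence": {"name": "exponential_simple", "params": {"b1": 0.02, "b2": 0.0773}},
    "total_fecundity": {"name": "gaussian", "params": {"y0": -88.5085, "a": 1005.384, "x0": 23.0144, "b": 5.4884}},
    "relative_oviposition": {"name": "exponential_modified_1", "params": {"a": -0.11825, "b": 1.17905, "c": 0.76887}},
    "female_time_slope": 10.63,
    "male_time_slope": 8.63
  }
}
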