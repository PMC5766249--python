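{
  "dose_response": {
    "b0": {"estimate": 1.4153, "se": 0.115, "p": 9.286e-08},
    "b1": {"estimate": -0.001043, "se": 0.0001392, "p": 1.204e-05},
    "d0": {"estimate": 0.02159, "se": 0.0055, "p": 0.00237},
    "d1": {"estimate": 0.0008418, "se": 9.816e-05, "p": 3.351e-06}
  },
  "toxicity": {
    "log_intercept": {"estimate": 9.02464, "se": 0.06392, "p": 0.00451},
    "log_slope": {"estimate": -0.20599, "se": 0.02021, "p": 0.06227},
    "linear_intercept": {"estimate": 7596.2, "se": 632.0, "p": 0.0528},
    "linear_slope": {"estimate": -942.3, "se": 199.9, "p": 0.1330}
  },
  "pk": {
    "tau0": {"estimate": -2.1987, "se": 1.1334, "p": 0.0843},
    "tau1": {"estimate": 0.4959, "se": 0.1541, "p": 0.0105},
    "tumor_serum_ratio": 0.61,
    "molecular_weight_g_per_mol": 943.5,
    "t_cmax_days": 0.16666666666666666,
    "half_life_days": 1.0
  }
}
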