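{
  "margins": {
    "p_pos_st": 0.3,
    "p_pos_ifmi": 0.1,
    "p_pos_second": 0.1,
    "psa_mode": "fixed_rr"
  },
  "costs": {
    "drg_cost": 3508.0,
    "lost_productivity": 521.0,
    "agent_cost": 500.0,
    "device_price": 150000.0,
    "maintenance_rate": 0.1,
    "device_lifespan": 7.0,
    "surgeries_per_year": 200.0,
    "draping_cost": 23.0,
    "staff_addon_cost": 107.0,
    "st_duration": 59.0,
    "prolongation": 10.0,
    "fsa_duration": 27.0,
    "staff_time_saving_factor": 0.64,
    "cost_per_minute": 68.22916666666666,
    "fsa_fixed_saving": 91.91166666666652,
    "working_days_lost": 14.0
  },
  "psa": {
    "p_pos_ifmi": {
      "kind": "beta",
      "mean": 0.1,
      "se": 0.018
    },
    "p_pos_st": {
      "kind": "beta",
      "mean": 0.3,
      "se": 0.051
    },
    "p_pos_second": {
      "kind": "beta",
      "mean": 0.1,
      "se": 0.018
    },
    "drg_cost": {
      "kind": "gamma",
      "mean": 3508.0,
      "se": 175.0
    },
    "st_duration": {
      "kind": "triangular",
      "mean": 59.0,
      "min": 35.0,
      "max": 83.0
    },
    "prolongation": {
      "kind": "triangular",
      "mean": 10.0,
      "min": 5.0,
      "max": 15.0
    },
    "fsa_duration": {
      "kind": "triangular",
      "mean": 27.0,
      "min": 13.0,
      "max": 53.0
    },
    "staff_time_saving_factor": {
      "kind": "fixed",
      "mean": 0.64
    },
    "staff_addon_cost": {
      "kind": "gamma",
      "mean": 107.0,
      "se": 5.0
    },
    "agent_cost": {
      "kind": "gamma",
      "mean": 500.0,
      "se": 25.0
    },
    "camera_cost": {
      "kind": "gamma",
      "mean": 182.0,
      "se": 18.0
    },
    "draping_cost": {
      "kind": "gamma",
      "mean": 23.0,
      "se": 2.0
    },
    "lost_productivity": {
      "kind": "gamma",
      "mean": 521.0,
      "se": 52.0
    }
  },
  "run": {
    "n_draws": 10000,
    "seed": 42,
    "tornado_fraction": 0.25
  }
}
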