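{
  "schema_version": 1,
  "regimes": {
    "normal": {
      "obtain": {
        "form": "regression",
        "distribution": {"family": "beta", "param1": 0.835, "param2": 0.718},
        "regression": {
          "beta0": 10.19,
          "beta1": -0.00115,
          "covariate": "units_sold_today",
          "random_effect_variance": 0.68,
          "beta0_se": 0.01588,
          "flags": []
        }
      },
      "time_success": {
        "form": "distribution",
        "distribution": {"family": "gamma", "param1": 2.9, "param2": 0.035}
      },
      "time_failure": {
        "form": "distribution",
        "distribution": {"family": "gamma", "param1": 9.11, "param2": 0.072}
      },
      "arrest": {
        "form": "distribution",
        "distribution": {"family": "beta", "param1": 0.43, "param2": 1500}
      },
      "broker": {
        "form": "distribution",
        "distribution": {"family": "beta", "param1": 0.61, "param2": 0.76}
      },
      "invite": {
        "form": "regression",
        "distribution": {"family": "beta", "param1": 0.55, "param2": 7.45},
        "regression": {
          "beta0": -4.0763,
          "beta1": 0.00141,
          "covariate": "broker_purchase_count",
          "random_effect_variance": 0.0,
          "beta0_se": 0.00762,
          "flags": []
        }
      }
    }
  },
  "fit_report": {
    "source": "reference fits for the Denver open-air market model, steady-state window (days 180-365) of 100 full-model runs",
    "selection": {
      "obtain": "regression",
      "time_success": "distribution",
      "time_failure": "distribution",
      "arrest": "distribution",
      "broker": "distribution",
      "invite": "regression"
    }
  }
}
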