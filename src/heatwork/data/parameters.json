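{
  "schema_version": 1,
  "sigmoid": {
    "heat_index": {
      "pwc50": 55.47,
      "hillslope": -2.90,
      "top": 100.0,
      "bottom": 0.0,
      "valid_range": [14.0, 85.0],
      "r_squared": 0.97,
      "rmse": 4.10,
      "provenance": "shipped-pooled"
    },
    "humidex": {
      "pwc50": 54.50,
      "hillslope": -4.10,
      "top": 100.0,
      "bottom": 0.0,
      "valid_range": [13.0, 71.0],
      "r_squared": 0.96,
      "rmse": 4.86,
      "provenance": "shipped-pooled"
    },
    "wet_bulb": {
      "pwc50": 30.98,
      "hillslope": -5.90,
      "top": 100.0,
      "bottom": 0.0,
      "valid_range": [10.0, 39.0],
      "r_squared": 0.95,
      "rmse": 5.60,
      "provenance": "shipped-pooled"
    },
    "utci": {
      "pwc50": 45.33,
      "hillslope": -4.30,
      "top": 100.0,
      "bottom": 0.0,
      "valid_range": [15.0, 63.0],
      "r_squared": 0.94,
      "rmse": 5.90,
      "provenance": "shipped-pooled"
    },
    "wbgt": {
      "pwc50": 33.63,
      "hillslope": -6.33,
      "top": 100.0,
      "bottom": 0.0,
      "valid_range": [12.0, 40.0],
      "r_squared": 0.94,
      "rmse": 5.94,
      "provenance": "shipped-pooled"
    },
    "tskin": {
      "pwc50": 36.06,
      "hillslope": -26.57,
      "top": 100.0,
      "bottom": 0.0,
      "valid_range": [30.0, 38.0],
      "r_squared": 0.88,
      "rmse": 8.42,
      "provenance": "shipped-pooled"
    }
  },
  "ta_rh": {
    "pooled": {
      "a": -12.28,
      "b": 87.99,
      "c": -2.21,
      "d": 2.63,
      "ta_valid": [15.0, 50.0],
      "rh_valid": [20.0, 80.0],
      "r_squared": 0.98,
      "rmse": 3.09,
      "provenance": "shipped-pooled"
    }
  },
  "perception": {
    "sensation": {"coefficient": 0.13, "rate": 0.15, "tskin_valid": [30.0, 38.0]},
    "comfort": {"slope": 0.47, "intercept": -13.06, "tskin_valid": [30.0, 38.0]}
  }
}
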